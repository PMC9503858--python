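# Methods

## Model and assumptions

`planardose` estimates the absorbed dose to the bone marrow (BM) after
systemic radionuclide therapy from one planar whole-body acquisition. The
core approximation is that the body's time–activity behaviour can be
described by two compartments with *fixed, experience-derived* normalized
kinetics, each scaled by a single factor determined from the scan:

* **High-uptake compartment** (tumour/remnant/physiological foci):
  mono-exponential, u_high(t) = 2^(−t/T_M).
* **Low-uptake compartment** (the rest of the body): bi-exponential,
  u_low(t) = w_S·2^(−t/T_S) + w_F·2^(−t/T_F), with w_S + w_F = 1.

The scale factors S_high, S_low solve a two-equation linear system: they sum
to the administered activity A0, and the ratio of scaled activities at the
acquisition time t̄ equals the measured high/low counts-per-second ratio ρ.
Because both compartments are measured in the same acquisition, ρ is a pure
counts ratio and no absolute camera calibration is needed
(*self-calibration*). This also means attenuation, scatter and background
are deliberately **not** corrected: regions with densities far from the body
mean (lungs) are known to be handled poorly, which is accepted as part of
the approximation.

The normalized curves are effective curves, not reconstructions of the true
kinetics. For a mono-exponential truth A(t) = A0·e^(−t/τ) approximated by
the scaled effective curve S·e^(−t/τ_eff) matched at t̄, the cumulated-
activity error is E = A0·(τ − τ_eff·w(t̄)) with
w(t̄) = e^(−t̄/τ)/e^(−t̄/τ_eff); `single_timepoint_error` reports this
surface (absolute and relative) rather than asserting any fixed accuracy
band — the error depends jointly on τ/τ_eff and t̄, and a blanket "within
10%" claim does not hold across the whole interval ½τ_eff < τ < 2τ_eff
under this construction.

## Parameters and defaults

| parameter | default | units | meaning / why |
|---|---|---|---|
| T_M | 69 (¹⁷⁷Lu profile) | h | effective half-life, high compartment |
| T_S, T_F | 61, 2.4 | h | slow/fast effective half-lives, low compartment |
| w_S, w_F | 1/6, 5/6 | — | low-compartment weights (empirical convention) |
| T_M (¹³¹I) | 16 | h | radioiodine high-compartment half-life; the low-compartment half-lives for ¹³¹I are deliberately **mandatory config** with no default — no established profile ships with the package |
| κ | 1.0 | — | BM-to-low activity-concentration ratio; radiopharmaceutical-specific, always surfaced in config |
| Δ | 147 | keV | mean energy emitted (locally absorbed) per decay, ¹⁷⁷Lu electrons |
| φ, φ_SL | 1.0 | — | absorbed fractions for BM and lesion self-irradiation (≈1 for electrons) |
| m_BM, m_body, m_low | 1170, 73000, 71000 | g | reference-male region masses used to convert Ã to concentration |
| nnuf_cutoff | 0.5 | — | first-crossing threshold-selection cutoff (clinical default) |
| body_fraction | 0.01 | — | body-outline threshold as a fraction of Cmax |
| n_steps | 100 | — | ThI sweep resolution |
| connectivity | 8 | — | focus connectivity; 4 available |

S factors are consumed as data from a CSV
(`phantom,source_region,target_region,S_mGy_per_MBq_h`) in
mGy/(MBq·h); other units must be declared in an explicit `unit` column and
are converted at load. Computing S values (Monte Carlo, phantom geometry)
is out of scope. Missing (source, target) lookups raise; they are never
silent zeros. Absolute reproduction of published clinical dose grids
requires the reference-phantom S values and the numeric κ for the
radiopharmaceutical, neither of which ships with the package; the grid
machinery itself (and its exact linearity in A0) is fully exercised with
synthetic S tables.

## Threshold selection

The published segmentation idea — sweep a count threshold, count uptake
foci (NUF), normalize, and read a separation threshold off the nNUF-vs-ThI
curve — leaves the selection rule itself open. Two rules are provided:

* **`nnuf_cutoff`** (default for clinical use): the smallest ThI whose nNUF
  reaches a configurable cutoff (default 0.5). On a clean phantom with N
  well-separated foci, any cutoff in ((N−1)/N, 1] recovers exactly the
  planted foci (the *stable range*).
* **`plateau`**: the midpoint of the longest run of constant positive NUF.
  On low-count Poisson images the NUF maximum can migrate into the
  partial-appearance region of the focus cores (or into background noise
  speckle), where the first-crossing rule locks onto a threshold that cuts
  through the foci; the longest constant-NUF plateau instead identifies the
  threshold band over which the partition is stable, and is the default for
  phantom/simulation work.

Ties at the threshold fall to the low compartment ("overcome" = strictly
greater). The body outline is a fractional-Cmax threshold with hole filling
and largest-component selection; on hot-focus phantoms the background can
sit below 1% of Cmax, so the phantom pipeline defaults to body_fraction
1e-3 (a threshold inside the background count distribution clips body-edge
pixels and biases the low-compartment counts).

## Skeletal lesions

Lesion designation is manual: focus labels listed in config are flagged as
skeletal-lesion sources. Their cumulated activity is the counts-weighted
share of Ã_high, and their BM dose contribution is a local beta deposit
(Ã_SL/m_BM_affected)·φ_SL·Δ added explicitly to the three-term MIRD sum.

## Benua comparator

Blood concentration (fraction of A0 per ml) and whole-body retention
(fraction of A0) series are fitted with bounded least squares in linear
space, weighted relatively (σ ∝ y) because retention data carry
multiplicative error and span decades. Initialization is deterministic:
log-linear regression for the mono-fit, curve peeling (tail → slow term,
residual head → fast term) for the bi-fit; no random restarts. Residence
times are the analytic integrals Σ Aᵢ·T½ᵢ/ln 2 of the fitted curves. With
the clinical six-sample schedule (2, 4, 8, 24, 48, 168 h) the fast
half-life rests on the three earliest samples, so at 5% CV its recovery
scatters at the O(10%) level in individual replicates (median well within
15%); this is an identifiability limit of the schedule, not of the fitter.

The blood dose is D = 108·A0[GBq]·τ_blood + (0.0188/wt^(2/3))·A0·τ_WB. The
108 Gy·ml/(GBq·h) constant is the complete local absorption of the mean
187 keV beta electron in 1 ml of blood: 187 keV → 2.9957×10⁻¹¹
Gy·ml/(Bq·s), conventionally rounded to 3×10⁻¹¹, which converts exactly to
108. The placement of wt^(2/3) is implemented as a division (the standard
form of the blood-dose formula); the alternative multiplicative reading
produces physically absurd doses and is rejected. The geometric factor ḡ of
the historical S(blood←body) expression is intentionally not modelled — the
weight-only term replaces it.

## Synthetic phantoms: what they do and do not show

`planardose.phantom` generates a body-shaped elliptical background plus N
compact disc foci with a known activity split; mean counts are
activity × sensitivity × duration, identical in both views, with optional
seeded Poisson noise. Defaults define the package's simulation conditions:
128×64 image, two foci holding 57% of the activity (matching the central
row of the clinical dose-grid convention), 2 GBq at scan time, t̄ = 24 h,
¹⁷⁷Lu kinetics. The noiseless chain
generation → segmentation → scale factors → dose is an exact identity (the
principal correctness surface, verified to ~1e−16 relative); Poisson runs
at 10⁶ total counts recover the activity split to well under 2%.

The phantom does **not** emulate attenuation (an optional exponential
thickness term exists solely to demonstrate the bias it causes), scatter,
collimator response, anatomical texture, or inter-patient kinetic
variability. Passing phantom tests therefore validates the computational
chain, not the clinical accuracy of the fixed-kinetics assumption itself.

## Numerical choices

* Scale factors are computed as S_high = A0·q/(1+q), S_low = A0/(1+q) with
  q = ρ·u_low(t̄)/u_high(t̄); computing S_low by subtraction loses up to
  8 digits when one compartment dominates.
* Cumulated activities use closed forms (T½/ln 2 per term); quadrature
  appears only as a test oracle.
* Fit tolerances are xtol = ftol = gtol = 1e−14 with positivity bounds;
  bi-fit degeneracy (coincident half-lives, e.g. a constant series) is
  reported through an honest `converged` flag.
* Activities are internal MBq; mCi converts with the exact factor 37.
* JSON reports serialize floats at 9 significant digits with sorted keys,
  so identical inputs yield byte-identical reports.
* Mean lives τ = T½/ln 2 are internal only; every user-facing parameter is
  a half-life.

## Known limitations

* Single-view scans are accepted (used as-is, with a warning) since the
  acquisition convention varies; the geometric-mean path assumes the
  posterior view needs a left-right mirror.
* The two-compartment split of a Table-style dose grid partitions the
  *initial* activities (scale factors); `--split-of cumulated` offers the
  alternative reading of partitioning time-integrated activities.
* Orally administered therapies violate the instantaneous-uptake assumption
  (no rising limb in u_high); the resulting overestimate of Ã grows with
  administered activity. A two-exponential uptake model is a possible
  extension, not implemented.
* Only the bone marrow target is exercised; the data model admits other
  regions but none are tested.
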