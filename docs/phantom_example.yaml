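# Annotated synthetic-phantom spec for `planardose simulate`.
# All fields optional; defaults shown produce the package's reference phantom.

image_shape: [128, 64]          # rows x cols; row 0 = cranial
body_center: [63.5, 31.5]       # ellipse centre in pixel coordinates
body_semi_axes: [60.0, 28.0]    # ellipse semi-axes in pixels

# High-uptake foci: [center_row, center_col, radius_px, activity_fraction].
# Fractions sum to <= 1; the remainder is spread uniformly over the body
# ellipse outside the foci (the low-uptake compartment).
foci:
  - [30.0, 31.5, 4.0, 0.35]
  - [75.0, 20.0, 3.0, 0.22]

A_total_MBq_at_scan: 2000.0     # total body activity at scan time
sensitivity_cps_per_MBq: 10.0   # camera sensitivity
acquisition_duration_s: 600.0
noise: poisson                  # "none" writes exact expected mean counts
seed: 0                         # fixed seed => bit-identical scans
attenuation_mu_per_px: 0.0      # demonstration-only bias switch; keep 0

pixel_spacing_mm: [4.0, 4.0]
time_post_admin_h: 24.0         # the single-time-point t̄
radionuclide: Lu-177
patient:
  sex: M
  weight_kg: 73.0
  administered_activity_MBq: 7400.0
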