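"""MIRD bone-marrow dose assembly from S-factor tables.

The absorbed dose to a target region is the sum over source regions of the
cumulated activity times the S factor (absorbed dose rate per unit source
activity, phantom-specific):

    D(rT) = Σ_rS  Ã(rS) · S(rT ← rS)

For the bone marrow (BM) the assembled dose has up to four terms: BM
self-irradiation, cross-dose from the high- and low-uptake compartments, and
an explicit beta add-on from skeletal lesions.  The BM cumulated activity is
not measured directly: following the blood-based scheme, the BM activity
concentration is taken proportional (factor κ) to the low-compartment
concentration.  The self-dose may be computed either through the S-matrix or
from the concentration directly,

    D(BM←BM) = C̃_BM · φ(BM→BM) · Δ,

with φ ≈ 1 for electrons and Δ the mean energy emitted per decay
(147 keV for Lu-177).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from planardose.kinetics import CompartmentKinetics

#: J per eV
EV_TO_J = 1.602e-19
#: default mean energy emitted per decay for Lu-177 electrons, keV
DEFAULT_DELTA_KEV = 147.0
#: S-value unit on disk
S_UNIT = "mGy_per_MBq_h"

_UNIT_TO_MGY_PER_MBQ_H = {
    "mGy_per_MBq_h": 1.0,
    "Gy_per_MBq_h": 1e3,
    "mGy_per_MBq_s": 3600.0,
    "Gy_per_GBq_h": 1.0,  # Gy/GBq == mGy/MBq
}


class SFactorLookupError(KeyError):
    """A (source, target) pair is absent from the S-factor table."""


@dataclass(frozen=True)
class SFactorTable:
    """Per-phantom source→target specific dose rates, mGy/(MBq·h).

    Lookups of missing pairs raise :class:`SFactorLookupError`, never
    returning silent zeros.
    """

    phantom: str  # "M" or "F"
    entries: Mapping[tuple[str, str], float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.phantom not in ("M", "F"):
            raise ValueError("phantom must be 'M' or 'F'")
        for (src, tgt), s in self.entries.items():
            if s < 0:
                raise ValueError(f"negative S value for {src}->{tgt}")

    def s(self, target: str, source: str) -> float:
        """S(target ← source) in mGy/(MBq·h)."""
        try:
            return self.entries[(source, target)]
        except KeyError:
            raise SFactorLookupError(
                f"no S entry for source={source!r} target={target!r} "
                f"in phantom {self.phantom}"
            ) from None


@dataclass(frozen=True)
class PhantomMasses:
    """Region masses (grams) used to convert cumulated activity to concentration."""

    m_BM_g: float
    m_body_g: float
    m_low_g: float

    def __post_init__(self) -> None:
        if min(self.m_BM_g, self.m_body_g, self.m_low_g) <= 0:
            raise ValueError("all masses must be positive")
        if self.m_BM_g > self.m_body_g or self.m_low_g > self.m_body_g:
            raise ValueError("region masses cannot exceed body mass")

    @classmethod
    def from_body(cls, m_BM_g: float, m_body_g: float, m_high_g: float = 0.0):
        """Low-compartment mass defaults to body minus high-compartment mass."""
        return cls(m_BM_g=m_BM_g, m_body_g=m_body_g, m_low_g=m_body_g - m_high_g)


@dataclass(frozen=True)
class DoseReport:
    """BM dose with component breakdown (Gy) and an echo of the inputs."""

    D_BM_total_Gy: float
    components: Mapping[str, float]
    inputs: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - self.D_BM_total_Gy) > 1e-12 * max(abs(total), 1.0):
            raise ValueError("component breakdown does not sum to the total")
        if any(v < 0 for v in self.components.values()):
            raise ValueError("dose components must be non-negative")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": 1,
            "D_BM_total_Gy": float(f"{self.D_BM_total_Gy:.9g}"),
            "components_Gy": {k: float(f"{v:.9g}") for k, v in sorted(self.components.items())},
            "inputs": _jsonable(self.inputs),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return float(f"{obj:.9g}")
    return obj


def load_sfactor_table(path: str | Path, phantom: str | None = None) -> SFactorTable:
    """Load a CSV S-factor table.

    Expected header: ``phantom,source_region,target_region,S_mGy_per_MBq_h``;
    an optional ``unit`` column triggers explicit conversion at load.
    Duplicate (source, target) pairs are rejected.
    """
    df = pd.read_csv(path, comment="#")
    required = {"phantom", "source_region", "target_region", "S_mGy_per_MBq_h"}
    if not required.issubset(df.columns):
        raise ValueError(f"S-factor CSV must have columns {sorted(required)}")
    if phantom is not None:
        df = df[df["phantom"] == phantom]
        if df.empty:
            raise ValueError(f"no rows for phantom {phantom!r} in {path}")
    phantoms = df["phantom"].unique()
    if len(phantoms) != 1:
        raise ValueError(
            "table mixes phantoms; pass phantom='M' or 'F' to select one"
        )
    if "unit" in df.columns:
        factors = df["unit"].map(_UNIT_TO_MGY_PER_MBQ_H)
        if factors.isna().any():
            bad = df.loc[factors.isna(), "unit"].unique()
            raise ValueError(f"unknown S-value units: {list(bad)}")
        df = df.assign(S_mGy_per_MBq_h=df["S_mGy_per_MBq_h"] * factors)
    pairs = list(zip(df["source_region"], df["target_region"]))
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate (source_region, target_region) pairs")
    s_vals = pd.to_numeric(df["S_mGy_per_MBq_h"], errors="raise")
    if (s_vals < 0).any():
        raise ValueError("negative S values")
    return SFactorTable(
        phantom=str(phantoms[0]),
        entries=dict(zip(pairs, s_vals.astype(float))),
        provenance=str(path),
    )


def mird_dose(
    cumulated: Mapping[str, float], sfactors: SFactorTable, target_region: str
) -> float:
    """Σ_S Ã_S · S(target ← S), converting mGy to Gy."""
    total_mGy = 0.0
    for source, a_tilde in cumulated.items():
        total_mGy += a_tilde * sfactors.s(target_region, source)
    return total_mGy * 1e-3


def bm_cumulated_from_low(
    A_tilde_low_MBq_h: float, kappa: float, masses: PhantomMasses
) -> float:
    """Ã_BM from the equal-concentration assumption: κ (Ã_low/m_low) m_BM."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return kappa * (A_tilde_low_MBq_h / masses.m_low_g) * masses.m_BM_g


def bm_self_dose_concentration(
    C_tilde_BM_MBq_h_per_g: float,
    phi: float = 1.0,
    delta_keV: float = DEFAULT_DELTA_KEV,
) -> float:
    """Concentration-based BM self-dose: D = C̃_BM · φ · Δ, in Gy.

    C̃ in MBq·h per gram gives C̃·3.6e9 decays per gram; each decay deposits
    φ·Δ·1.602e-19 J/keV·1e3; one gram is 1e-3 kg.
    """
    if C_tilde_BM_MBq_h_per_g < 0:
        raise ValueError("concentration must be non-negative")
    if not 0 <= phi <= 1:
        raise ValueError("phi must lie in [0, 1]")
    if delta_keV <= 0:
        raise ValueError("delta_keV must be positive")
    decays_per_g = C_tilde_BM_MBq_h_per_g * 1e6 * 3600.0
    joule_per_decay = phi * delta_keV * 1e3 * EV_TO_J
    return decays_per_g * joule_per_decay / 1e-3  # J/kg = Gy


@dataclass(frozen=True)
class DoseConfig:
    """Dosimetry parameters for BM dose assembly.

    ``self_dose_mode`` selects the BM self-irradiation path: ``"s_matrix"``
    uses S(BM←BM); ``"concentration"`` uses the Δ-based formula.  κ is the
    BM-to-low concentration ratio (default 1), surfaced because its numeric
    value depends on the radiopharmaceutical.  The skeletal-lesion term is a
    local beta deposit (Ã_SL/m_BM_affected)·φ_SL·Δ.
    """

    kappa: float = 1.0
    delta_keV: float = DEFAULT_DELTA_KEV
    phi: float = 1.0
    phi_SL: float = 1.0
    self_dose_mode: str = "concentration"
    m_BM_affected_g: float | None = None
    bm_region: str = "red_marrow"
    high_region: str = "high"
    low_region: str = "low"

    def __post_init__(self) -> None:
        if self.self_dose_mode not in ("concentration", "s_matrix"):
            raise ValueError("self_dose_mode must be 'concentration' or 's_matrix'")


def bm_dose(
    cumulated,
    sfactors: SFactorTable | None,
    masses: PhantomMasses,
    config: DoseConfig = DoseConfig(),
    inputs_echo: Mapping | None = None,
) -> DoseReport:
    """Assemble the BM dose from its self, high, low and lesion terms.

    ``cumulated`` is a :class:`~planardose.kinetics.CumulatedActivitySet`.
    Ã_BM, if zero, is derived from Ã_low via the κ concentration assumption.
    The lesion term is included only when Ã_SL > 0.
    """
    a_high = cumulated.A_tilde_high
    a_low = cumulated.A_tilde_low
    a_bm = cumulated.A_tilde_BM
    if a_bm == 0.0:
        a_bm = bm_cumulated_from_low(a_low, config.kappa, masses)
    a_sl = cumulated.A_tilde_SL

    if config.self_dose_mode == "concentration":
        d_self = bm_self_dose_concentration(
            a_bm / masses.m_BM_g, phi=config.phi, delta_keV=config.delta_keV
        )
    else:
        if sfactors is None:
            raise ValueError("s_matrix self-dose mode requires an S-factor table")
        d_self = mird_dose({config.bm_region: a_bm}, sfactors, config.bm_region)

    if sfactors is None:
        raise ValueError("cross-dose terms require an S-factor table")
    d_high = mird_dose({config.high_region: a_high}, sfactors, config.bm_region)
    d_low = mird_dose({config.low_region: a_low}, sfactors, config.bm_region)

    components = {"self": d_self, "from_high": d_high, "from_low": d_low}
    if a_sl > 0:
        m_aff = config.m_BM_affected_g if config.m_BM_affected_g else masses.m_BM_g
        components["from_SL"] = bm_self_dose_concentration(
            a_sl / m_aff, phi=config.phi_SL, delta_keV=config.delta_keV
        )
    echo = dict(inputs_echo or {})
    echo.update(
        {
            "A_tilde_high_MBq_h": a_high,
            "A_tilde_low_MBq_h": a_low,
            "A_tilde_BM_MBq_h": a_bm,
            "A_tilde_SL_MBq_h": a_sl,
            "kappa": config.kappa,
            "delta_keV": config.delta_keV,
            "phi": config.phi,
            "self_dose_mode": config.self_dose_mode,
            "m_BM_g": masses.m_BM_g,
            "m_low_g": masses.m_low_g,
        }
    )
    return DoseReport(
        D_BM_total_Gy=sum(components.values()), components=components, inputs=echo
    )


def dose_table(
    A0_MBq_list,
    split_list,
    kinetics: CompartmentKinetics,
    sfactors_M: SFactorTable | None,
    sfactors_F: SFactorTable | None,
    masses_M: PhantomMasses,
    masses_F: PhantomMasses,
    config: DoseConfig = DoseConfig(),
    split_of: str = "scale_factors",
) -> pd.DataFrame:
    """Clinical-practice dose grid over activities and compartment splits.

    Each cell is the BM dose for an administered activity A0 partitioned
    between the compartments as (high%, low%).  By default the split
    partitions the scale factors (initial compartment activities); pass
    ``split_of="cumulated"`` to partition the time-integrated activities
    instead.  Doses are strictly linear in A0 at a fixed split.
    """
    from planardose.kinetics import (
        CumulatedActivitySet,
        cumulated_activity_high,
        cumulated_activity_low,
    )

    rows = []
    for high_pct, low_pct in split_list:
        if abs(high_pct + low_pct - 100.0) > 1e-9:
            raise ValueError(f"split {high_pct}-{low_pct} does not sum to 100")
        for a0 in A0_MBq_list:
            s_high = a0 * high_pct / 100.0
            s_low = a0 * low_pct / 100.0
            if split_of == "cumulated":
                # interpret the split as the partition of Ã directly
                cum = CumulatedActivitySet(A_tilde_high=s_high, A_tilde_low=s_low)
            else:
                cum = CumulatedActivitySet(
                    A_tilde_high=cumulated_activity_high(s_high, kinetics),
                    A_tilde_low=cumulated_activity_low(s_low, kinetics),
                )
            for phantom, sf, masses in (
                ("M", sfactors_M, masses_M),
                ("F", sfactors_F, masses_F),
            ):
                rep = bm_dose(cum, sf, masses, config)
                rows.append(
                    {
                        "A0_MBq": a0,
                        "split_high_pct": high_pct,
                        "split_low_pct": low_pct,
                        "phantom": phantom,
                        "D_BM_Gy": rep.D_BM_total_Gy,
                    }
                )
    return pd.DataFrame(rows)
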