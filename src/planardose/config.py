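"""Study configuration: schema-validated YAML with full provenance echo.

Unknown keys are rejected so typos never silently fall back to defaults;
every resolved default is echoed into the output report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from planardose.dosimetry import DoseConfig, PhantomMasses
from planardose.kinetics import PRESETS, CompartmentKinetics


class ConfigError(ValueError):
    """The study configuration violates the schema."""


@dataclass(frozen=True)
class SegmentationParams:
    nnuf_cutoff: float = 0.5
    connectivity: int = 8
    body_fraction: float = 0.01
    n_steps: int = 100


@dataclass(frozen=True)
class StudyConfig:
    """Complete resolved configuration of a dosimetry run."""

    kinetics: CompartmentKinetics
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    dose: DoseConfig = field(default_factory=DoseConfig)
    masses: PhantomMasses = field(
        default_factory=lambda: PhantomMasses(m_BM_g=1170.0, m_body_g=73000.0, m_low_g=71000.0)
    )
    sfactor_path: str | None = None
    skeletal_lesion_labels: tuple[int, ...] = ()

    def resolved(self) -> dict:
        """Full provenance: every field (defaults included) as plain data."""
        return {
            "kinetics": asdict(self.kinetics),
            "segmentation": asdict(self.segmentation),
            "dose": asdict(self.dose),
            "masses": asdict(self.masses),
            "sfactor_path": self.sfactor_path,
            "skeletal_lesion_labels": list(self.skeletal_lesion_labels),
        }


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a study YAML.

    Schema (all sections optional except ``kinetics``)::

        kinetics:
          preset: lu177_dotatate        # or explicit half-lives
          t_half_M_h: ...               # overrides applied over the preset
          t_half_S_h: ...
          t_half_F_h: ...
          w_S: ...
          w_F: ...
        segmentation: {nnuf_cutoff, connectivity, body_fraction, n_steps}
        dose: {kappa, delta_keV, phi, phi_SL, self_dose_mode,
               m_BM_affected_g, bm_region, high_region, low_region}
        masses: {m_BM_g, m_body_g, m_low_g}
        sfactors: path/to/sfactors.csv
        skeletal_lesion_labels: [2, 5]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys(
        raw,
        {"kinetics", "segmentation", "dose", "masses", "sfactors", "skeletal_lesion_labels"},
        "study config",
    )
    ksec = dict(raw.get("kinetics") or {})
    _check_keys(
        ksec,
        {"preset", "t_half_M_h", "t_half_S_h", "t_half_F_h", "w_S", "w_F"},
        "kinetics",
    )
    preset = ksec.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown kinetics preset {preset!r}; available: {sorted(PRESETS)}"
            )
        base = asdict(PRESETS[preset])
        base.update(ksec)
        kin = CompartmentKinetics(**base)
    else:
        missing = {"t_half_M_h", "t_half_S_h", "t_half_F_h"} - set(ksec)
        if missing:
            raise ConfigError(
                f"kinetics requires a preset or explicit half-lives; missing {sorted(missing)}"
            )
        kin = CompartmentKinetics(**ksec)

    ssec = dict(raw.get("segmentation") or {})
    _check_keys(ssec, {"nnuf_cutoff", "connectivity", "body_fraction", "n_steps"}, "segmentation")
    dsec = dict(raw.get("dose") or {})
    _check_keys(
        dsec,
        {
            "kappa", "delta_keV", "phi", "phi_SL", "self_dose_mode",
            "m_BM_affected_g", "bm_region", "high_region", "low_region",
        },
        "dose",
    )
    msec = dict(raw.get("masses") or {})
    _check_keys(msec, {"m_BM_g", "m_body_g", "m_low_g"}, "masses")
    try:
        return StudyConfig(
            kinetics=kin,
            segmentation=SegmentationParams(**ssec),
            dose=DoseConfig(**dsec),
            masses=PhantomMasses(**msec) if msec else StudyConfig.__dataclass_fields__[
                "masses"
            ].default_factory(),
            sfactor_path=raw.get("sfactors"),
            skeletal_lesion_labels=tuple(raw.get("skeletal_lesion_labels") or ()),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def parse_activity_mbq(text: str) -> float:
    """Parse an activity with explicit unit suffix into MBq.

    Accepted: ``"7400MBq"``, ``"7.4GBq"``, ``"200mCi"`` (mCi→MBq factor 37
    exactly).  A bare number is an error: units must be explicit.
    """
    t = text.strip()
    for suffix, factor in (("GBq", 1000.0), ("MBq", 1.0), ("mCi", 37.0)):
        if t.endswith(suffix):
            return float(t[: -len(suffix)]) * factor
    raise ConfigError(
        f"activity {text!r} needs an explicit unit suffix (MBq, GBq or mCi)"
    )
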