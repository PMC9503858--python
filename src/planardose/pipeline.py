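"""One-command end-to-end run: scan → segmentation → kinetics → dose report."""

from __future__ import annotations

import logging
from pathlib import Path

from planardose.config import StudyConfig, load_study_config
from planardose.dosimetry import DoseReport, load_sfactor_table
from planardose.imaging import geometric_mean_image, load_planar_scan
from planardose.kinetics import (
    CumulatedActivitySet,
    cumulated_activity_high,
    cumulated_activity_low,
    solve_scale_factors,
)
from planardose.segmentation import segment_scan_image, write_mask_rle_csv

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remedy hint."""

    def __init__(self, stage: str, cause: Exception, hint: str):
        super().__init__(f"[{stage}] {cause} — {hint}")
        self.stage = stage
        self.hint = hint


def run_planar_dosimetry(
    scan_path: str | Path,
    config: StudyConfig | str | Path,
    out_dir: str | Path | None = None,
) -> DoseReport:
    """Execute the full workflow and optionally write all artifacts.

    Writes (when ``out_dir`` is given): the NUF curve CSV, run-length mask
    CSVs, and the JSON dose report with component breakdown and the complete
    resolved configuration.  Deterministic: identical inputs produce
    byte-identical JSON.
    """
    if not isinstance(config, StudyConfig):
        config = load_study_config(config)

    try:
        scan = load_planar_scan(scan_path)
    except Exception as exc:
        raise StageError("imaging", exc, "check scan directory layout and meta.yaml") from exc

    gm = geometric_mean_image(scan)
    try:
        seg, curve = segment_scan_image(
            gm,
            nnuf_cutoff=config.segmentation.nnuf_cutoff,
            connectivity=config.segmentation.connectivity,
            body_fraction=config.segmentation.body_fraction,
            n_steps=config.segmentation.n_steps,
            acquisition_duration_s=scan.acquisition_duration_s,
            skeletal_lesion_labels=list(config.skeletal_lesion_labels),
        )
    except Exception as exc:
        raise StageError(
            "segmentation", exc, "inspect the NUF curve; adjust nnuf_cutoff/body_fraction"
        ) from exc

    try:
        scale = solve_scale_factors(
            scan.patient.administered_activity_MBq,
            seg.rho,
            scan.time_post_admin_h,
            config.kinetics,
        )
        a_sl = 0.0
        if config.skeletal_lesion_labels:
            sl_counts = sum(f.counts for f in seg.foci if f.is_skeletal_lesion)
            if seg.counts_high > 0:
                # lesion share of the high compartment, by counts
                a_sl = cumulated_activity_high(scale, config.kinetics) * (
                    sl_counts / seg.counts_high
                )
        cum = CumulatedActivitySet(
            A_tilde_high=cumulated_activity_high(scale, config.kinetics),
            A_tilde_low=cumulated_activity_low(scale, config.kinetics),
            A_tilde_SL=a_sl,
        )
    except Exception as exc:
        raise StageError("kinetics", exc, "check rho, t_post_admin and half-lives") from exc

    try:
        from planardose.dosimetry import bm_dose

        sfactors = None
        if config.sfactor_path:
            sfactors = load_sfactor_table(config.sfactor_path, phantom=scan.patient.sex)
        report = bm_dose(
            cum,
            sfactors,
            config.masses,
            config.dose,
            inputs_echo={
                "A0_MBq": scan.patient.administered_activity_MBq,
                "rho": seg.rho,
                "t_obs_h": scan.time_post_admin_h,
                "chosen_Cthr": seg.chosen_c_thr,
                "chosen_ThI": seg.chosen_thi,
                "config": config.resolved(),
            },
        )
    except Exception as exc:
        raise StageError("dosimetry", exc, "check the S-factor table covers all regions") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve.to_csv(out / "nuf_curve.csv")
        write_mask_rle_csv(seg.body_mask, out / "body_mask.csv")
        write_mask_rle_csv(seg.high_mask, out / "high_mask.csv")
        report.to_json(out / "dose_report.json")
    return report
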