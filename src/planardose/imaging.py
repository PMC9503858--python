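"""Planar whole-body scan I/O and the conjugate-view geometric-mean image.

A scan is a pair of anterior/posterior count matrices plus acquisition
metadata (pixel spacing, acquisition duration, time post administration,
radionuclide, patient data).  On disk a scan is a directory with
``anterior.csv`` / ``posterior.csv`` (plain comma-separated non-negative
integers, one row per line) and a ``meta.yaml`` sidecar; 16-bit grayscale
image pairs and a minimal DICOM-NM single file are also accepted.

Image coordinates are row-major and 0-based with row 0 = cranial.  The
posterior view is mirrored left-right before the geometric mean (standard
conjugate-view convention); pre-registered data can disable the mirroring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

log = logging.getLogger(__name__)

_REQUIRED_META = (
    "pixel_spacing_mm",
    "acquisition_duration_s",
    "time_post_admin_h",
    "radionuclide",
)


class ScanValidationError(ValueError):
    """A scan or its metadata violates the input contract."""


@dataclass(frozen=True)
class Patient:
    """Minimal patient description needed for dose assembly."""

    sex: str  # "M" or "F"
    weight_kg: float
    administered_activity_MBq: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ScanValidationError(f"patient sex must be 'M' or 'F', got {self.sex!r}")
        if not self.weight_kg > 0:
            raise ScanValidationError("patient weight_kg must be positive")
        if not self.administered_activity_MBq > 0:
            raise ScanValidationError("administered_activity_MBq must be positive")


@dataclass(frozen=True)
class PlanarScan:
    """A registered anterior/posterior planar WBS with acquisition metadata.

    ``posterior`` may be None for single-view acquisitions; the geometric-mean
    stage then uses the anterior view as-is (with a logged warning).
    """

    anterior: np.ndarray
    posterior: np.ndarray | None
    pixel_spacing_mm: tuple[float, float]
    acquisition_duration_s: float
    time_post_admin_h: float
    radionuclide: str
    patient: Patient

    def __post_init__(self) -> None:
        ant = np.asarray(self.anterior)
        object.__setattr__(self, "anterior", ant)
        _check_counts(ant, "anterior")
        if self.posterior is not None:
            post = np.asarray(self.posterior)
            object.__setattr__(self, "posterior", post)
            _check_counts(post, "posterior")
            if post.shape != ant.shape:
                raise ScanValidationError(
                    f"anterior shape {ant.shape} != posterior shape {post.shape}"
                )
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ScanValidationError(f"pixel_spacing_mm must be a positive pair, got {sp}")
        object.__setattr__(self, "pixel_spacing_mm", sp)
        if not self.acquisition_duration_s > 0:
            raise ScanValidationError("acquisition_duration_s must be positive")
        if self.time_post_admin_h < 0:
            raise ScanValidationError("time_post_admin_h must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.anterior.shape


@dataclass(frozen=True)
class CountImage:
    """A non-negative real-valued count image (e.g. the geometric mean)."""

    values: np.ndarray
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ScanValidationError("CountImage values must be 2-D")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ScanValidationError("CountImage values must be finite and non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def c_max(self) -> float:
        """Maximum pixel value, the Cmax anchoring the threshold index."""
        return float(self.values.max())


def _check_counts(arr: np.ndarray, name: str) -> None:
    if arr.ndim != 2:
        raise ScanValidationError(f"{name} view must be a 2-D matrix")
    if not np.all(np.isfinite(arr)):
        raise ScanValidationError(f"{name} view contains non-finite values")
    if np.any(arr < 0):
        raise ScanValidationError(f"{name} view contains negative counts")
    # acquired counts are integers, but synthetic noiseless scans carry
    # exact (non-integer) expected means, so integrality is not enforced here


def geometric_mean_image(scan: PlanarScan, mirror_posterior: bool = True) -> CountImage:
    """Pixelwise geometric mean of the anterior and (mirrored) posterior view.

    GM = sqrt(anterior * posterior'), zero wherever either view is zero.
    With ``mirror_posterior`` the posterior matrix is flipped left-right
    first, the conjugate-view convention.  Single-view scans return the
    anterior view unchanged.
    """
    if scan.posterior is None:
        log.warning("single-view scan: using the anterior view as the count image")
        return CountImage(scan.anterior.astype(float), scan.pixel_spacing_mm)
    post = np.fliplr(scan.posterior) if mirror_posterior else scan.posterior
    gm = np.sqrt(scan.anterior.astype(float) * post.astype(float))
    return CountImage(gm, scan.pixel_spacing_mm)


# ---------------------------------------------------------------------------
# I/O


def _read_csv_matrix(path: Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    return arr


def _patient_from_mapping(m: Mapping) -> Patient:
    try:
        return Patient(
            sex=str(m["sex"]),
            weight_kg=float(m["weight_kg"]),
            administered_activity_MBq=float(m["administered_activity_MBq"]),
        )
    except KeyError as exc:
        raise ScanValidationError(f"patient metadata missing key: {exc}") from exc


def load_planar_scan(
    path: str | Path,
    format_hint: str | None = None,
    metadata_overrides: Mapping | None = None,
) -> PlanarScan:
    """Load a planar scan from a directory (CSV/image pair) or DICOM file.

    Parameters
    ----------
    path
        Scan directory containing ``anterior.csv`` (+ optional
        ``posterior.csv``) or ``anterior.png``/``.tif`` pairs, with a
        ``meta.yaml`` sidecar; or a single DICOM-NM file.
    format_hint
        One of ``"csv"``, ``"image"``, ``"dicom"``; inferred when None.
    metadata_overrides
        Mapping merged over the sidecar metadata (CLI flags win).
    """
    path = Path(path)
    overrides = dict(metadata_overrides or {})
    if not path.exists():
        raise FileNotFoundError(path)

    if format_hint is None:
        if path.is_file() and path.suffix.lower() in (".dcm", ".dicom"):
            format_hint = "dicom"
        elif path.is_dir() and (path / "anterior.csv").exists():
            format_hint = "csv"
        elif path.is_dir():
            format_hint = "image"
        else:
            raise ScanValidationError(f"cannot infer scan format for {path}")

    meta: dict = {}
    if format_hint == "dicom":
        anterior, posterior, meta = _load_dicom(path)
    else:
        sidecar = path / "meta.yaml"
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
        if format_hint == "csv":
            anterior = _read_csv_matrix(path / "anterior.csv")
            pfile = path / "posterior.csv"
            posterior = _read_csv_matrix(pfile) if pfile.exists() else None
        elif format_hint == "image":
            anterior, posterior = _load_image_pair(path)
        else:
            raise ScanValidationError(f"unknown format_hint {format_hint!r}")

    meta.update(overrides)
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ScanValidationError(f"missing required metadata: {missing}")
    if "patient" not in meta:
        raise ScanValidationError("missing required metadata: ['patient']")

    spacing = meta["pixel_spacing_mm"]
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    scan = PlanarScan(
        anterior=anterior,
        posterior=posterior,
        pixel_spacing_mm=tuple(spacing),
        acquisition_duration_s=float(meta["acquisition_duration_s"]),
        time_post_admin_h=float(meta["time_post_admin_h"]),
        radionuclide=str(meta["radionuclide"]),
        patient=_patient_from_mapping(meta["patient"]),
    )
    if meta.get("flip_rows"):
        # configurable axis flip so row 0 is always cranial
        post = None if scan.posterior is None else np.flipud(scan.posterior)
        scan = replace(scan, anterior=np.flipud(scan.anterior), posterior=post)
    return scan


def _load_image_pair(path: Path):
    import imageio.v3 as iio

    ant_file = next((p for ext in (".png", ".tif", ".tiff")
                     for p in [path / f"anterior{ext}"] if p.exists()), None)
    if ant_file is None:
        raise ScanValidationError(f"no anterior image found in {path}")
    anterior = np.asarray(iio.imread(ant_file), dtype=float)
    post_file = ant_file.with_name("posterior" + ant_file.suffix)
    posterior = np.asarray(iio.imread(post_file), dtype=float) if post_file.exists() else None
    return anterior, posterior


def _load_dicom(path: Path):
    """Minimal DICOM-NM ingestion: pixel array + Actual Frame Duration only."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array, dtype=float)
    if arr.ndim == 3 and arr.shape[0] >= 2:
        anterior, posterior = arr[0], arr[1]
    elif arr.ndim == 3:
        anterior, posterior = arr[0], None
    else:
        anterior, posterior = arr, None
    meta: dict = {}
    try:
        # Actual Frame Duration is in ms
        dur_ms = ds.ActualFrameDuration
        meta["acquisition_duration_s"] = float(dur_ms) / 1000.0
    except AttributeError:
        pass
    return anterior, posterior, meta


def write_scan(scan: PlanarScan, path: str | Path) -> Path:
    """Write a scan as a CSV-matrix directory with a ``meta.yaml`` sidecar.

    Round-trips bit-exactly through :func:`load_planar_scan`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    def _fmt(arr: np.ndarray) -> str:
        return "%d" if np.allclose(arr, np.round(arr)) else "%.17g"

    np.savetxt(path / "anterior.csv", scan.anterior, fmt=_fmt(scan.anterior), delimiter=",")
    if scan.posterior is not None:
        np.savetxt(
            path / "posterior.csv", scan.posterior, fmt=_fmt(scan.posterior), delimiter=","
        )
    meta = {
        "pixel_spacing_mm": list(scan.pixel_spacing_mm),
        "acquisition_duration_s": scan.acquisition_duration_s,
        "time_post_admin_h": scan.time_post_admin_h,
        "radionuclide": scan.radionuclide,
        "patient": {
            "sex": scan.patient.sex,
            "weight_kg": scan.patient.weight_kg,
            "administered_activity_MBq": scan.patient.administered_activity_MBq,
        },
    }
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path
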