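"""Automatic two-compartment segmentation of the geometric-mean WBS image.

The body is split into a high-uptake and a low-uptake compartment by a
threshold sweep: for each candidate count threshold Cthr the number of
connected uptake foci (NUF) above the threshold is counted.  The sweep is
parameterised by the threshold index

    ThI = (Cmax - Cthr) / Cmax,

which runs from 0 (threshold at the image maximum) to 1 (threshold zero).
NUF is normalised to its maximum over the sweep (nNUF) and the compartment
threshold is chosen as the smallest ThI at which nNUF reaches a configurable
cutoff — the point where the focus count has grown to a set fraction of its
peak, separating compact high-uptake foci from the merging background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from planardose.imaging import CountImage

#: default fraction of Cmax delimiting the body outline
DEFAULT_BODY_FRACTION = 0.01
#: default nNUF cutoff for compartment-threshold selection
DEFAULT_NNUF_CUTOFF = 0.5
#: default number of equally spaced ThI sweep steps
DEFAULT_N_STEPS = 100


@dataclass(frozen=True)
class NufCurve:
    """The NUF-versus-ThI sweep: (ThI, Cthr, NUF, nNUF) per point."""

    thi: np.ndarray
    c_thr: np.ndarray
    nuf: np.ndarray
    nnuf: np.ndarray

    def __post_init__(self) -> None:
        if len(self.thi) == 0:
            raise ValueError("empty NUF curve")
        if np.any(np.diff(self.thi) <= 0):
            raise ValueError("ThI values must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"ThI": self.thi, "Cthr": self.c_thr, "NUF": self.nuf, "nNUF": self.nnuf}
        ).to_csv(path, index=False)


@dataclass
class Focus:
    """A connected high-uptake component."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    counts: float
    is_skeletal_lesion: bool = False


@dataclass
class SegmentationResult:
    """Two-compartment partition of the body with per-compartment count rates.

    Invariants: high ⊆ body; low = body AND NOT high;
    counts_high + counts_low = total in-body counts.
    """

    body_mask: np.ndarray
    high_mask: np.ndarray
    low_mask: np.ndarray
    chosen_c_thr: float
    chosen_thi: float
    counts_high: float
    counts_low: float
    cps_high: float
    cps_low: float
    foci: list[Focus] = field(default_factory=list)

    @property
    def rho(self) -> float:
        """Measured high/low count-rate ratio (the self-calibration input)."""
        if self.counts_low == 0:
            raise ZeroDivisionError("low compartment has zero counts; rho undefined")
        return self.counts_high / self.counts_low


def threshold_index(c_thr: float, c_max: float) -> float:
    """ThI = (Cmax - Cthr)/Cmax, in [0, 1]."""
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    if not 0 <= c_thr <= c_max:
        raise ValueError(f"c_thr must lie in [0, {c_max}], got {c_thr}")
    return (c_max - c_thr) / c_max


def threshold_from_index(thi: float, c_max: float) -> float:
    """Invert the threshold index: Cthr = Cmax (1 - ThI)."""
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    if not 0 <= thi <= 1:
        raise ValueError(f"ThI must lie in [0, 1], got {thi}")
    return c_max * (1.0 - thi)


def _as_values(image: CountImage | np.ndarray) -> np.ndarray:
    return image.values if isinstance(image, CountImage) else np.asarray(image, dtype=float)


def count_uptake_foci(
    image: CountImage | np.ndarray, c_thr: float, connectivity: int = 8
) -> int:
    """Number of connected components of {pixels with counts > c_thr}."""
    vals = _as_values(image)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = vals > c_thr
    # skimage connectivity: 1 = edges (4-neighbour), 2 = edges+corners (8)
    _, n = measure.label(mask, connectivity=1 if connectivity == 4 else 2, return_num=True)
    return int(n)


def nuf_curve(
    image: CountImage | np.ndarray,
    n_steps: int = DEFAULT_N_STEPS,
    connectivity: int = 8,
) -> NufCurve:
    """Sweep Cthr over ``n_steps`` equally spaced ThI values in [0, 1].

    Each point carries the focus count NUF and its normalisation
    nNUF = NUF / max(NUF); max(nNUF) is exactly 1.
    """
    vals = _as_values(image)
    c_max = float(vals.max())
    if c_max <= 0:
        raise ValueError("image must have a positive maximum")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    thi = np.linspace(0.0, 1.0, n_steps)
    c_thr = c_max * (1.0 - thi)
    nuf = np.array([count_uptake_foci(vals, c, connectivity) for c in c_thr])
    peak = nuf.max()
    if peak == 0:
        raise ValueError("no uptake foci at any threshold")
    return NufCurve(thi=thi, c_thr=c_thr, nuf=nuf, nnuf=nuf / peak)


def select_segmentation_threshold(
    curve: NufCurve, nnuf_cutoff: float = DEFAULT_NNUF_CUTOFF
) -> tuple[float, float]:
    """Smallest ThI at which nNUF >= cutoff; returns (Cthr, ThI)."""
    if not 0 < nnuf_cutoff <= 1:
        raise ValueError("nnuf_cutoff must lie in (0, 1]")
    idx = np.nonzero(curve.nnuf >= nnuf_cutoff)[0]
    # nnuf reaches 1 somewhere by construction, so idx is never empty
    i = int(idx[0])
    return float(curve.c_thr[i]), float(curve.thi[i])


def select_plateau_threshold(curve: NufCurve) -> tuple[float, float]:
    """Threshold at the midpoint of the longest stable NUF plateau.

    The sweep's focus count is piecewise constant; the longest run of
    consecutive points with an identical positive NUF is the threshold range
    over which the two-compartment partition is stable (between the focus
    levels above and the background below).  Returns (Cthr, ThI) at the
    middle of that run.  This is the robust companion to the first-crossing
    nNUF-cutoff rule, which on low-count images can lock onto the partial
    appearance of focus cores or onto noise speckle instead of the plateau.
    """
    nuf = curve.nuf
    best_start, best_len = 0, 0
    i = 0
    while i < len(nuf):
        j = i
        while j < len(nuf) and nuf[j] == nuf[i]:
            j += 1
        if nuf[i] >= 1 and j - i > best_len:
            best_start, best_len = i, j - i
        i = j
    if best_len == 0:
        raise ValueError("no positive-NUF plateau in the curve")
    mid = best_start + best_len // 2
    return float(curve.c_thr[mid]), float(curve.thi[mid])


def body_mask(
    image: CountImage | np.ndarray, body_fraction: float = DEFAULT_BODY_FRACTION
) -> np.ndarray:
    """Body outline: counts > fraction*Cmax, hole-filled, largest component."""
    vals = _as_values(image)
    c_max = float(vals.max())
    if c_max <= 0:
        raise ValueError("image must have a positive maximum")
    if not 0 <= body_fraction < 1:
        raise ValueError("body_fraction must lie in [0, 1)")
    mask = vals > body_fraction * c_max
    if not mask.any():
        raise ValueError("empty body mask")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def segment_compartments(
    image: CountImage | np.ndarray,
    chosen_c_thr: float,
    body: np.ndarray | None = None,
    connectivity: int = 8,
    acquisition_duration_s: float | None = None,
    chosen_thi: float | None = None,
    skeletal_lesion_labels: list[int] | None = None,
) -> SegmentationResult:
    """Partition the body into high (> Cthr, strict) and low compartments.

    Pixels whose counts tie the threshold fall to the low compartment.
    ``skeletal_lesion_labels`` marks focus labels as skeletal-lesion sources
    (manual designation; there is no automatic rule).
    """
    vals = _as_values(image)
    if body is None:
        body = body_mask(vals)
    high = vals > chosen_c_thr
    if np.any(high & ~body):
        raise ValueError("high-uptake pixels found outside the body mask")
    low = body & ~high
    counts_high = float(vals[high].sum())
    counts_low = float(vals[low].sum())
    dur = acquisition_duration_s
    cps_high = counts_high / dur if dur else counts_high
    cps_low = counts_low / dur if dur else counts_low

    labels = measure.label(high, connectivity=1 if connectivity == 4 else 2)
    sl = set(skeletal_lesion_labels or [])
    foci = []
    for lab in range(1, labels.max() + 1):
        pix = np.argwhere(labels == lab)
        foci.append(
            Focus(
                label=lab,
                pixels=pix,
                counts=float(vals[labels == lab].sum()),
                is_skeletal_lesion=lab in sl,
            )
        )
    c_max = float(vals.max())
    return SegmentationResult(
        body_mask=body,
        high_mask=high,
        low_mask=low,
        chosen_c_thr=float(chosen_c_thr),
        chosen_thi=(
            chosen_thi if chosen_thi is not None else threshold_index(min(chosen_c_thr, c_max), c_max)
        ),
        counts_high=counts_high,
        counts_low=counts_low,
        cps_high=cps_high,
        cps_low=cps_low,
        foci=foci,
    )


def segment_scan_image(
    image: CountImage | np.ndarray,
    nnuf_cutoff: float = DEFAULT_NNUF_CUTOFF,
    connectivity: int = 8,
    body_fraction: float = DEFAULT_BODY_FRACTION,
    n_steps: int = DEFAULT_N_STEPS,
    acquisition_duration_s: float | None = None,
    skeletal_lesion_labels: list[int] | None = None,
    threshold_method: str = "nnuf_cutoff",
) -> tuple[SegmentationResult, NufCurve]:
    """Full automatic segmentation: sweep, select threshold, partition.

    ``threshold_method`` is ``"nnuf_cutoff"`` (first ThI whose nNUF reaches
    the cutoff) or ``"plateau"`` (midpoint of the longest stable NUF run).
    """
    curve = nuf_curve(image, n_steps=n_steps, connectivity=connectivity)
    if threshold_method == "plateau":
        c_thr, thi = select_plateau_threshold(curve)
    elif threshold_method == "nnuf_cutoff":
        c_thr, thi = select_segmentation_threshold(curve, nnuf_cutoff)
    else:
        raise ValueError("threshold_method must be 'nnuf_cutoff' or 'plateau'")
    body = body_mask(image, body_fraction)
    result = segment_compartments(
        image,
        c_thr,
        body=body,
        connectivity=connectivity,
        acquisition_duration_s=acquisition_duration_s,
        chosen_thi=thi,
        skeletal_lesion_labels=skeletal_lesion_labels,
    )
    return result, curve


def write_mask_rle_csv(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as run-length CSV (row, col_start, run_length)."""
    rows = []
    for r in range(mask.shape[0]):
        row = mask[r]
        diff = np.diff(np.concatenate(([0], row.astype(int), [0])))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            rows.append((r, s, e - s))
    with open(path, "w") as fh:
        fh.write("row,col_start,run_length\n")
        fh.write(f"# shape={mask.shape[0]}x{mask.shape[1]}\n")
        for r, s, n in rows:
            fh.write(f"{r},{s},{n}\n")
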