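"""Bone / marrow / air segmentation and air-bubble volumetry.

Two entry points: :func:`binarize_local` (sliding-window Otsu, robust to
smooth shading gradients) and :func:`segment_three_phase` (3-class Otsu
for CT-like images where air, marrow and bone form distinct intensity
modes).  :func:`quantify_bubbles` turns the AIR phase into absolute and
relative bubble volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Union

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label

from .core_io import GrayImage, Modality, ROI, require_analysis_size

__all__ = [
    "Phase",
    "PhaseMask",
    "BubbleReport",
    "binarize_local",
    "segment_three_phase",
    "quantify_bubbles",
    "bubble_report_from_volumes",
]


class Phase(IntEnum):
    OUTSIDE = 0
    BONE = 1
    MARROW = 2
    AIR = 3


@dataclass
class PhaseMask:
    """Per-pixel phase labels with the spacing of the source image."""

    labels: np.ndarray
    spacing_x: float
    spacing_y: float
    slice_thickness: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        valid = set(int(p) for p in Phase)
        found = set(np.unique(labels).tolist())
        if not found <= valid:
            raise ValueError(f"invalid phase labels {sorted(found - valid)}")
        self.labels = labels.astype(np.uint8)
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_x * self.spacing_y

    def phase_pixels(self, phase: Phase) -> np.ndarray:
        return self.labels == int(phase)

    def counts(self) -> dict:
        return {p.name: int(np.count_nonzero(self.labels == int(p))) for p in Phase}


@dataclass
class BubbleReport:
    """Absolute and relative air-bubble volume for one mask.

    ``abv_abs`` is mm³ when a slice thickness is available, otherwise the
    in-plane area in mm² (``is_area`` flags this degenerate unit).
    """

    abv_abs: float
    abv_rel_initial: Optional[float] = None  # % of a reference initial volume
    abv_rel_marrow: Optional[float] = None   # % of total marrow volume
    is_area: bool = False

    def __post_init__(self) -> None:
        if self.abv_abs < 0:
            raise ValueError("abv_abs must be >= 0")
        if self.abv_rel_marrow is not None and self.abv_rel_marrow > 100 + 1e-9:
            raise ValueError("abv_rel_marrow cannot exceed 100%")


def _resolve_polarity(image: GrayImage, polarity: Optional[str]) -> str:
    if polarity is not None:
        if polarity not in ("bone-bright", "bone-dark"):
            raise ValueError(f"unknown polarity {polarity!r}")
        return polarity
    if image.modality == Modality.CT_LIKE:
        return "bone-bright"
    if image.modality == Modality.MR_LIKE:
        return "bone-dark"
    raise ValueError("polarity must be given for UNKNOWN-modality images")


def binarize_local(
    image: GrayImage,
    window: Optional[int] = None,
    polarity: Optional[str] = None,
    roi: Optional[ROI] = None,
) -> PhaseMask:
    """Binarize bone vs marrow with a sliding-window Otsu threshold.

    The image is tiled into ``window``-sized blocks, Otsu's threshold is
    computed per tile (tiles with too little contrast fall back to the
    global Otsu threshold) and the per-tile thresholds are bilinearly
    interpolated to a smooth threshold surface.  ``polarity`` selects
    whether bone is the bright or the dark phase; it defaults from the
    image modality.  Deterministic, and invariant to global affine
    intensity rescaling a*I + b with a > 0.
    """
    require_analysis_size(image)
    h, w = image.shape
    if window is None:
        window = int(np.clip(min(h, w) // 4, 8, min(h, w)))
    if window < 8 or window > min(h, w):
        raise ValueError(f"window {window} outside valid range [8, {min(h, w)}]")
    polarity = _resolve_polarity(image, polarity)

    work = np.asarray(image.pixels, dtype=np.float64)
    if polarity == "bone-dark":
        work = -work

    labels = np.full((h, w), int(Phase.MARROW), dtype=np.uint8)
    roi_mask = None
    if roi is not None:
        roi.check_against(image)
        roi_mask = roi.mask
        labels[~roi_mask] = int(Phase.OUTSIDE)

    if np.ptp(work) == 0:
        warnings.warn("constant image: threshold undefined, labelling all MARROW")
        return PhaseMask(labels, image.spacing_x, image.spacing_y,
                         image.slice_thickness)

    thr = _local_otsu_surface(work, window)
    bone = work > thr
    if roi_mask is not None:
        bone &= roi_mask
    labels[bone] = int(Phase.BONE)
    return PhaseMask(labels, image.spacing_x, image.spacing_y,
                     image.slice_thickness)


def _safe_otsu(values: np.ndarray, fallback: float) -> float:
    if np.ptp(values) == 0:
        return fallback
    try:
        return float(threshold_otsu(values, nbins=256))
    except ValueError:
        return fallback


def _local_otsu_surface(work: np.ndarray, window: int) -> np.ndarray:
    h, w = work.shape
    global_thr = _safe_otsu(work, np.inf)
    ny, nx = max(1, round(h / window)), max(1, round(w / window))
    r_edges = np.linspace(0, h, ny + 1).astype(int)
    c_edges = np.linspace(0, w, nx + 1).astype(int)
    centers_r = (r_edges[:-1] + r_edges[1:]) / 2.0 - 0.5
    centers_c = (c_edges[:-1] + c_edges[1:]) / 2.0 - 0.5
    grid = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            tile = work[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            # near-constant tiles (pure bone or pure marrow) would place a
            # threshold inside noise; defer to the global threshold there
            if np.ptp(tile) < 0.05 * np.ptp(work):
                grid[i, j] = global_thr
            else:
                grid[i, j] = _safe_otsu(tile, global_thr)
    if ny == 1 and nx == 1:
        return np.full((h, w), grid[0, 0])
    interp = RegularGridInterpolator(
        (centers_r, centers_c), grid, bounds_error=False, fill_value=None
    )
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    np.clip(pts[:, 0], centers_r[0], centers_r[-1], out=pts[:, 0])
    np.clip(pts[:, 1], centers_c[0], centers_c[-1], out=pts[:, 1])
    return interp(pts).reshape(h, w)


def _min_error_threshold(values: np.ndarray, nbins: int = 256):
    """Kittler-Illingworth minimum-error threshold for the air/marrow split.

    Air bubbles can be a tiny fraction of the pixels; Otsu-family criteria
    cannot see such an imbalanced valley, while the minimum-error criterion
    models the two classes as Gaussians with explicit priors.  The search
    is restricted to below the dominant mode (air is darker than marrow by
    premise, and partial-volume shoulders above the marrow peak must not
    capture the threshold).
    """
    if np.ptp(values) == 0:
        return None
    counts, edges = np.histogram(values, bins=nbins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    if peak < 2:
        return None
    w1 = np.cumsum(p)
    w2 = 1.0 - w1
    mu = np.cumsum(p * centers)
    mu2c = np.cumsum(p * centers**2)
    bin_var = (0.5 * (edges[1] - edges[0])) ** 2  # variance floor
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = mu / w1
        m2 = (mu[-1] - mu) / w2
        v1 = np.maximum(mu2c / w1 - m1**2, bin_var)
        v2 = np.maximum((mu2c[-1] - mu2c) / w2 - m2**2, bin_var)
        crit = (w1 * np.log(v1) / 2 + w2 * np.log(v2) / 2
                - w1 * np.log(w1) - w2 * np.log(w2))
    crit = np.where(np.isfinite(crit), crit, np.inf)
    crit[peak:] = np.inf
    crit[w1 <= 0] = np.inf
    k = int(np.argmin(crit))
    if not np.isfinite(crit[k]):
        return None
    return float(edges[k + 1])


def _modes_separated(values: np.ndarray, threshold: float,
                     min_ratio: float = 3.5) -> bool:
    """True when the classes split at ``threshold`` look like two modes.

    A single Gaussian split anywhere yields a mean gap of ~2.7x the class
    spread; genuinely bimodal data well exceeds ``min_ratio``.
    """
    lo = values[values <= threshold]
    hi = values[values > threshold]
    if lo.size < 4 or hi.size < 4:
        return False
    spread = max(lo.std(), hi.std(), 1e-12 * max(abs(float(values.mean())), 1.0))
    return (hi.mean() - lo.mean()) / spread > min_ratio


def segment_three_phase(
    image: GrayImage,
    min_air_px: int = 4,
    roi: Optional[ROI] = None,
) -> PhaseMask:
    """Split a CT-like image into AIR (darkest), MARROW and BONE (brightest).

    Uses 3-class Otsu; if fewer than three intensity modes are
    distinguishable it falls back to :func:`binarize_local` with an empty
    AIR phase and emits a warning.  Connected AIR components smaller than
    ``min_air_px`` pixels are merged back into MARROW.
    """
    if image.modality != Modality.CT_LIKE:
        raise ValueError("three-phase segmentation requires a CT_LIKE image")
    require_analysis_size(image)
    work = np.asarray(image.pixels, dtype=np.float64)
    try:
        _, hi = threshold_multiotsu(work, classes=3, nbins=256)
    except ValueError:
        warnings.warn(
            "fewer than three distinguishable intensity modes; "
            "falling back to two-phase local threshold (AIR empty)"
        )
        return binarize_local(image, polarity="bone-bright", roi=roi)

    labels = np.full(image.shape, int(Phase.MARROW), dtype=np.uint8)
    labels[work > hi] = int(Phase.BONE)
    # air splits off the sub-bone intensities; plain Otsu is unreliable
    # when air is a tiny class, so use valley emphasis + a separation test
    rest = work[work <= hi]
    lo = _min_error_threshold(rest)
    if lo is not None and _modes_separated(rest, lo):
        labels[work <= lo] = int(Phase.AIR)
    else:
        warnings.warn("no distinguishable air mode below the bone threshold; "
                      "AIR left empty")
    if roi is not None:
        roi.check_against(image)
        labels[~roi.mask] = int(Phase.OUTSIDE)

    if min_air_px > 0:
        air = labels == int(Phase.AIR)
        comps = cc_label(air, connectivity=2)
        for cid, size in zip(*np.unique(comps[comps > 0], return_counts=True)):
            if size < min_air_px:
                labels[comps == cid] = int(Phase.MARROW)
    return PhaseMask(labels, image.spacing_x, image.spacing_y,
                     image.slice_thickness)


def quantify_bubbles(
    mask: PhaseMask,
    slice_thickness: Optional[float] = None,
    reference_initial: Optional[float] = None,
    marrow_total: Optional[float] = None,
) -> BubbleReport:
    """Air-bubble volumetry from a phase mask.

    ``abv_abs`` is AIR pixel count x pixel area x slice thickness (mm³);
    without a thickness the in-plane area (mm²) is reported and flagged.
    ``reference_initial`` is a pre-treatment air volume in the same units;
    ``marrow_total`` defaults to the AIR+MARROW volume of this mask.
    """
    if slice_thickness is None:
        slice_thickness = mask.slice_thickness or None
    air_px = int(np.count_nonzero(mask.labels == int(Phase.AIR)))
    marrow_px = int(np.count_nonzero(mask.labels == int(Phase.MARROW)))
    area = air_px * mask.pixel_area_mm2
    if slice_thickness:
        abv_abs = area * slice_thickness
        marrow_default = (air_px + marrow_px) * mask.pixel_area_mm2 * slice_thickness
        is_area = False
    else:
        abv_abs = area
        marrow_default = (air_px + marrow_px) * mask.pixel_area_mm2
        is_area = True
    if marrow_total is None:
        marrow_total = marrow_default
    return bubble_report_from_volumes(
        abv_abs, reference_initial=reference_initial,
        marrow_total=marrow_total, is_area=is_area,
    )


def bubble_report_from_volumes(
    abv_abs: float,
    reference_initial: Optional[float] = None,
    marrow_total: Optional[float] = None,
    is_area: bool = False,
) -> BubbleReport:
    """Relative bubble volumes from already-measured absolute volumes."""
    if abv_abs < 0:
        raise ValueError("abv_abs must be >= 0")
    rel_initial = None
    if reference_initial is not None:
        if reference_initial <= 0:
            raise ValueError("reference_initial must be > 0")
        rel_initial = 100.0 * abv_abs / reference_initial
    rel_marrow = None
    if marrow_total is not None:
        if marrow_total <= 0:
            if abv_abs == 0:
                rel_marrow = 0.0
            else:
                raise ValueError("marrow_total must be > 0")
        else:
            rel_marrow = 100.0 * abv_abs / marrow_total
    return BubbleReport(abv_abs, rel_initial, rel_marrow, is_area)
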