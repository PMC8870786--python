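"""Aperture-map histomorphometry: BVF, Tb.Th, Tb.Sp, Tb.N.

The aperture map assigns to every pixel of a phase the diameter of the
largest disk that is fully contained in that phase and covers the pixel
(a 2D local-thickness map).  Diameters are real-valued (sub-pixel):
candidate disk centres live on the half-pixel lattice (pixel centres,
edge midpoints and corners), and the maximal radius at a centre is the
Euclidean distance to the out-of-phase region with pixels modelled as
closed unit squares — the disk may not cross the physical phase
boundary, which runs halfway between pixel centres.  A disk covers a
pixel when the pixel centre lies inside the closed disk.  Under this
convention a straight bar of width w pixels measures exactly w*spacing
for both parities of w (for even w the optimal disk centre sits between
two pixel rows), and no disk ever covers an out-of-phase pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt

from .core_io import ROI
from .segmentation import Phase, PhaseMask

__all__ = [
    "ApertureMap",
    "MorphometryReport",
    "compute_aperture_map",
    "compute_bvf",
    "summarize_thickness",
    "compute_tbn",
    "aperture_histogram",
]


@dataclass
class ApertureMap:
    """Per-pixel maximal-inclusion-disk diameters in mm (0 off-phase)."""

    diameters: np.ndarray
    phase: Phase
    spacing: float  # isotropic mm/pixel

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=np.float64)
        if np.any(self.diameters < 0):
            raise ValueError("aperture diameters must be >= 0")

    @property
    def positive(self) -> np.ndarray:
        return self.diameters[self.diameters > 0]


@dataclass
class MorphometryReport:
    """Scalar microarchitecture metrics for one image/ROI.

    Lengths in mm, angles in degrees; ``tbors_deg`` is ``None`` when no
    secondary orientation was detected (serialized as ``ND``).
    ``tbn_per_mm`` is always BVF / Tb.Th and is recomputed when omitted.
    """

    bvf: float
    tbth_mm: Optional[float] = None
    tbsp_mm: Optional[float] = None
    tbn_per_mm: Optional[float] = None
    tbth_sd_mm: Optional[float] = None
    tbsp_sd_mm: Optional[float] = None
    tborp_deg: Optional[float] = None
    tborp_sd_deg: Optional[float] = None
    tbors_deg: Optional[float] = None
    tbors_diff_deg: Optional[float] = None
    tbint_deg: Optional[float] = None
    abv_mm3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bvf is None or not (0.0 <= self.bvf <= 1.0):
            raise ValueError("bvf is mandatory and must lie in [0, 1]")
        if self.tbn_per_mm is None and self.tbth_mm:
            self.tbn_per_mm = compute_tbn(self.bvf, self.tbth_mm)


def _isotropic_spacing(mask: PhaseMask) -> float:
    sx, sy = mask.spacing_x, mask.spacing_y
    if abs(sx - sy) > 1e-6 * max(sx, sy):
        raise ValueError(
            f"aperture map requires isotropic in-plane spacing, got {(sy, sx)}"
        )
    return sx


def compute_aperture_map(
    mask: Union[PhaseMask, np.ndarray],
    phase: Phase = Phase.BONE,
    spacing: Optional[float] = None,
    periodic: bool = False,
) -> ApertureMap:
    """Maximal-inclusion-disk diameter for every pixel of ``phase``.

    Accepts a :class:`PhaseMask` or a plain boolean array (then
    ``spacing`` is required, defaulting to 1.0).  Pixels outside the image
    do not bound disks: the phase is implicitly continued past the border,
    so a bar touching the frame keeps its nominal thickness.  With
    ``periodic=True`` the mask is treated as one period of a tiling
    (computed on a 3x3 tile, centre crop), which removes border effects
    for exactly periodic structures.
    """
    if isinstance(mask, PhaseMask):
        target = mask.phase_pixels(phase)
        spacing = _isotropic_spacing(mask)
    else:
        target = np.asarray(mask, dtype=bool)
        spacing = 1.0 if spacing is None else float(spacing)
    if not target.any():
        raise ValueError(f"phase {phase.name} is empty")
    if periodic:
        h, w = target.shape
        tiled = compute_aperture_map(np.tile(target, (3, 3)), phase, spacing)
        return ApertureMap(tiled.diameters[h:2 * h, w:2 * w].copy(),
                           phase, spacing)

    if target.all():
        # no background anywhere: aperture unbounded, cap at image diagonal
        diag = float(np.hypot(*target.shape)) * spacing
        return ApertureMap(np.full(target.shape, diag), phase, spacing)

    h, w = target.shape
    # node (i, j) of the half-grid sits at pixel coordinates (i/2, j/2).
    # The out-of-phase region is the union of unit squares around
    # out-of-phase centres; square corners and edge feet both lie on the
    # half-grid, so an EDT against the 3x3-node-dilated background gives
    # the exact point-to-region distance at every node.
    features = np.zeros((2 * h - 1, 2 * w - 1), dtype=bool)
    features[::2, ::2] = ~target
    features |= binary_dilation(features, structure=np.ones((3, 3), dtype=bool))
    node_radius = distance_transform_edt(~features, sampling=(0.5, 0.5))

    diam = np.zeros((h, w))
    ni, nj = np.nonzero(node_radius > 0)
    # paint in ascending radius order so larger disks win via plain writes
    order = np.argsort(node_radius[ni, nj], kind="stable")
    ni, nj = ni[order], nj[order]
    radii = node_radius[ni, nj]
    for i, j, rpx in zip(ni, nj, radii):
        r0, c0 = i / 2.0, j / 2.0
        rlo, rhi = int(np.ceil(r0 - rpx)), int(np.floor(r0 + rpx))
        clo, chi = int(np.ceil(c0 - rpx)), int(np.floor(c0 + rpx))
        rsl = slice(max(0, rlo), min(h, rhi + 1))
        csl = slice(max(0, clo), min(w, chi + 1))
        if rsl.start >= rsl.stop or csl.start >= csl.stop:
            continue
        dr = np.arange(rsl.start, rsl.stop) - r0
        dc = np.arange(csl.start, csl.stop) - c0
        covered = dr[:, None] ** 2 + dc[None, :] ** 2 <= rpx * rpx + 1e-9
        block = diam[rsl, csl]
        d = 2.0 * rpx
        block[covered & (block < d)] = d
    return ApertureMap(diam * spacing, phase, spacing)


def compute_bvf(mask: PhaseMask, roi: Optional[ROI] = None) -> float:
    """Bone pixels over all in-ROI pixels (BONE + MARROW + AIR)."""
    labels = mask.labels
    if roi is not None:
        if roi.mask.shape != labels.shape:
            raise ValueError("ROI shape mismatch")
        labels = np.where(roi.mask, labels, int(Phase.OUTSIDE))
    inside = labels != int(Phase.OUTSIDE)
    total = int(np.count_nonzero(inside))
    if total == 0:
        raise ValueError("empty ROI")
    bone = int(np.count_nonzero(labels == int(Phase.BONE)))
    return bone / total


def summarize_thickness(ap: ApertureMap) -> float:
    """Pixel-weighted mean aperture diameter (mm) over the target phase."""
    values = ap.positive
    if values.size == 0:
        raise ValueError("empty aperture map")
    return float(values.mean())


def aperture_histogram(ap: ApertureMap, bin_width_px: float = 1.0):
    """(bin_centers_mm, fraction) histogram of the aperture distribution."""
    values = ap.positive
    if values.size == 0:
        raise ValueError("empty aperture map")
    width = bin_width_px * ap.spacing
    nbins = max(1, int(np.ceil(values.max() / width)))
    counts, edges = np.histogram(values, bins=nbins, range=(0, nbins * width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def compute_tbn(bvf: float, tbth: float) -> float:
    """Trabecular number: BVF / Tb.Th, in 1/mm."""
    if bvf == 0:
        return 0.0
    if tbth is None or tbth <= 0:
        raise ValueError("tbth must be > 0")
    return bvf / tbth
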