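"""Synthetic trabecular phantoms with exact ground truth.

Bone is a union of straight struts: a principal family whose per-strut
orientation is drawn from Normal(theta_p, sigma_p²) and an optional
secondary family at ``theta_p + secondary_offset``.  Struts are
anti-aliased bands rasterized on the pixel grid and thresholded at 0.5
coverage, which keeps sub-pixel geometry controllable; intensities are
assigned by modality (CT-like: bone bright, marrow dark, air darkest;
MR-like: bone dark, marrow bright, air dark), then blurred by a Gaussian
PSF and corrupted with additive noise.  The emitted ground truth is
bookkept directly from the rasterized mask, independent of every
estimator in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from ._angles import axial_difference
from .core_io import GrayImage, Modality
from .segmentation import Phase, PhaseMask

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "insert_bubbles"]

# epsilon (px) nudging band edges off pixel centres: closed-interval
# thresholding then behaves half-open, so a width-w band always covers
# exactly w pixel rows regardless of parity
_EDGE_EPS = 1e-6


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic trabecular slice."""

    width: int = 256
    height: int = 256
    spacing: float = 0.051            # mm/pixel, isotropic
    theta_p: float = 67.0             # principal strut orientation, deg in [0,180)
    sigma_p: float = 0.0              # per-strut angular jitter SD, deg
    secondary_offset: float = 90.0
    secondary_fraction: float = 0.0   # target pixel-mass weight of 2nd family
    strut_thickness: float = 0.15     # mm
    strut_spacing: float = 0.6        # mm, marrow gap between strut edges
    bone_level: Optional[float] = None
    marrow_level: Optional[float] = None
    air_level: Optional[float] = None
    noise_sd: float = 0.0
    psf_sigma: float = 0.0            # mm
    bubbles: Tuple[Tuple[Tuple[float, float], float], ...] = ()
    # each bubble: ((row_px, col_px), radius_mm)
    slice_thickness: float = 0.0      # mm; 0 = pure-2D phantom
    modality: Modality = Modality.CT_LIKE
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.width < 8 or self.height < 8:
            raise ValueError("phantom must be at least 8x8 pixels")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not (0 <= self.strut_thickness < self.strut_spacing):
            raise ValueError("require 0 <= strut_thickness < strut_spacing")
        if self.sigma_p < 0 or self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("SDs must be >= 0")
        if not (0.0 <= self.secondary_fraction <= 1.0):
            raise ValueError("secondary_fraction must lie in [0, 1]")
        half_extent = 0.5 * min(self.width, self.height) * self.spacing
        for (_, radius) in self.bubbles:
            if radius <= 0 or radius >= half_extent:
                raise ValueError(
                    f"bubble radius {radius} mm outside (0, {half_extent}) mm"
                )
        levels = _default_levels(self.modality)
        if self.bone_level is None:
            self.bone_level = levels[0]
        if self.marrow_level is None:
            self.marrow_level = levels[1]
        if self.air_level is None:
            self.air_level = levels[2]

    @property
    def period_px(self) -> float:
        return (self.strut_thickness + self.strut_spacing) / self.spacing

    @property
    def thickness_px(self) -> float:
        return self.strut_thickness / self.spacing

    def to_json(self) -> str:
        d = asdict(self)
        d["modality"] = self.modality.value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        if "bubbles" in d:
            d["bubbles"] = tuple(
                (tuple(centre), radius) for centre, radius in d["bubbles"]
            )
        return cls(**d)


def _default_levels(modality: Modality) -> Tuple[float, float, float]:
    if modality == Modality.MR_LIKE:
        return (30.0, 200.0, 10.0)  # bone dark, marrow bright, air dark
    return (200.0, 50.0, 10.0)      # bone bright, marrow dark, air darkest


@dataclass
class GroundTruth:
    """Exact mask-derived metrics of a generated phantom."""

    mask: PhaseMask
    bvf_true: float
    tbth_true: float                  # nominal strut thickness, mm
    tbsp_true: float                  # nominal strut gap, mm
    theta_p_true: float
    sigma_p_true: float
    tbint_true: float                 # deg, from the per-pixel truth angles
    bubble_area_true: float = 0.0     # mm²
    bubble_volume_true: float = 0.0   # mm³ (0 when slice_thickness is 0)
    angle_map: Optional[np.ndarray] = None  # per-pixel truth angle (NaN off-bone)
    strut_angles: Tuple[float, ...] = ()

    def summary(self) -> dict:
        return {
            "bvf_true": self.bvf_true,
            "tbth_true_mm": self.tbth_true,
            "tbsp_true_mm": self.tbsp_true,
            "theta_p_true_deg": self.theta_p_true,
            "sigma_p_true_deg": self.sigma_p_true,
            "tbint_true_deg": self.tbint_true,
            "bubble_area_true_mm2": self.bubble_area_true,
            "bubble_volume_true_mm3": self.bubble_volume_true,
        }


def _family_anchors(half_diag: float, period: float) -> np.ndarray:
    k = int(math.ceil(half_diag / period)) + 1
    return np.arange(-k, k + 1, dtype=float) * period


def _strut_coverage(rr, cc, centre, offset_along_normal, theta_deg, width_px,
                    family_normal):
    """Anti-aliased coverage of one strut band over the pixel grid.

    The strut line passes through ``centre + offset*family_normal`` with
    its own (possibly jittered) orientation ``theta_deg``.
    """
    t = np.deg2rad(theta_deg)
    # normal to a strut of axis angle theta, in (row, col) components
    n = np.array([-np.cos(t), -np.sin(t)])
    anchor = centre + offset_along_normal * family_normal
    dist = (rr - anchor[0]) * n[0] + (cc - anchor[1]) * n[1] - _EDGE_EPS
    return np.clip(0.5 * width_px - np.abs(dist) + 0.5, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> Tuple[GrayImage, GroundTruth]:
    """Rasterize a phantom and its exact ground truth (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rr, cc = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    half_diag = 0.5 * math.hypot(h, w) + spec.period_px

    families = []
    f = spec.secondary_fraction
    if f < 1.0:
        families.append((spec.theta_p, spec.period_px))
    if f > 0.0:
        # areal density of a family ~ width/period: choose the secondary
        # period so the two families mix at the requested pixel weight
        period_s = spec.period_px if f == 1.0 else spec.period_px * (1.0 - f) / f
        if period_s <= spec.thickness_px:
            raise ValueError(
                "secondary_fraction too high: secondary struts would fuse"
            )
        families.append((spec.theta_p + spec.secondary_offset, period_s))

    coverage = np.zeros((h, w))
    angle_map = np.full((h, w), np.nan)
    strut_angles: List[float] = []
    for family_theta, period in families:
        t = np.deg2rad(family_theta)
        family_normal = np.array([-np.cos(t), -np.sin(t)])
        for offset in _family_anchors(half_diag, period):
            theta_i = rng.normal(family_theta, spec.sigma_p) if spec.sigma_p > 0 \
                else family_theta
            cov_i = _strut_coverage(rr, cc, centre, offset, theta_i,
                                    spec.thickness_px, family_normal)
            if not np.any(cov_i > 0):
                continue
            strut_angles.append(float(np.mod(theta_i, 180.0)))
            better = cov_i > coverage
            angle_map[better & (cov_i >= 0.5)] = strut_angles[-1]
            coverage = np.maximum(coverage, cov_i)

    bone = coverage >= 0.5
    angle_map[~bone] = np.nan
    labels = np.where(bone, int(Phase.BONE), int(Phase.MARROW)).astype(np.uint8)
    mask = PhaseMask(labels, spec.spacing, spec.spacing, spec.slice_thickness)

    intensity = spec.marrow_level + (spec.bone_level - spec.marrow_level) * coverage
    image = GrayImage(intensity, spec.spacing, spec.spacing,
                      spec.slice_thickness, spec.modality)

    if spec.bubbles:
        image, mask = insert_bubbles(image, mask, spec.bubbles,
                                     bloom_factor=1.0,
                                     air_level=spec.air_level)
        angle_map[mask.labels == int(Phase.AIR)] = np.nan

    pixels = image.pixels.astype(np.float64)
    if spec.psf_sigma > 0:
        pixels = gaussian_filter(pixels, spec.psf_sigma / spec.spacing)
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    image = GrayImage(pixels, spec.spacing, spec.spacing,
                      spec.slice_thickness, spec.modality)

    truth = _ground_truth(spec, mask, angle_map, tuple(strut_angles))
    return image, truth


def _ground_truth(spec, mask, angle_map, strut_angles) -> GroundTruth:
    labels = mask.labels
    n_total = labels.size
    n_bone = int(np.count_nonzero(labels == int(Phase.BONE)))
    n_air = int(np.count_nonzero(labels == int(Phase.AIR)))
    bone_angles = angle_map[np.isfinite(angle_map)]
    if bone_angles.size:
        delta = axial_difference(bone_angles, spec.theta_p)
        tbint = float(np.sqrt(np.mean(delta**2)))
    else:
        tbint = 0.0
    area = n_air * spec.spacing**2
    return GroundTruth(
        mask=mask,
        bvf_true=n_bone / n_total,
        tbth_true=spec.strut_thickness,
        tbsp_true=spec.strut_spacing,
        theta_p_true=float(np.mod(spec.theta_p, 180.0)),
        sigma_p_true=spec.sigma_p,
        tbint_true=tbint,
        bubble_area_true=area,
        bubble_volume_true=area * spec.slice_thickness,
        angle_map=angle_map,
        strut_angles=strut_angles,
    )


def insert_bubbles(
    image: GrayImage,
    mask: PhaseMask,
    bubbles: Sequence[Tuple[Tuple[float, float], float]],
    bloom_factor: float = 1.0,
    air_level: Optional[float] = None,
    overlap_tolerance: float = 0.25,
) -> Tuple[GrayImage, PhaseMask]:
    """Stamp spherical (disk) air bubbles into the marrow phase.

    The phase mask records the true air extent at the nominal radius; for
    MR-like images the intensity signal void is widened by
    ``bloom_factor`` to mimic susceptibility blooming.  A bubble whose
    nominal disk overlaps bone by more than ``overlap_tolerance`` of its
    area is rejected.
    """
    if bloom_factor < 1.0:
        raise ValueError("bloom_factor must be >= 1")
    pixels = np.array(image.pixels, dtype=np.float64)
    labels = np.array(mask.labels)
    if air_level is None:
        air_level = _default_levels(image.modality)[2]
    if not bubbles:
        return image.with_pixels(pixels), PhaseMask(
            labels, mask.spacing_x, mask.spacing_y, mask.slice_thickness
        )
    h, w = pixels.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")
    bloom = bloom_factor if image.modality == Modality.MR_LIKE else 1.0
    for (centre, radius_mm) in bubbles:
        r_px = radius_mm / image.spacing_x
        d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
        nominal = d2 <= r_px**2
        if not nominal.any():
            continue
        bone_frac = np.count_nonzero(
            nominal & (labels == int(Phase.BONE))
        ) / np.count_nonzero(nominal)
        if bone_frac > overlap_tolerance:
            raise ValueError(
                f"bubble at {centre} overlaps bone ({bone_frac:.0%} of its area)"
            )
        labels[nominal & (labels == int(Phase.MARROW))] = int(Phase.AIR)
        pixels[d2 <= (bloom * r_px) ** 2] = air_level
    return image.with_pixels(pixels), PhaseMask(
        labels, mask.spacing_x, mask.spacing_y, mask.slice_thickness
    )
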