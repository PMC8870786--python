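"""Multi-scale Hessian orientation analysis of trabecular struts.

Per pixel, the Hessian of the Gaussian-smoothed intensity is computed at
several scales (sigma = 1..5 px by default), gamma-normalized (x sigma²),
and the scale with the strongest eigenvalue response is kept.  For a
line-like structure the eigenvector of the largest-magnitude eigenvalue
points across the strut, so the reported orientation is that eigenvector's
angle + 90° (mod 180): the strut axis.

The pooled orientation histogram over bone pixels is then fitted with a
two-Gaussian-plus-linear-baseline model, from which the principal and
secondary orientations (Tb.OrP / Tb.OrS) and the interconnectivity metric
Tb.Int (SD of the whole distribution about the principal orientation)
are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from ._angles import axial_difference, axial_mean, wrap_axial
from .core_io import GrayImage
from .segmentation import Phase, PhaseMask

__all__ = [
    "OrientationField",
    "OrientationDistribution",
    "GaussianMixtureFit",
    "hessian_orientation",
    "orientation_distribution",
    "distribution_from_angles",
    "fit_dual_gaussian",
    "compute_orientation_metrics",
    "orientation_spread",
]

DEFAULT_SCALES = (1.0, 2.0, 3.0, 4.0, 5.0)

#: a fitted Gaussian broader than this (degrees) on the 180-degree axis is
#: indistinguishable from a flat baseline and is never reported as a mode
_SIGMA_FLAT = 45.0


@dataclass
class OrientationField:
    theta: np.ndarray            # degrees in [0, 180), defined on every pixel
    response: np.ndarray         # scale-normalized |largest eigenvalue|
    scales_used: Tuple[float, ...]


@dataclass
class OrientationDistribution:
    """Normalized histogram of axial orientations over [0, 180)."""

    bin_centers: np.ndarray
    density: np.ndarray          # per-bin mass, sums to 1
    n_pixels: int

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_centers.shape != self.density.shape:
            raise ValueError("bin_centers and density shapes differ")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        total = self.density.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"density must sum to 1, got {total}")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass
class GaussianMixtureFit:
    """Fitted two-Gaussian-plus-linear-baseline orientation model.

    ``amp1`` / ``amp2`` scale the otherwise unit-area Gaussians (free by
    default; the strict unit-area form pins both to 1).  ``mu`` values are
    wrapped into [0, 180).
    """

    a: float
    m: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    amp1: float
    amp2: float
    converged: bool
    secondary_detected: bool
    residual_norm: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "a": self.a, "m": self.m,
            "mu1": self.mu1, "sigma1": self.sigma1,
            "mu2": self.mu2, "sigma2": self.sigma2,
            "amp1": self.amp1, "amp2": self.amp2,
            "converged": self.converged,
            "secondary_detected": self.secondary_detected,
        }


# ---------------------------------------------------------------------------
# per-pixel orientation
# ---------------------------------------------------------------------------

def hessian_orientation(
    image: GrayImage,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> OrientationField:
    """Per-pixel strut-axis orientation from the multi-scale Hessian."""
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if min(scales) < 0.5:
        raise ValueError("every scale must be >= 0.5 px")
    h, w = image.shape
    if min(h, w) < 6 * max(scales):
        raise ValueError(
            f"image {h}x{w} smaller than 6x the largest scale {max(scales)}"
        )

    pixels = np.asarray(image.pixels, dtype=np.float64)
    best_resp = np.full((h, w), -np.inf)
    best_theta = np.zeros((h, w))
    for sigma in scales:
        hrr = gaussian_filter(pixels, sigma, order=(2, 0))
        hcc = gaussian_filter(pixels, sigma, order=(0, 2))
        hrc = gaussian_filter(pixels, sigma, order=(1, 1))
        # gamma-normalization makes responses comparable across scales
        norm = sigma * sigma
        hrr, hcc, hrc = norm * hrr, norm * hcc, norm * hrc

        half_tr = 0.5 * (hrr + hcc)
        root = np.sqrt((0.5 * (hrr - hcc)) ** 2 + hrc**2)
        lam_hi, lam_lo = half_tr + root, half_tr - root
        lam = np.where(np.abs(lam_hi) >= np.abs(lam_lo), lam_hi, lam_lo)
        resp = np.abs(lam)

        # eigenvector of lam in (row, col) components, picked from the
        # numerically better-conditioned of the two defining relations
        v1 = np.stack([hrc, lam - hrr], axis=0)
        v2 = np.stack([lam - hcc, hrc], axis=0)
        use_v2 = np.linalg.norm(v1, axis=0) < np.linalg.norm(v2, axis=0)
        vr = np.where(use_v2, v2[0], v1[0])
        vc = np.where(use_v2, v2[1], v1[1])
        # math coords: x = col, y = -row; transverse angle then + 90 deg
        transverse = np.rad2deg(np.arctan2(-vr, vc))
        theta = wrap_axial(transverse + 90.0)

        better = resp > best_resp
        best_resp = np.where(better, resp, best_resp)
        best_theta = np.where(better, theta, best_theta)
    return OrientationField(best_theta, best_resp, scales)


# ---------------------------------------------------------------------------
# orientation distribution
# ---------------------------------------------------------------------------

def _histogram(theta: np.ndarray, bin_width: float) -> OrientationDistribution:
    nbins = int(round(180.0 / bin_width))
    if not np.isclose(nbins * bin_width, 180.0):
        raise ValueError("bin_width must divide 180 evenly")
    counts, edges = np.histogram(theta, bins=nbins, range=(0.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OrientationDistribution(centers, counts / counts.sum(), int(theta.size))


def orientation_distribution(
    field: OrientationField,
    mask: Union[PhaseMask, np.ndarray],
    bin_width: float = 1.0,
    exclude_border: bool = True,
) -> OrientationDistribution:
    """Histogram of the orientation field restricted to bone pixels.

    By default a margin of 3x the largest Hessian scale is excluded along
    the image frame: the smoothing kernels see padded (fabricated)
    content there and report unreliable orientations.
    """
    if isinstance(mask, PhaseMask):
        select = mask.phase_pixels(Phase.BONE)
    else:
        select = np.asarray(mask, dtype=bool)
    if select.shape != field.theta.shape:
        raise ValueError("mask shape does not match orientation field")
    if exclude_border:
        margin = int(np.ceil(3 * max(field.scales_used)))
        interior = np.zeros_like(select)
        if select.shape[0] > 2 * margin and select.shape[1] > 2 * margin:
            interior[margin:-margin, margin:-margin] = True
            if (select & interior).any():
                select = select & interior
    theta = field.theta[select]
    if theta.size == 0:
        raise ValueError("empty bone phase")
    return _histogram(wrap_axial(theta), bin_width)


def distribution_from_angles(
    angles_deg: np.ndarray, bin_width: float = 1.0
) -> OrientationDistribution:
    """Histogram a raw angle sample (wrapped axially) — handy for tests
    and for fitting simulated orientation mixtures."""
    angles = wrap_axial(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise ValueError("no angles given")
    return _histogram(angles, bin_width)


# ---------------------------------------------------------------------------
# dual-Gaussian model fit
# ---------------------------------------------------------------------------

def _wrapped_delta(x, mu):
    d = np.mod(x - mu, 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def _model(params, x, bin_width, free_amplitudes):
    a, m, mu1, s1, mu2, s2, amp1, amp2 = params
    if not free_amplitudes:
        amp1 = amp2 = 1.0
    d1 = _wrapped_delta(x, mu1)
    d2 = _wrapped_delta(x, mu2)
    g1 = amp1 / (s1 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * (d1 / s1) ** 2)
    g2 = amp2 / (s2 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * (d2 / s2) ** 2)
    return a + m * x + bin_width * (g1 + g2)


def _baseline_init(x, y):
    # robust linear baseline from the lowest-density quartile
    k = max(2, len(y) // 4)
    idx = np.argsort(y)[:k]
    m, a = np.polyfit(x[idx], y[idx], 1)
    return a, m


def fit_dual_gaussian(
    dist: OrientationDistribution,
    free_amplitudes: bool = True,
    max_restarts: int = 5,
    xtol: float = 1e-8,
) -> GaussianMixtureFit:
    """Nonlinear least-squares fit of the dual-Gaussian orientation model.

    The model is ``y = a + m*x + amp1*N(x; mu1, sigma1) + amp2*N(x; mu2,
    sigma2)`` with unit-area (per-degree) Gaussians evaluated with wrapped
    angular residuals and scaled by the bin width so that amplitudes read
    as mixture weights.  With ``free_amplitudes=False`` the strict unit-area
    form (amp1 = amp2 = 1) is used.

    Component labelling: the principal Gaussian is the one with larger
    fitted mass; when the masses are within 15% of each other the broader
    component (larger sigma) is taken as principal.  ``secondary_detected``
    turns false (the ND case) when the secondary mass is below 5% of the
    principal, when the two means are closer than 2*max(sigma1, bin
    width), when dropping the second component costs less than 15% extra
    residual (guards against spurious modes on flat or unimodal data),
    or when the fit failed to converge.
    """
    x = dist.bin_centers
    y = dist.density
    if len(y) < 20 or np.count_nonzero(y) < 2:
        raise ValueError("need at least 20 bins (2 non-empty) to fit the model")
    bw = dist.bin_width

    mode = float(x[np.argmax(y)])
    a0, m0 = _baseline_init(x, y)

    def mass_near(mu, s):
        sel = axial_difference(x, mu) <= 2 * s
        return float(np.clip(y[sel].sum(), 0.05, 1.0))

    mu1_0 = mode
    mu2_0 = wrap_axial(mode + 90.0)
    s0 = 10.0
    p0 = np.array([
        a0, m0, mu1_0, s0, mu2_0, s0,
        mass_near(mu1_0, s0), mass_near(mu2_0, s0),
    ])
    lower = [-np.inf, -np.inf, -360.0, bw, -360.0, bw, 0.0, 0.0]
    upper = [np.inf, np.inf, 540.0, 90.0, 540.0, 90.0, 2.0, 2.0]

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = p0.copy()
        if attempt:
            start[2] = wrap_axial(p0[2] + rng.normal(0, 15))
            start[4] = wrap_axial(p0[4] + rng.normal(0, 25))
            start[3] = np.clip(p0[3] * rng.uniform(0.5, 2.0), bw, 90)
            start[5] = np.clip(p0[5] * rng.uniform(0.5, 2.0), bw, 90)
        start = np.clip(start, lower, upper)
        try:
            res = least_squares(
                lambda p: _model(p, x, bw, free_amplitudes) - y,
                start, bounds=(lower, upper), xtol=xtol, ftol=xtol, gtol=xtol,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        return GaussianMixtureFit(0, 0, mu1_0, s0, mu2_0, s0, 0, 0,
                                  converged=False, secondary_detected=False)

    a, m, mu1, s1, mu2, s2, amp1, amp2 = best.x
    if not free_amplitudes:
        amp1 = amp2 = 1.0
    mu1, mu2 = float(wrap_axial(mu1)), float(wrap_axial(mu2))
    converged = bool(best.success)

    # principal = dominant mass; near-ties resolved toward the broader mode.
    # A quasi-flat component (sigma beyond _SIGMA_FLAT on a 180 deg axis)
    # is a baseline surrogate, never a trabecular orientation mode.
    flat1, flat2 = s1 > _SIGMA_FLAT, s2 > _SIGMA_FLAT
    if flat1 != flat2:
        swap = flat1
    else:
        swap = amp2 > amp1
        if min(amp1, amp2) > 0 and abs(amp1 - amp2) <= 0.15 * max(amp1, amp2):
            swap = s2 > s1
    if swap:
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
        amp1, amp2 = amp2, amp1

    separation = float(axial_difference(mu1, mu2))
    overlapping = separation < 2.0 * max(min(s1, _SIGMA_FLAT), bw)
    secondary = (
        converged
        and s2 <= _SIGMA_FLAT
        and amp2 >= 0.05 * amp1
        and not overlapping
    )
    if (overlapping and s2 <= _SIGMA_FLAT and s1 <= _SIGMA_FLAT
            and amp1 + amp2 > 0):
        # the two Gaussians jointly describe one clump and their split is
        # degenerate; anchor mu1 on the data instead: the axial mean of
        # the baseline-subtracted distribution
        excess = np.clip(y - (a + m * x), 0.0, None)
        if excess.sum() > 1e-12:
            mu1 = float(axial_mean(x, weights=excess))
            w = excess / excess.sum()
            s1 = float(min(np.sqrt(np.sum(w * axial_difference(x, mu1) ** 2)),
                           90.0))
            amp1 = amp1 + amp2
    if secondary and free_amplitudes:
        # dual model must clearly beat single-Gaussian-plus-baseline
        single_start = np.array([a, m, mu1, s1, mu2, s2, amp1, 0.0])
        single_upper = list(upper)
        single_upper[7] = 1e-12
        try:
            single = least_squares(
                lambda p: _model(p, x, bw, True) - y,
                np.clip(single_start, lower, single_upper),
                bounds=(lower, single_upper), xtol=xtol, ftol=xtol, gtol=xtol,
            )
            if best.cost > 0.85 * single.cost:
                secondary = False
        except Exception:
            pass
    return GaussianMixtureFit(
        a=float(a), m=float(m), mu1=mu1, sigma1=float(s1),
        mu2=mu2, sigma2=float(s2), amp1=float(amp1), amp2=float(amp2),
        converged=converged, secondary_detected=bool(secondary),
        residual_norm=float(np.sqrt(2 * best.cost)),
    )


# ---------------------------------------------------------------------------
# orientation metrics
# ---------------------------------------------------------------------------

def orientation_spread(dist: OrientationDistribution, mu1: float) -> float:
    """SD of the whole orientation distribution about ``mu1`` (degrees).

    Uses bin-level densities and minimal axial differences (capped at
    90°), so the result lies in [0, 90].
    """
    delta = axial_difference(dist.bin_centers, mu1)
    return float(np.sqrt(np.sum(dist.density * delta**2)))


def compute_orientation_metrics(
    dist: OrientationDistribution,
    fit: GaussianMixtureFit,
) -> dict:
    """Tb.OrP, Tb.OrS and Tb.Int from a distribution and its model fit.

    Returns a dict with ``tborp`` = (mu1, sigma1); ``tbors_raw`` = mu2 and
    ``tbors_diff`` = |mu2 - mu1| (both ``None`` when the secondary mode
    was not detected — the ND case); and ``tbint`` = SD of the whole
    distribution about mu1.
    """
    if not fit.converged:
        raise ValueError("model fit did not converge; Tb.OrP undefined")
    tbint = orientation_spread(dist, fit.mu1)
    if fit.secondary_detected:
        tbors_raw = fit.mu2
        tbors_diff = abs(fit.mu2) - fit.mu1
    else:
        tbors_raw = None
        tbors_diff = None
    return {
        "tborp": (fit.mu1, fit.sigma1),
        "tbors_raw": tbors_raw,
        "tbors_diff": tbors_diff,
        "tbint": tbint,
    }


def plot_distribution(dist, fit=None, path=None):  # pragma: no cover - QC only
    """Optional QC plot of the orientation distribution and fitted model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(dist.bin_centers, dist.density, width=dist.bin_width,
           color="#7b6bd6", alpha=0.7, label="orientation distribution")
    if fit is not None and fit.converged:
        xx = np.linspace(0, 180, 721)
        p = [fit.a, fit.m, fit.mu1, fit.sigma1, fit.mu2, fit.sigma2,
             fit.amp1, fit.amp2]
        ax.plot(xx, _model(np.array(p), xx, dist.bin_width, True),
                "k-", lw=1.5, label="dual-Gaussian fit")
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel("density")
    ax.set_xlim(0, 180)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
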