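"""2D slice-to-stack registration with correlation scoring.

Each moving slice is matched against every slice of a reference stack:
after resampling to the stack's pixel grid, an affine transform
(translation, rotation, isotropic scale, shear) is optimized per slice
under either Pearson correlation (monomodal) or mutual information
(multimodal, e.g. contrast-inverted pairs), and the best-matching slice
is the one maximizing the similarity profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .core_io import GrayImage

__all__ = [
    "RegistrationResult",
    "correlation_score",
    "mutual_information",
    "register_pair",
    "register_slice",
]


@dataclass
class RegistrationResult:
    best_slice_index: int
    transform: np.ndarray            # 2x3 forward affine, (row, col) pixel coords
    score: float                     # Pearson correlation of the registered pair
    score_profile: np.ndarray        # per-slice similarity-metric values
    metric: str = "correlation"

    def __post_init__(self) -> None:
        self.transform = np.asarray(self.transform, dtype=float)
        if self.transform.shape != (2, 3):
            raise ValueError("transform must be a 2x3 affine matrix")
        if abs(np.linalg.det(self.transform[:, :2])) < 1e-12:
            raise ValueError("transform is not invertible")


def _as_array(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return np.asarray(img.pixels, dtype=np.float64)
    return np.asarray(img, dtype=np.float64)


def _znorm(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        raise ValueError("constant image: correlation undefined (zero variance)")
    return (a - a.mean()) / sd


def correlation_score(a, b) -> float:
    """Pearson correlation over all pixel pairs of two same-shape images."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean(_znorm(a) * _znorm(b)))


def mutual_information(a, b, bins: int = 32) -> float:
    """Joint-histogram mutual information (nats) of two same-shape images."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# affine machinery (forward transform maps moving -> fixed, about the centre)
# ---------------------------------------------------------------------------

def _params_to_affine(params, shape) -> np.ndarray:
    ty, tx, rot_deg, log_scale, shear = params
    c, s = np.cos(np.deg2rad(rot_deg)), np.sin(np.deg2rad(rot_deg))
    scale = np.exp(log_scale)
    lin = scale * np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]])
    centre = (np.asarray(shape, dtype=float) - 1) / 2.0
    offset = centre + np.array([ty, tx]) - lin @ centre
    return np.column_stack([lin, offset])


def _warp(moving: np.ndarray, affine: np.ndarray, shape,
          fill: str = "nearest") -> np.ndarray:
    lin, off = affine[:, :2], affine[:, 2]
    inv = np.linalg.inv(lin)
    if fill == "nan":
        out = ndimage.affine_transform(
            moving, inv, offset=-inv @ off, output_shape=shape,
            order=1, mode="constant", cval=np.nan,
        )
        return out
    return ndimage.affine_transform(
        moving, inv, offset=-inv @ off, output_shape=shape,
        order=1, mode="nearest",
    )


def _masked_similarity(metric, warped: np.ndarray, fixed: np.ndarray) -> float:
    """Similarity over the valid overlap only (NaN marks out-of-view)."""
    valid = np.isfinite(warped)
    if np.count_nonzero(valid) < 0.25 * fixed.size:
        return -np.inf
    try:
        return metric(warped[valid], fixed[valid])
    except ValueError:
        return -np.inf


def _similarity(metric: str):
    if metric == "correlation":
        return correlation_score
    if metric == "mi":
        return mutual_information
    raise ValueError(f"unknown metric {metric!r}")


def _resample_to(moving: GrayImage, fixed: GrayImage) -> np.ndarray:
    """Bilinear resample of the moving slice onto the fixed pixel grid."""
    arr = _as_array(moving)
    fy = moving.spacing_y / fixed.spacing_y
    fx = moving.spacing_x / fixed.spacing_x
    out_shape = (max(2, round(arr.shape[0] * fy)), max(2, round(arr.shape[1] * fx)))
    up = resize(arr, out_shape, order=1, anti_aliasing=False, preserve_range=True)
    # pad or crop symmetrically to the fixed frame
    target = fixed.shape
    out = np.full(target, float(up.mean()))
    r = min(target[0], up.shape[0])
    c = min(target[1], up.shape[1])
    ro, uo = (target[0] - r) // 2, (up.shape[0] - r) // 2
    co, vo = (target[1] - c) // 2, (up.shape[1] - c) // 2
    out[ro:ro + r, co:co + c] = up[uo:uo + r, vo:vo + c]
    return out


def register_pair(
    moving: np.ndarray,
    fixed: np.ndarray,
    metric: str = "correlation",
) -> Tuple[np.ndarray, float]:
    """Affine-register ``moving`` onto ``fixed`` (same grid already).

    Returns the 2x3 forward affine and the achieved similarity.  A
    translation warm start comes from subpixel phase correlation (on
    gradient magnitudes, which survive contrast inversion); a Nelder-Mead
    simplex then refines the full affine and is only accepted when it
    improves the similarity.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    sim = _similarity(metric)

    gm = np.hypot(*np.gradient(moving))
    gf = np.hypot(*np.gradient(fixed))
    try:
        shift, _, _ = phase_cross_correlation(gf, gm, upsample_factor=50)
    except Exception:
        shift = np.zeros(2)

    def score_of(params) -> float:
        warped = _warp(moving, _params_to_affine(params, fixed.shape),
                       fixed.shape, fill="nan")
        return _masked_similarity(sim, warped, fixed)

    p0 = np.array([shift[0], shift[1], 0.0, 0.0, 0.0])
    candidates = [np.zeros(5), p0]
    best_p = max(candidates, key=score_of)
    best_score = score_of(best_p)

    # staged refinement: translation only, then the full affine; each
    # stage is kept only when it actually improves the similarity
    free_masks = [np.array([1, 1, 0, 0, 0], bool), np.ones(5, dtype=bool)]
    for free in free_masks:
        base = best_p.copy()

        def neg(sub, base=base, free=free):
            p = base.copy()
            p[free] = sub
            return -score_of(p)

        res = minimize(
            neg, best_p[free], method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 400},
        )
        if np.isfinite(res.fun) and -res.fun > best_score:
            best_p = base.copy()
            best_p[free] = res.x
            best_score = -res.fun
    return _params_to_affine(best_p, fixed.shape), float(best_score)


def register_slice(
    moving: GrayImage,
    stack: Sequence[GrayImage],
    metric: str = "correlation",
) -> RegistrationResult:
    """Find and register the stack slice best matching ``moving``.

    The moving slice is first resampled to the stack's pixel grid; every
    stack slice is then affine-registered and scored with ``metric``
    ('correlation' or 'mi').  ``best_slice_index`` maximizes the score
    profile; ``score`` is the Pearson correlation of the winning
    registered pair (negative for contrast-inverted multimodal matches).
    """
    if len(stack) == 0:
        raise ValueError("stack is empty")
    moved = _resample_to(moving, stack[0])
    profile = np.full(len(stack), -np.inf)
    transforms: List[Optional[np.ndarray]] = [None] * len(stack)
    for k, ref in enumerate(stack):
        try:
            transforms[k], profile[k] = register_pair(
                moved, _as_array(ref), metric=metric
            )
        except ValueError:
            continue
    if not np.any(np.isfinite(profile)):
        raise RuntimeError("registration failed on every stack slice")
    best = int(np.argmax(profile))
    warped = _warp(moved, transforms[best], stack[best].shape)
    return RegistrationResult(
        best_slice_index=best,
        transform=transforms[best],
        score=correlation_score(warped, stack[best]),
        score_profile=profile,
        metric=metric,
    )
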