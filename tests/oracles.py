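"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the production code paths (no EDT, no painting
order tricks): everything is an explicit minimization/maximization over
all candidates, vectorized only for speed.
"""

from __future__ import annotations

import numpy as np


def aperture_oracle(mask: np.ndarray) -> np.ndarray:
    """Exhaustive maximal-inclusion-disk search, in pixel units.

    Shares the package's stated convention: disk centres on the
    half-pixel lattice, maximal radius = Euclidean distance to the union
    of out-of-phase unit squares, a pixel is covered when its centre lies
    in the closed disk.  Every (centre, radius) candidate is enumerated
    directly against every background pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    bg = np.argwhere(~mask).astype(float)
    if bg.size == 0:
        return np.full(mask.shape, float(np.hypot(h, w)))

    ii, jj = np.meshgrid(np.arange(2 * h - 1), np.arange(2 * w - 1),
                         indexing="ij")
    nodes = np.column_stack([ii.ravel() / 2.0, jj.ravel() / 2.0])

    radius = np.empty(len(nodes))
    chunk = 2048
    for s in range(0, len(nodes), chunk):
        blk = nodes[s:s + chunk]
        dr = np.maximum(np.abs(blk[:, 0:1] - bg[None, :, 0].reshape(1, -1)) - 0.5, 0.0)
        dc = np.maximum(np.abs(blk[:, 1:2] - bg[None, :, 1].reshape(1, -1)) - 0.5, 0.0)
        radius[s:s + chunk] = np.sqrt(dr**2 + dc**2).min(axis=1)

    keep = radius > 0
    nodes, radius = nodes[keep], radius[keep]
    r2 = radius**2

    out = np.zeros(mask.shape)
    for (pr, pc) in np.argwhere(mask):
        d2 = (nodes[:, 0] - pr) ** 2 + (nodes[:, 1] - pc) ** 2
        covering = d2 <= r2 + 1e-9
        if covering.any():
            out[pr, pc] = 2.0 * radius[covering].max()
    return out


def kruskal_oracle(groups):
    """Textbook tie-corrected Kruskal-Wallis H from explicit average ranks."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    start = 0
    h = 0.0
    for g in groups:
        k = len(g)
        rbar = ranks[start:start + k].mean()
        h += k * (rbar - (n + 1) / 2.0) ** 2
        start += k
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else np.nan
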