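"""Resolution degradation by integer block-merging (partial-volume model).

Merging pixels in f x f blocks (f³ voxels in 3D) with an arithmetic mean
multiplies the pixel spacing by f and mixes bone and marrow signal within
each output pixel — the partial-volume effect under study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .core_io import GrayImage

__all__ = ["DegradeSpec", "degrade"]


@dataclass
class DegradeSpec:
    factor: int
    mode: str = "2d"
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        if int(self.factor) != self.factor or self.factor < 2:
            raise ValueError("degradation factor must be an integer >= 2")
        self.factor = int(self.factor)
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if self.aggregator != "mean":
            raise ValueError("only the 'mean' aggregator is supported")


def degrade(image: GrayImage, spec: Union[DegradeSpec, int]) -> GrayImage:
    """Block-merge ``image`` by ``spec.factor``, scaling the spacing.

    Trailing rows/columns that do not fill a complete block are cropped
    with a warning.  The global mean intensity of the retained area is
    preserved exactly; the physical field of view shrinks only by the
    cropped margin.
    """
    if not isinstance(spec, DegradeSpec):
        spec = DegradeSpec(int(spec))
    f = spec.factor
    h, w = image.shape
    hc, wc = (h // f) * f, (w // f) * f
    if hc == 0 or wc == 0:
        raise ValueError(f"image {h}x{w} smaller than one {f}x{f} block")
    if (hc, wc) != (h, w):
        warnings.warn(
            f"image {h}x{w} not divisible by {f}; cropping to {hc}x{wc}"
        )
    pixels = np.asarray(image.pixels, dtype=np.float64)[:hc, :wc]
    merged = pixels.reshape(hc // f, f, wc // f, f).mean(axis=(1, 3))
    thickness = image.slice_thickness
    if spec.mode == "3d" and thickness:
        thickness = thickness * f
    return GrayImage(
        pixels=merged,
        spacing_x=image.spacing_x * f,
        spacing_y=image.spacing_y * f,
        slice_thickness=thickness,
        modality=image.modality,
    )
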