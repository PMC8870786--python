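"""Image / report I/O with physical spacing metadata.

Supported raster formats: TIFF (single or multi-page, spacing from the
resolution tags), NIfTI-1 (``.nii`` / ``.nii.gz``, spacing from ``pixdim``)
and MetaImage (``.mhd`` + ``.raw``, spacing from ``ElementSpacing``).
All physical quantities are millimetres; angles are degrees.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "Modality",
    "GrayImage",
    "ROI",
    "read_image",
    "write_image",
    "write_report",
    "read_report",
    "require_analysis_size",
]

PathLike = Union[str, Path]

#: Minimum raster size accepted by analysis entry points.
MIN_ANALYSIS_DIM = 8


class Modality(str, Enum):
    """Acquisition regime; decides default segmentation polarity."""

    CT_LIKE = "CT_LIKE"  # bone bright, marrow dark, air darkest
    MR_LIKE = "MR_LIKE"  # bone dark, marrow bright, air dark
    UNKNOWN = "UNKNOWN"


@dataclass
class GrayImage:
    """A 2D grayscale raster with physical pixel spacing.

    Parameters
    ----------
    pixels : (H, W) ndarray
        Finite intensities, arbitrary units.
    spacing_x, spacing_y : float
        In-plane pixel size, mm/pixel, strictly positive.
    slice_thickness : float
        Through-plane extent in mm (metadata only; 0 when unknown).
    modality : Modality
        Acquisition regime tag.
    """

    pixels: np.ndarray
    spacing_x: float
    spacing_y: float
    slice_thickness: float = 0.0
    modality: Modality = Modality.UNKNOWN

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise ValueError("spacing must be strictly positive (mm/pixel)")
        if self.slice_thickness < 0:
            raise ValueError("slice_thickness must be >= 0")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def spacing(self) -> Tuple[float, float]:
        """(spacing_y, spacing_x) in mm/pixel, matching array axis order."""
        return (self.spacing_y, self.spacing_x)

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Copy of this image with new pixel data, metadata untouched."""
        return replace(self, pixels=np.asarray(pixels))


@dataclass
class ROI:
    """Boolean region-of-interest mask congruent with a host image."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")

    def check_against(self, image: GrayImage) -> None:
        if self.mask.shape != image.shape:
            raise ValueError(
                f"ROI shape {self.mask.shape} != image shape {image.shape}"
            )
        if not self.mask.any():
            raise ValueError("ROI is empty")


def require_analysis_size(image: GrayImage) -> None:
    """Reject rasters too small for any morphometric analysis."""
    h, w = image.shape
    if h < MIN_ANALYSIS_DIM or w < MIN_ANALYSIS_DIM:
        raise ValueError(
            f"image {h}x{w} below minimum analysis size "
            f"{MIN_ANALYSIS_DIM}x{MIN_ANALYSIS_DIM}"
        )


# ---------------------------------------------------------------------------
# raster reading
# ---------------------------------------------------------------------------

def read_image(
    path: PathLike,
    spacing_override: Optional[float] = None,
    slice_index: Optional[int] = None,
    modality: Union[Modality, str] = Modality.UNKNOWN,
) -> GrayImage:
    """Load a 2D grayscale image with spacing metadata.

    Spacing is taken from file metadata when present, else from
    ``spacing_override`` (mm/pixel, isotropic); if neither is available a
    ``ValueError`` is raised.  3D content requires an explicit
    ``slice_index``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        pixels, spacing, thickness = _read_tiff(path, slice_index)
    elif suffix.endswith((".nii", ".nii.gz")):
        pixels, spacing, thickness = _read_nifti(path, slice_index)
    elif suffix.endswith(".mhd"):
        pixels, spacing, thickness = _read_metaimage(path, slice_index)
    else:
        raise ValueError(f"unsupported image format: {path.name}")

    if spacing is None:
        if spacing_override is None:
            raise ValueError(f"spacing unknown for {path.name} and no override given")
        spacing = (float(spacing_override), float(spacing_override))
    return GrayImage(
        pixels=pixels,
        spacing_x=spacing[1],
        spacing_y=spacing[0],
        slice_thickness=thickness,
        modality=Modality(modality),
    )


def _pick_slice(arr: np.ndarray, slice_index: Optional[int]) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if slice_index is None:
            raise ValueError(
                "file holds a 3D stack; pass an explicit slice index"
            )
        return arr[slice_index]
    raise ValueError(f"unsupported array dimensionality {arr.ndim}")


def _read_tiff(path: Path, slice_index):
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) > 1:
            if slice_index is None:
                raise ValueError("multi-page TIFF requires an explicit slice index")
            page = tf.pages[slice_index]
        else:
            page = tf.pages[0]
        pixels = page.asarray()
        if pixels.ndim != 2:
            raise ValueError("TIFF page is not a 2D grayscale raster")
        spacing = _tiff_spacing(page)
    return pixels, spacing, 0.0


def _tiff_spacing(page):
    tags = page.tags
    unit = tags.get("ResolutionUnit")
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if unit is None or xres is None or yres is None:
        return None
    unit = int(getattr(unit.value, "value", unit.value))
    mm_per_unit = {2: 25.4, 3: 10.0}.get(unit)
    if mm_per_unit is None:  # RESUNIT.NONE
        return None

    def _ratio(v):
        num, den = v.value if isinstance(v.value, tuple) else (v.value, 1)
        return num / den

    px_per_unit_x, px_per_unit_y = _ratio(xres), _ratio(yres)
    if px_per_unit_x <= 0 or px_per_unit_y <= 0:
        return None
    return (mm_per_unit / px_per_unit_y, mm_per_unit / px_per_unit_x)


def _read_nifti(path: Path, slice_index):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim == 3:
        if slice_index is None:
            raise ValueError("NIfTI holds a 3D stack; pass an explicit slice index")
        data = data[:, :, slice_index]
    elif data.ndim != 2:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    # NIfTI fastest axis = x (columns); stored transposed relative to (row, col)
    pixels = np.ascontiguousarray(data.T)
    spacing = (float(zooms[1]), float(zooms[0]))
    thickness = float(zooms[2]) if len(zooms) > 2 else 0.0
    if spacing[0] <= 0 or spacing[1] <= 0:
        spacing = None
    return pixels, spacing, thickness


_MET_DTYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def _read_metaimage(path: Path, slice_index):
    header = {}
    for line in path.read_text().splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        header[key.strip()] = value.strip()
    ndims = int(header.get("NDims", 2))
    dims = [int(v) for v in header["DimSize"].split()]
    dtype = _MET_DTYPES.get(header.get("ElementType", "MET_FLOAT"))
    if dtype is None:
        raise ValueError(f"unsupported MetaImage ElementType {header['ElementType']}")
    if header.get("CompressedData", "False").lower() == "true":
        raise ValueError("compressed MetaImage data is not supported")
    datafile = header.get("ElementDataFile", "LOCAL")
    raw_path = path.parent / datafile
    data = np.fromfile(str(raw_path), dtype=dtype)
    big_endian = header.get("ElementByteOrderMSB", "False").lower() == "true"
    if big_endian:
        data = data.byteswap().view(data.dtype.newbyteorder())
    # MetaImage DimSize is (x, y[, z]); fastest-varying axis first
    shape = tuple(reversed(dims))
    data = data.reshape(shape)
    data = _pick_slice(data, slice_index)
    spacing_vals = [float(v) for v in header.get("ElementSpacing", "").split()] or None
    spacing = None
    thickness = 0.0
    if spacing_vals:
        spacing = (spacing_vals[1], spacing_vals[0])
        if ndims > 2 and len(spacing_vals) > 2:
            thickness = spacing_vals[2]
    return data, spacing, thickness


# ---------------------------------------------------------------------------
# raster writing
# ---------------------------------------------------------------------------

def write_image(image: GrayImage, path: PathLike) -> None:
    """Write a :class:`GrayImage` preserving spacing metadata.

    Integer rasters round-trip bit-exactly through every supported format.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        _write_tiff(image, path)
    elif suffix.endswith((".nii", ".nii.gz")):
        _write_nifti(image, path)
    elif suffix.endswith(".mhd"):
        _write_metaimage(image, path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def _write_tiff(image: GrayImage, path: Path) -> None:
    import tifffile

    # resolution stored as pixels per centimetre
    res = (10.0 / image.spacing_x, 10.0 / image.spacing_y)
    tifffile.imwrite(
        str(path), image.pixels, resolution=res, resolutionunit="CENTIMETER"
    )


def _write_nifti(image: GrayImage, path: Path) -> None:
    import nibabel as nib

    data = np.ascontiguousarray(image.pixels.T)
    affine = np.diag([image.spacing_x, image.spacing_y, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((image.spacing_x, image.spacing_y))
    nib.save(img, str(path))


def _write_metaimage(image: GrayImage, path: Path) -> None:
    raw_name = path.with_suffix(".raw").name
    arr = np.ascontiguousarray(image.pixels)
    met_type = next(
        (k for k, v in _MET_DTYPES.items() if np.dtype(v) == arr.dtype), None
    )
    if met_type is None:
        arr = arr.astype(np.float64)
        met_type = "MET_DOUBLE"
    h, w = arr.shape
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 2",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            "CompressedData = False",
            f"DimSize = {w} {h}",
            f"ElementSpacing = {image.spacing_x:.17g} {image.spacing_y:.17g}",
            f"ElementType = {met_type}",
            f"ElementDataFile = {raw_name}",
        ]
    )
    path.write_text(header + "\n")
    arr.tofile(str(path.parent / raw_name))


# ---------------------------------------------------------------------------
# morphometry reports
# ---------------------------------------------------------------------------

#: column order of a flattened report row; mirrors the standard
#: histomorphometry table layout (lengths in mm, angles in degrees).
REPORT_FIELDS = [
    "bvf",
    "tbth_mm",
    "tbth_sd_mm",
    "tbsp_mm",
    "tbsp_sd_mm",
    "tbn_per_mm",
    "tborp_deg",
    "tborp_sd_deg",
    "tbors_deg",
    "tbors_diff_deg",
    "tbint_deg",
    "abv_mm3",
]

_ND = "ND"


def write_report(report, path: PathLike) -> None:
    """Serialize a morphometry report to CSV or JSON (by extension).

    A missing secondary orientation is written as the literal ``ND``.
    BVF is mandatory; a report without it is rejected.
    """
    row = _report_row(report)
    if row["bvf"] is None:
        raise ValueError("report is missing mandatory BVF")
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {k: (_ND if v is None else v) for k, v in row.items()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(REPORT_FIELDS)
            writer.writerow(
                [_ND if row[k] is None else repr(float(row[k])) for k in REPORT_FIELDS]
            )
    else:
        raise ValueError(f"unsupported report format: {path.name}")


def _report_row(report) -> dict:
    if isinstance(report, dict):
        row = {k: report.get(k) for k in REPORT_FIELDS}
    else:
        row = {k: getattr(report, k, None) for k in REPORT_FIELDS}
    out = {}
    for k, v in row.items():
        if v is None or (isinstance(v, str) and v.upper() == _ND):
            out[k] = None
        else:
            v = float(v)
            out[k] = None if math.isnan(v) else v
    return out


def read_report(path: PathLike) -> dict:
    """Inverse of :func:`write_report`; ND cells come back as ``None``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    elif path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        raw = dict(zip(rows[0], rows[1]))
    else:
        raise ValueError(f"unsupported report format: {path.name}")
    out = {}
    for k in REPORT_FIELDS:
        v = raw.get(k)
        if v is None or (isinstance(v, str) and v.strip().upper() == _ND):
            out[k] = None
        else:
            out[k] = float(v)
    return out
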