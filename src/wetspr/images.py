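"""Axial CT image containers, HU/attenuation conversion and plain-text I/O.

The Hounsfield scale relates the CT number ``H`` of a voxel to its linear
x-ray attenuation coefficient relative to water, ``mu``::

    H = (mu - 1) * 1000 HU        <=>        mu = H / 1000 + 1

so water is 0 HU (mu = 1) and air is -1000 HU (mu = 0).  All thickness
estimation and SPR machinery in this package works on single axial slices;
a volume is simply an ordered list of slices.

Coordinate convention: the row index is y (increasing downward as stored),
the column index is x.  All pixel index intervals are half-open and 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "HUImage",
    "AttenuationImage",
    "DualEnergyImage",
    "CropBox",
    "hu_to_mu",
    "mu_to_hu",
    "crop",
    "read_dicom_series",
    "read_matrix_fixture",
    "write_matrix_fixture",
]


def _validate_grid(pixels: np.ndarray, spacing_x: float, spacing_y: float) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"pixel grid must be 2-D, got shape {arr.shape}")
    if not (spacing_x > 0 and spacing_y > 0):
        raise ValueError(f"pixel spacing must be positive, got ({spacing_x}, {spacing_y})")
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"non-finite pixel value at (row={i}, col={j})")
    return arr


@dataclass(frozen=True)
class HUImage:
    """One axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : 2-D array of CT numbers (HU).
    spacing_x, spacing_y : pixel dimensions in mm (column / row direction).
    slice_index : position of the slice in its series (>= 0).
    """

    pixels: np.ndarray
    spacing_x: float
    spacing_y: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _validate_grid(self.pixels, self.spacing_x, self.spacing_y))
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class AttenuationImage:
    """One axial slice of linear attenuation relative to water (dimensionless)."""

    pixels: np.ndarray
    spacing_x: float
    spacing_y: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _validate_grid(self.pixels, self.spacing_x, self.spacing_y))
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DualEnergyImage:
    """Paired low/high tube-voltage HU slices sharing one geometry.

    ``low`` plays the 80 kVp role and ``high`` the 140 kVp role of a
    dual-spiral DECT acquisition.
    """

    low: HUImage
    high: HUImage

    def __post_init__(self) -> None:
        if self.low.shape != self.high.shape:
            raise ValueError(f"low/high shapes differ: {self.low.shape} vs {self.high.shape}")
        if (self.low.spacing_x, self.low.spacing_y) != (self.high.spacing_x, self.high.spacing_y):
            raise ValueError("low/high pixel spacings differ")
        if self.low.slice_index != self.high.slice_index:
            raise ValueError("low/high slice indices differ")

    @property
    def spacing_x(self) -> float:
        return self.low.spacing_x

    @property
    def spacing_y(self) -> float:
        return self.low.spacing_y

    @property
    def slice_index(self) -> int:
        return self.low.slice_index


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel index ranges [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_min < self.row_max):
            raise ValueError(f"invalid row range [{self.row_min}, {self.row_max})")
        if not (0 <= self.col_min < self.col_max):
            raise ValueError(f"invalid col range [{self.col_min}, {self.col_max})")

    def check_within(self, shape: tuple[int, int]) -> None:
        n_rows, n_cols = shape
        if self.row_max > n_rows or self.col_max > n_cols:
            raise ValueError(f"crop box {self} exceeds image shape {shape}")


def hu_to_mu(image: HUImage, clip_negative: bool = True) -> AttenuationImage:
    """Convert CT numbers to attenuation relative to water: mu = H/1000 + 1.

    Noise in reconstructed images can push H below -1000 HU, which would
    yield a non-physical negative attenuation; by default such values are
    clipped to 0 so that attenuation-weighted extents stay non-negative.
    Pass ``clip_negative=False`` to keep raw values for diagnostics.
    """
    mu = image.pixels / 1000.0 + 1.0
    if clip_negative:
        mu = np.maximum(mu, 0.0)
    return AttenuationImage(mu, image.spacing_x, image.spacing_y, image.slice_index)


def mu_to_hu(image: AttenuationImage) -> HUImage:
    """Convert relative attenuation back to CT numbers: H = (mu - 1)*1000."""
    return HUImage((image.pixels - 1.0) * 1000.0, image.spacing_x, image.spacing_y, image.slice_index)


def crop(image: HUImage | AttenuationImage, box: CropBox):
    """Extract the sub-grid of ``box`` (half-open ranges); spacing preserved.

    Typical use is removal of the patient couch before thickness estimation.
    """
    box.check_within(image.shape)
    sub = image.pixels[box.row_min : box.row_max, box.col_min : box.col_max].copy()
    return replace(image, pixels=sub)


# ---------------------------------------------------------------------------
# DICOM series reading
# ---------------------------------------------------------------------------

def read_dicom_series(path: str | os.PathLike) -> list[HUImage]:
    """Read a directory of single-frame CT DICOM files as ordered HU slices.

    Pixel data are rescaled to HU with the rescale slope/intercept metadata
    (an error is raised when either is missing); slices are ordered by axial
    position (ImagePositionPatient z, falling back to InstanceNumber) and
    must share one pixel spacing and shape.
    """
    import pydicom

    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, stray text)
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {directory}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices: list[HUImage] = []
    ref_spacing = None
    ref_shape = None
    for k, ds in enumerate(datasets):
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            raise ValueError(f"missing rescale slope/intercept in {getattr(ds, 'filename', '?')}")
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None or len(spacing) != 2:
            raise ValueError(f"missing pixel spacing in {getattr(ds, 'filename', '?')}")
        spacing_y, spacing_x = float(spacing[0]), float(spacing[1])  # DICOM: (row, col)
        hu = ds.pixel_array.astype(np.float64) * float(slope) + float(intercept)
        if ref_spacing is None:
            ref_spacing = (spacing_x, spacing_y)
            ref_shape = hu.shape
        elif (spacing_x, spacing_y) != ref_spacing:
            raise ValueError(f"inconsistent pixel spacing across series: {(spacing_x, spacing_y)} vs {ref_spacing}")
        elif hu.shape != ref_shape:
            raise ValueError(f"inconsistent slice shape across series: {hu.shape} vs {ref_shape}")
        slices.append(HUImage(hu, spacing_x, spacing_y, slice_index=k))
    return slices


# ---------------------------------------------------------------------------
# Plain-text matrix fixture format
# ---------------------------------------------------------------------------
# Header lines are '#'-prefixed 'key: value' pairs; the body is one
# whitespace-separated row of the matrix per line.  Values are written with
# 17 significant digits so float64 grids round-trip losslessly.

_KIND_BY_TYPE = {HUImage: "hu", AttenuationImage: "mu"}
_TYPE_BY_KIND = {"hu": HUImage, "mu": AttenuationImage}


def write_matrix_fixture(
    image: HUImage | AttenuationImage,
    path: str | os.PathLike,
    extra_header: dict[str, str] | None = None,
) -> None:
    """Write a slice to the plain-text matrix fixture format."""
    kind = _KIND_BY_TYPE[type(image)]
    lines = [
        "# wetspr matrix fixture v1",
        f"# kind: {kind}",
        f"# spacing_x: {image.spacing_x!r}",
        f"# spacing_y: {image.spacing_y!r}",
        f"# slice_index: {image.slice_index}",
    ]
    for key, value in (extra_header or {}).items():
        lines.append(f"# {key}: {value}")
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in image.pixels)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_matrix_fixture(path: str | os.PathLike) -> HUImage | AttenuationImage:
    """Read a slice written by :func:`write_matrix_fixture`.

    Unknown header keys (e.g. provenance entries) are ignored.  Raises on a
    missing spacing header or a ragged matrix body.
    """
    text = Path(path).read_text()
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            content = stripped.lstrip("#").strip()
            if ":" in content:
                key, _, value = content.partition(":")
                header[key.strip()] = value.strip()
            continue
        try:
            rows.append([float(tok) for tok in stripped.split()])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed matrix row at line {lineno}") from exc
    if "spacing_x" not in header or "spacing_y" not in header:
        raise ValueError(f"{path}: fixture header missing spacing_x/spacing_y")
    if not rows:
        raise ValueError(f"{path}: fixture has no matrix body")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged matrix body (rows of unequal length)")
    cls = _TYPE_BY_KIND.get(header.get("kind", "hu"))
    if cls is None:
        raise ValueError(f"{path}: unknown fixture kind {header.get('kind')!r}")
    return cls(
        np.array(rows, dtype=np.float64),
        spacing_x=float(header["spacing_x"]),
        spacing_y=float(header["spacing_y"]),
        slice_index=int(header.get("slice_index", 0)),
    )
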