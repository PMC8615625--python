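"""Calibrated image and table I/O.

All images are carried as plain numpy arrays with explicit physical
calibration (µm per pixel, µm per z-slice) supplied by the caller; TIFF
metadata is never trusted as the source of calibration.  Coordinates are
0-based array indices; the physical position of a pixel is its center,
``(index + 0.5) * pixel_size``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ZStack",
    "PlaneImage",
    "BinaryMask",
    "MASK_SEMANTICS",
    "read_stack",
    "write_stack",
    "read_plane",
    "read_mask",
    "read_labels",
    "write_labels",
    "write_nucleus_table",
    "read_nucleus_table",
    "NUCLEUS_TABLE_COLUMNS",
]

#: Allowed interpretations of a binary mask channel.
MASK_SEMANTICS = frozenset(
    {"vessel_perfused", "pimonidazole_pos", "brdu_pos", "nucleus_label_source"}
)


def _check_calibration(pixel_size: float, z_step: float | None = None) -> None:
    if not (pixel_size > 0):
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    if z_step is not None and not (z_step > 0):
        raise ValueError(f"z_step must be positive, got {z_step}")


def _check_intensities(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite intensities")
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative intensities")


@dataclass
class ZStack:
    """A calibrated single-channel 3-D acquisition, axes (z, y, x)."""

    voxels: np.ndarray
    z_step: float  # µm between slices
    pixel_size: float  # µm per pixel in y and x
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("ZStack.voxels must be a 3-D (z, y, x) array with >= 1 slice")
        _check_calibration(self.pixel_size, self.z_step)
        _check_intensities(self.voxels, "ZStack.voxels")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.voxels.shape[1:]


@dataclass
class PlaneImage:
    """A calibrated single-channel 2-D image."""

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("PlaneImage.pixels must be 2-D")
        _check_calibration(self.pixel_size)
        _check_intensities(self.pixels, "PlaneImage.pixels")


@dataclass
class BinaryMask:
    """A calibrated boolean mask with a declared biological meaning."""

    pixels: np.ndarray
    pixel_size: float
    semantics: str = "vessel_perfused"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask.pixels must be 2-D")
        _check_calibration(self.pixel_size)
        if self.semantics not in MASK_SEMANTICS:
            raise ValueError(
                f"unknown mask semantics {self.semantics!r}; expected one of {sorted(MASK_SEMANTICS)}"
            )


def check_same_frame(*images: ZStack | PlaneImage | BinaryMask) -> None:
    """Enforce that all channels of one section share 2-D shape and pixel size."""
    shapes = set()
    sizes = set()
    for im in images:
        if isinstance(im, ZStack):
            shapes.add(im.shape_2d)
        else:
            shapes.add(im.pixels.shape)
        sizes.add(float(im.pixel_size))
    if len(shapes) > 1:
        raise ValueError(f"channels disagree in 2-D shape: {sorted(shapes)}")
    if len(sizes) > 1:
        raise ValueError(f"channels disagree in pixel_size: {sorted(sizes)}")


def read_stack(path: str | os.PathLike, pixel_size: float, z_step: float,
               channel_name: str = "") -> ZStack:
    """Read a single- or multi-page TIFF as a calibrated z-stack.

    Calibration is explicit user input; a mismatching resolution tag in the
    file is ignored (the file tag is frequently absent or wrong on exported
    microscopy TIFFs).
    """
    _check_calibration(pixel_size, z_step)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # zero pages / truncated file
        raise ValueError(f"not a readable TIFF: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a single-channel stack, got shape {arr.shape}")
    return ZStack(voxels=arr, z_step=z_step, pixel_size=pixel_size,
                  channel_name=channel_name)


def write_stack(stack: ZStack, path: str | os.PathLike) -> None:
    """Write a z-stack as a multi-page TIFF (one page per slice)."""
    tifffile.imwrite(path, stack.voxels)


def read_plane(path: str | os.PathLike, pixel_size: float, channel_name: str = "") -> PlaneImage:
    stack = read_stack(path, pixel_size=pixel_size, z_step=1.0, channel_name=channel_name)
    if stack.n_slices != 1:
        raise ValueError(f"expected a single-plane TIFF, got {stack.n_slices} pages")
    return PlaneImage(pixels=stack.voxels[0], pixel_size=pixel_size, channel_name=channel_name)


def read_mask(path: str | os.PathLike, pixel_size: float, semantics: str) -> BinaryMask:
    plane = read_plane(path, pixel_size=pixel_size)
    return BinaryMask(pixels=plane.pixels > 0, pixel_size=pixel_size, semantics=semantics)


def read_labels(path: str | os.PathLike) -> np.ndarray:
    """Read an integer label image (0 = background) from a 16-bit TIFF."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"label image must be 2-D, got shape {arr.shape}")
    return arr.astype(np.int32)


def write_labels(labels: np.ndarray, path: str | os.PathLike) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit label TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


#: Column schema of the per-nucleus output table (one row per nucleus).
NUCLEUS_TABLE_COLUMNS = [
    "section_id",      # section (slide) identifier
    "tumor_id",        # tumor the section came from
    "arm_id",          # treatment arm
    "roi_id",          # region-of-interest index within the section
    "nucleus_id",      # label of the nucleus within the ROI
    "centroid_y_px",   # 0-based array row of the nucleus centroid
    "centroid_x_px",   # 0-based array column of the nucleus centroid
    "area_um2",        # nucleus area, µm²
    "distance_um",     # distance of centroid to nearest perfused-vessel pixel, µm
    "category",        # distance category label (see geometry module)
    "n_foci",          # detected foci count
    "cfoci",           # size-corrected foci count
    "median_mutual_distance_um",  # median pairwise focus distance; NaN when < 2 foci
    "mean_area_used_um2",         # stratum mean area used in the cfoci correction
    "sampled",         # 1 if the nucleus was in the random per-category sample
    "analyzable",      # 1 if the nucleus passed the analyzable-cell rule
]


def write_nucleus_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-nucleus table as RFC-4180 CSV with a header row.

    ``records`` may carry extra columns (marker intensities, truth columns);
    the documented columns are placed first, extras follow in their input
    order.  Distances are rounded to 2 decimals of a µm on output.
    """
    df = records.copy()
    for col in NUCLEUS_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if len(df) and df["section_id"].nunique() > 1:
        raise ValueError("a nucleus table holds one section; got multiple section_id values")
    extras = [c for c in df.columns if c not in NUCLEUS_TABLE_COLUMNS]
    df = df[NUCLEUS_TABLE_COLUMNS + extras]
    df["distance_um"] = df["distance_um"].round(2)
    df.to_csv(path, index=False, lineterminator="\r\n", float_format="%.10g")


def read_nucleus_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
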