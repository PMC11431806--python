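"""Per-nucleus geometry from integer label masks.

A label mask (0 = background, k >= 1 = nucleus id, e.g. a CellProfiler
export) defines each nucleus as an 8-connected pixel region.  From it we
measure the three raw quantities the morphological features need: area
``Ar`` (pixel count), perimeter ``Peri`` (Crofton boundary-length
estimate, so that digital disks have isoperimetric quotient ~ 1), and the
enclosed hollow-pixel count ``Hol`` — non-chromatin pixels strictly inside
the nucleus, i.e. 4-connected components of low-hematoxylin pixels that do
not touch the nucleus boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled nucleus segmentation raster."""

    labels: np.ndarray  # 2-D, int, >= 0
    resolution: float | None = None  # microns per pixel, if known

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label mask must be single-channel 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label mask must have integer dtype, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValueError("label mask must not contain negative labels")

    def nucleus_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


@dataclass(frozen=True)
class NucleusGeometry:
    """Raw per-nucleus measurements: area, perimeter, hollow count."""

    nucleus_id: int
    ar: int  # area, pixels
    peri: float  # perimeter, pixel units
    hol: int | None = None  # enclosed hollow pixels; None until counted

    def __post_init__(self) -> None:
        if self.ar < 1:
            raise ValueError("area must be >= 1 pixel")
        if self.peri <= 0:
            raise ValueError("perimeter must be positive")
        if self.hol is not None and not 0 <= self.hol <= self.ar:
            raise ValueError("hollow count must lie in [0, area]")

    def with_hol(self, hol: int) -> "NucleusGeometry":
        return replace(self, hol=int(hol))


def read_label_mask(path: str | Path, resolution: float | None = None) -> LabelMask:
    """Read a PNG or TIFF label mask; rejects float or multi-channel images."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: label masks must be single-channel, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label masks must be integer-typed, got {arr.dtype}")
    return LabelMask(labels=arr.astype(np.int64), resolution=resolution)


def _nucleus_mask(mask: LabelMask, nucleus_id: int) -> np.ndarray:
    """Binary mask of one nucleus; multi-fragment labels keep the largest
    8-connected fragment (with a warning)."""
    if nucleus_id <= 0:
        raise KeyError(f"nucleus id must be >= 1, got {nucleus_id}")
    binary = mask.labels == nucleus_id
    if not binary.any():
        raise KeyError(f"nucleus id {nucleus_id} not present in mask")
    comps, n = cc_label(binary, connectivity=2, return_num=True)
    if n > 1:
        warnings.warn(
            f"label {nucleus_id} has {n} fragments; keeping the largest",
            stacklevel=3,
        )
        sizes = np.bincount(comps.ravel())[1:]
        binary = comps == (int(np.argmax(sizes)) + 1)
    return binary


def region_geometry(mask: LabelMask, nucleus_id: int) -> NucleusGeometry:
    """Area and Crofton perimeter of one nucleus (hollow count unset)."""
    binary = _nucleus_mask(mask, nucleus_id)
    ar = int(binary.sum())
    peri = float(perimeter_crofton(binary, directions=4))
    if peri <= 0:  # single-pixel or degenerate regions
        peri = float(max(4.0, 2.0 * np.sqrt(np.pi * ar)))
    return NucleusGeometry(nucleus_id=nucleus_id, ar=ar, peri=peri)


def chromatin_map(
    h_channel: np.ndarray, mask: LabelMask, nucleus_id: int
) -> np.ndarray:
    """Split one nucleus into chromatin and non-chromatin pixels.

    Otsu's threshold on the hematoxylin concentrations inside the nucleus;
    pixels above the threshold (high hematoxylin) are chromatin
    foreground.  A constant-intensity nucleus has no threshold and is
    returned all-foreground.
    """
    if h_channel.shape != mask.labels.shape:
        raise ValueError("h_channel and mask must share their spatial shape")
    binary = _nucleus_mask(mask, nucleus_id)
    values = h_channel[binary]
    out = np.zeros_like(binary)
    if np.ptp(values) == 0:
        out[binary] = True
        return out
    thr = threshold_otsu(values)
    out[binary] = h_channel[binary] > thr
    return out


def count_hollow(mask: LabelMask, nucleus_id: int, chromatin: np.ndarray) -> int:
    """Count enclosed hollow pixels in one nucleus.

    A hollow pixel is a non-chromatin pixel inside the nucleus whose
    4-connected non-chromatin component touches neither a pixel outside
    the nucleus nor the image border — i.e. it lies in a hole fully
    surrounded by chromatin.
    """
    binary = _nucleus_mask(mask, nucleus_id)
    if chromatin.shape != binary.shape:
        raise ValueError("chromatin map and mask must share their spatial shape")
    holes = binary & ~chromatin.astype(bool)
    if not holes.any():
        return 0
    comps, n = cc_label(holes, connectivity=1, return_num=True)
    # Pixels outside the nucleus, with the image border treated as outside.
    outside = np.pad(~binary, 1, constant_values=True)
    near_outside = ndimage.binary_dilation(
        outside, structure=ndimage.generate_binary_structure(2, 1)
    )[1:-1, 1:-1]
    touching = np.unique(comps[near_outside & holes])
    sizes = np.bincount(comps.ravel(), minlength=n + 1)
    return int(holes.sum() - sizes[touching].sum())
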