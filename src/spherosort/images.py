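"""Image quantification: degradation area per cell, foreground area, and the
junction/cytosol line-profile ratio.

These reimplement the Fiji-macro recipes used for matrix-degradation assays:
automatic global thresholding (Otsu by default, the method name is recorded
in the output), connected-component filtering of small objects, pixel-size
conversion to µm², and bilinear sampling along a 10 µm line centered on a
cell-cell junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters

__all__ = [
    "DegradationQuant",
    "LineProfile",
    "quantify_degradation",
    "quantify_area",
    "junction_ratio",
]

_THRESHOLDERS = {
    "otsu": filters.threshold_otsu,
    "li": filters.threshold_li,
    "yen": filters.threshold_yen,
    "mean": filters.threshold_mean,
    "triangle": filters.threshold_triangle,
}

DEFAULT_MIN_OBJECT_AREA_PX2 = 4


@dataclass
class DegradationQuant:
    """Result of a degradation-area measurement on one field of view."""

    threshold_method: str
    threshold_value: float
    total_degraded_area: float  # µm²
    n_cells: int
    area_per_cell: float  # µm² / cell
    min_object_area: int  # px²
    n_objects: int


@dataclass
class LineProfile:
    """Intensity profile along a 10 µm line centered at a junction.

    ``cytosol_value`` is the intensity at arc position 0 µm, ``junction_value``
    at the 5 µm midpoint; ``ratio`` = junction / cytosol.
    """

    positions: np.ndarray  # µm along the line
    samples: np.ndarray
    cytosol_value: float
    junction_value: float
    ratio: float


def _as_2d(image: np.ndarray) -> np.ndarray:
    """Return a 2D image; stacks are max-projected along the first axis."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.max(axis=0)
    if img.ndim != 2:
        raise ValueError(f"expected 2D image or stack, got shape {img.shape}")
    return img.astype(float)


def _auto_threshold(img: np.ndarray, method: str) -> float:
    try:
        fn = _THRESHOLDERS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; choose from {sorted(_THRESHOLDERS)}"
        ) from None
    return float(fn(img))


def quantify_degradation(
    image: np.ndarray,
    n_cells: int,
    threshold_method: str = "otsu",
    polarity: str = "dark-holes",
    min_object_area: int = DEFAULT_MIN_OBJECT_AREA_PX2,
    pixel_size: float = 1.0,
) -> DegradationQuant:
    """Total degraded area per cell in a field of view.

    A global automatic threshold splits the gelatin channel; with the default
    ``dark-holes`` polarity, pixels below the threshold are degradation.
    8-connected components smaller than ``min_object_area`` px² are dropped
    as noise.  Areas are converted to µm² via ``pixel_size`` (µm/px) and
    divided by the manually counted ``n_cells``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    img = _as_2d(image)
    if img.max() == img.min():
        # blank field: no degradation signal to threshold
        return DegradationQuant(
            threshold_method=threshold_method,
            threshold_value=float(img.max()),
            total_degraded_area=0.0,
            n_cells=n_cells,
            area_per_cell=0.0,
            min_object_area=min_object_area,
            n_objects=0,
        )
    thr = _auto_threshold(img, threshold_method)
    fg = img < thr if polarity == "dark-holes" else img > thr
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    total_px = 0
    n_objects = 0
    if n:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = sizes >= min_object_area
        total_px = int(sizes[keep].sum())
        n_objects = int(keep.sum())
    total_um2 = total_px * pixel_size**2
    return DegradationQuant(
        threshold_method=threshold_method,
        threshold_value=thr,
        total_degraded_area=total_um2,
        n_cells=n_cells,
        area_per_cell=total_um2 / n_cells,
        min_object_area=min_object_area,
        n_objects=n_objects,
    )


def quantify_area(
    mask_or_image: np.ndarray,
    threshold_method: str = "otsu",
    pixel_size: float = 1.0,
) -> float:
    """Total foreground area in µm² (nuclei / spheroid area measurements).

    Boolean input is used as-is; grayscale input is max-projected if a stack
    and thresholded automatically (foreground = above threshold).
    """
    arr = np.asarray(mask_or_image)
    if arr.dtype == bool:
        return float(arr.sum()) * pixel_size**2
    img = _as_2d(arr)
    if img.max() == img.min():
        warnings.warn("image is constant; foreground area is 0")
        return 0.0
    thr = _auto_threshold(img, threshold_method)
    return float((img > thr).sum()) * pixel_size**2


def junction_ratio(
    image: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    pixel_size: float = 1.0,
    sampling_step: float = 0.1,
) -> LineProfile:
    """Junction/cytosol intensity ratio along a 10 µm line.

    ``line`` gives the endpoints (x, y) in µm; the segment must be 10 µm long
    (the junction sits at the 5 µm midpoint) and lie fully inside the image.
    Intensities are sampled by bilinear interpolation every ``sampling_step``
    µm; pixel centers are at integer pixel coordinates.
    """
    img = _as_2d(image)
    (x1, y1), (x2, y2) = line
    length = float(np.hypot(x2 - x1, y2 - y1))
    if not np.isclose(length, 10.0, atol=1e-6):
        raise ValueError(f"line must be 10 µm long, got {length:.4f} µm")

    n = int(round(length / sampling_step)) + 1
    s = np.linspace(0.0, length, n)
    xs = (x1 + (x2 - x1) * s / length) / pixel_size
    ys = (y1 + (y2 - y1) * s / length) / pixel_size
    h, w = img.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        raise ValueError("line endpoints fall outside the image")
    # map_coordinates takes (row, col) = (y, x); order=1 is bilinear
    samples = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")

    cytosol = float(np.interp(0.0, s, samples))
    junction = float(np.interp(5.0, s, samples))
    if cytosol == 0:
        raise ValueError("cytosol intensity is 0; ratio undefined")
    return LineProfile(
        positions=s,
        samples=samples,
        cytosol_value=cytosol,
        junction_value=junction,
        ratio=junction / cytosol,
    )
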