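"""Axon-density contour quantification and mask-based colocalization calls.

Density pipeline: an 8-bit image is background-subtracted by morphological
top-hat (image minus its opening with a disk structuring element),
binarized at a strict intensity threshold (default > 120), cleaned of
connected components of two pixels or fewer (8-connectivity by default),
divided into 20 x 20 px bins whose above-threshold pixels are counted
exactly, smoothed with a normalized moving average over a
100 x 100 px (5 x 5 bin) neighborhood with reflective edge padding, and
contoured at evenly spaced iso-levels.

Colocalization: for every labeled mask the fraction of pixels that are
co-intense in both channels (each channel exceeding its own threshold,
Otsu by default) is computed; a mask is called positive when at least 65%
of its pixels are co-intense. Soma area is the mask pixel count times the
pixel area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "ColocalizationCall",
    "subtract_background",
    "binarize_and_clean",
    "bin_and_smooth",
    "contour_from_density",
    "call_colocalization",
]

DEFAULT_BINARIZE_THRESHOLD = 120
DEFAULT_MIN_COMPONENT_PIXELS = 3
DEFAULT_BIN_PX = 20
DEFAULT_SMOOTH_PX = 100
DEFAULT_COLOC_MIN_FRACTION = 0.65


@dataclass
class DensityGrid:
    """Binned above-threshold pixel counts and their smoothed version."""

    bin_counts: np.ndarray
    smoothed: np.ndarray
    bin_px: int

    def __post_init__(self) -> None:
        if self.bin_counts.shape != self.smoothed.shape:
            raise ValueError("bin_counts and smoothed shapes differ")


@dataclass
class ColocalizationCall:
    mask_id: int
    n_pixels: int
    n_co_intense: int
    fraction: float
    positive: bool
    soma_area_px: int
    soma_area_um2: float | None = None


def subtract_background(img: np.ndarray, radius: int = 15) -> np.ndarray:
    """Top-hat background subtraction with a disk structuring element.

    Equivalent to subtracting the morphological opening of the image;
    output clipped to the 8-bit range.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape[:2]) / 2:
        raise ValueError("structuring element radius too large for the image")
    selem = morphology.disk(radius)
    opened = morphology.opening(img, selem)
    out = img.astype(np.int16) - opened.astype(np.int16)
    return np.clip(out, 0, 255).astype(np.uint8)


def binarize_and_clean(
    img: np.ndarray,
    threshold: int = DEFAULT_BINARIZE_THRESHOLD,
    min_component_pixels: int = DEFAULT_MIN_COMPONENT_PIXELS,
    connectivity: int = 2,
) -> np.ndarray:
    """Strict-threshold binarization with small-component removal.

    A pixel is retained iff its intensity is strictly greater than
    ``threshold``; connected components smaller than
    ``min_component_pixels`` (default: only components of more than two
    pixels are kept) are removed. ``connectivity=2`` counts diagonals
    (8-connectivity); 1 gives 4-connectivity.
    """
    mask = np.asarray(img) > threshold
    labels = measure.label(mask, connectivity=connectivity)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component_pixels
    keep[0] = False
    return keep[labels]


def bin_and_smooth(
    mask: np.ndarray,
    bin_px: int = DEFAULT_BIN_PX,
    smooth_px: int = DEFAULT_SMOOTH_PX,
    smooth_unit: str = "pixels",
) -> DensityGrid:
    """Count retained pixels per bin and smooth with a normalized window.

    The image is zero-padded up to a bin multiple, so the bin counts sum
    exactly to the retained pixel count. The smoothing window is
    ``smooth_px`` pixels (converted to a bin-sized neighborhood, default
    100 px = 5 x 5 bins) when ``smooth_unit='pixels'``, or a
    ``smooth_px x smooth_px`` *bin* window when ``smooth_unit='bins'``;
    edges are padded by reflection and the kernel is mass-preserving in
    the interior.
    """
    if min(mask.shape) < bin_px:
        raise ValueError("mask smaller than one bin")
    m = np.asarray(mask, dtype=np.int64)
    h = -(-m.shape[0] // bin_px) * bin_px
    w = -(-m.shape[1] // bin_px) * bin_px
    padded = np.zeros((h, w), dtype=np.int64)
    padded[: m.shape[0], : m.shape[1]] = m
    counts = padded.reshape(h // bin_px, bin_px, w // bin_px, bin_px).sum(axis=(1, 3))
    if smooth_unit == "pixels":
        win = max(int(round(smooth_px / bin_px)), 1)
    elif smooth_unit == "bins":
        win = max(int(smooth_px), 1)
    else:
        raise ValueError("smooth_unit must be 'pixels' or 'bins'")
    smoothed = ndimage.uniform_filter(counts.astype(float), size=win, mode="reflect")
    return DensityGrid(bin_counts=counts, smoothed=smoothed, bin_px=bin_px)


def contour_from_density(
    grid: DensityGrid, n_levels: int = 5
) -> dict[float, list[np.ndarray]]:
    """Iso-level polylines from the smoothed density, in image coordinates.

    Levels are evenly spaced strictly between 0 and the smoothed maximum;
    each polyline is an (n, 2) array of (row, col) image-space pixel
    coordinates (bin centers scaled back by the bin size). A flat grid
    yields no contours, with a warning.
    """
    s = grid.smoothed
    vmax = float(s.max())
    if vmax <= s.min():
        logger.warning("flat density grid: no contours")
        return {}
    levels = np.linspace(0.0, vmax, n_levels + 2)[1:-1]
    out: dict[float, list[np.ndarray]] = {}
    for lv in levels:
        polys = measure.find_contours(s, level=lv)
        out[float(lv)] = [
            (p + 0.5) * grid.bin_px for p in polys
        ]
    return out


def call_colocalization(
    ch1: np.ndarray,
    ch2: np.ndarray,
    masks: np.ndarray,
    thresholds: tuple[float, float] | None = None,
    min_fraction: float = DEFAULT_COLOC_MIN_FRACTION,
    pixel_size_um: float | None = None,
    expected_ids: list[int] | None = None,
) -> list[ColocalizationCall]:
    """Per-mask two-channel colocalization calls.

    A pixel is co-intense when both channels strictly exceed their
    per-channel thresholds (Otsu per channel when ``thresholds`` is None).
    A mask is positive when at least ``min_fraction`` (default 65%) of its
    pixels are co-intense. ``masks`` is an integer label image; label 0 is
    background. Empty masks raise, naming the mask id.
    """
    ch1 = np.asarray(ch1)
    ch2 = np.asarray(ch2)
    masks = np.asarray(masks)
    if not (ch1.shape == ch2.shape == masks.shape):
        raise ValueError("channel and mask shapes differ")
    if thresholds is None:
        thresholds = (float(threshold_otsu(ch1)), float(threshold_otsu(ch2)))
    co = (ch1 > thresholds[0]) & (ch2 > thresholds[1])
    present = [int(m) for m in np.unique(masks) if m != 0]
    if expected_ids is not None:
        empty = sorted(set(expected_ids) - set(present))
        if empty:
            raise ValueError(f"mask {empty[0]} is empty")
        present = sorted(expected_ids)
    calls = []
    for mid in present:
        sel = masks == mid
        n = int(sel.sum())
        n_co = int(co[sel].sum())
        frac = n_co / n
        calls.append(
            ColocalizationCall(
                mask_id=int(mid), n_pixels=n, n_co_intense=n_co,
                fraction=frac, positive=frac >= min_fraction,
                soma_area_px=n,
                soma_area_um2=(n * pixel_size_um ** 2 if pixel_size_um else None),
            )
        )
    return calls
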