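"""Radiograph preprocessing: ROI crop, median denoising, histogram equalization.

Raw esophagrams (typically ~1012 x 974) are mostly background; the lesion is
isolated by cropping a fixed 140 x 240 region of interest, denoised with a
median filter, and contrast-stretched with global histogram equalization.
The three steps compose into :func:`preprocess_pipeline`, whose output feeds
every feature extractor.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import GrayImage, RoiSpec

__all__ = ["crop_roi", "median_filter", "equalize_histogram", "preprocess_pipeline"]


def crop_roi(img: GrayImage, roi: RoiSpec) -> GrayImage:
    """Extract the rectangular ROI; pixel values are copied unchanged.

    Raises
    ------
    ValueError
        If the ROI extends past an image edge (the offending edge is named).
    """
    rows, cols = img.shape
    if roi.top + roi.height > rows:
        raise ValueError(
            f"ROI bottom edge {roi.top + roi.height} exceeds image height {rows}"
        )
    if roi.left + roi.width > cols:
        raise ValueError(
            f"ROI right edge {roi.left + roi.width} exceeds image width {cols}"
        )
    out = img.pixels[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width].copy()
    return GrayImage(out, bit_depth=img.bit_depth, id=img.id)


def median_filter(img: GrayImage, kernel: int = 3) -> GrayImage:
    """Median-filter with a ``kernel x kernel`` window and reflected borders.

    Reflect padding avoids the darkened frame a zero-padded filter would
    create, which would otherwise bias co-occurrence statistics near edges.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"median kernel must be an odd integer >= 3, got {kernel}")
    out = ndimage.median_filter(img.pixels, size=kernel, mode="reflect")
    return GrayImage(out, bit_depth=img.bit_depth, id=img.id)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Global histogram equalization by the standard CDF remap.

    Each input level ``v`` maps to ``round((L - 1) * cdf(v))`` where ``cdf``
    is the empirical cumulative distribution of pixel intensities (inclusive
    of ``v``). The mapping is monotone non-decreasing, so gray-level order is
    preserved; a constant image passes through as a constant.
    """
    levels = img.levels
    pix = img.pixels
    hist = np.bincount(pix.ravel(), minlength=levels)
    cdf = np.cumsum(hist) / pix.size
    lut = np.round((levels - 1) * cdf).astype(pix.dtype)
    return GrayImage(lut[pix], bit_depth=img.bit_depth, id=img.id)


def preprocess_pipeline(img: GrayImage, roi: RoiSpec | None = None, kernel: int = 3) -> GrayImage:
    """Crop -> median filter -> histogram equalization, in that order.

    ``roi=None`` keeps the full frame (identity crop), which is the default
    for synthetic inputs generated directly at ROI size.
    """
    if roi is None:
        roi = RoiSpec(0, 0, *img.shape)
    return equalize_histogram(median_filter(crop_roi(img, roi), kernel=kernel))
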