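"""Core image container and disk I/O.

A radiograph is represented as a :class:`GrayImage`: a 2-D integer array of
pixel intensities together with its bit depth (the number of representable
gray levels is ``2**bit_depth``) and a free-text identifier used to join
images with region-of-interest sidecar files and class labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = ["GrayImage", "RoiSpec", "read_image", "write_image", "as_pixels"]


@dataclass
class GrayImage:
    """A 2-D grayscale image with bit-depth and provenance metadata.

    Parameters
    ----------
    pixels
        Integer intensity matrix, shape ``(rows, cols)``.
    bit_depth
        Bits per pixel; intensities live in ``[0, 2**bit_depth - 1]``.
    id
        Free-text label, typically the source file stem.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D intensity matrix, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError(f"image must be at least 3x3, got {self.pixels.shape}")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > self.levels - 1:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.levels - 1}] for bit_depth={self.bit_depth}"
            )

    @property
    def levels(self) -> int:
        """Number of representable gray levels, ``2**bit_depth``."""
        return 2**self.bit_depth

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest in pixel coordinates.

    Defaults give the 140-row x 240-column lesion window used throughout the
    pipeline (rows x cols, matrix convention).
    """

    top: int = 0
    left: int = 0
    height: int = 140
    width: int = 240

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI extents must be positive, got {self.height}x{self.width}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"ROI offsets must be non-negative, got top={self.top}, left={self.left}")


def as_pixels(img: "GrayImage | np.ndarray") -> np.ndarray:
    """Return the raw pixel matrix from a GrayImage or pass an array through."""
    if isinstance(img, GrayImage):
        return img.pixels
    return np.asarray(img)


def read_image(path: str | Path, id: str | None = None) -> GrayImage:
    """Read a PNG/TIFF grayscale image as an 8-bit :class:`GrayImage`.

    16-bit inputs are rescaled to 8 bits (a warning is logged); color inputs
    are converted to luminance.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode == "I;16" or im.mode == "I":
            arr = np.asarray(im, dtype=np.float64)
            logger.warning("rescaling 16-bit image %s to 8-bit", path)
            warnings.warn(f"rescaling 16-bit image {path} to 8-bit", stacklevel=2)
            hi = arr.max()
            arr = np.round(arr / hi * 255.0) if hi > 0 else arr
            arr = arr.astype(np.uint8)
        else:
            arr = np.asarray(im.convert("L"))
    return GrayImage(arr, bit_depth=8, id=id if id is not None else path.stem)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale image to PNG/TIFF (by file extension)."""
    Image.fromarray(np.asarray(img.pixels, dtype=np.uint8), mode="L").save(Path(path))
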