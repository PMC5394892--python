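"""Lempel-Ziv (Kaspar-Schuster) complexity of binarized images.

True Kolmogorov complexity is uncomputable; the Kaspar-Schuster production
count is its standard computable proxy for finite binary sequences. The
parser scans left to right, extending the current word while it can be
copied from the already-seen history, and counts one production each time an
insertion closes a word. The count is normalized by ``n / log2(n)``, the
asymptotic production count of a random sequence, so values are comparable
across image sizes and tend to 1 for incompressible input.

The image-level feature: binarize the image, compute the normalized
complexity of each row's bit sequence, binarize that row-complexity vector
at its median, and return the normalized complexity of the resulting
sequence — one scalar per image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .image import GrayImage, as_pixels

logger = logging.getLogger(__name__)

__all__ = ["ComplexityResult", "binarize", "lz_complexity", "kc_feature"]


@dataclass(frozen=True)
class ComplexityResult:
    """Kaspar-Schuster parse summary for one binary sequence."""

    production_count: int
    normalized: float
    n: int


def binarize(img: GrayImage | np.ndarray, method: str = "global_mean") -> np.ndarray:
    """Threshold an image to a bit matrix: pixel >= threshold -> 1, else 0.

    ``global_mean`` thresholds at the image mean, ``otsu`` at the Otsu
    optimum. A constant image has no content on either side of its
    threshold and maps to all zeros by convention (logged).
    """
    pix = as_pixels(img)
    if pix.min() == pix.max():
        logger.info("constant image: binarization returns all zeros by convention")
        return np.zeros(pix.shape, dtype=np.uint8)
    if method == "global_mean":
        thr = pix.mean()
    elif method == "otsu":
        thr = threshold_otsu(pix)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return (pix >= thr).astype(np.uint8)


def lz_complexity(bits: "np.ndarray | str | list[int]") -> ComplexityResult:
    """Kaspar-Schuster production count of a binary sequence.

    The sequence is parsed into consecutive words: each word is grown while
    the candidate (all of it but its final symbol appended) occurs as a
    substring of the sequence prefix ending just before that final symbol;
    the symbol that breaks copyability closes the word (one insertion). The
    trailing word counts whether or not it was closed by an insertion.

    ``normalized`` is ``production_count / (n / log2 n)`` for ``n >= 2``
    (and equals ``production_count`` for ``n == 1``).
    """
    if isinstance(bits, str):
        s = bits
    else:
        arr = np.asarray(bits).ravel()
        s = "".join("1" if b else "0" for b in arr.astype(int))
    if not set(s) <= {"0", "1"}:
        raise ValueError("sequence must be binary")
    n = len(s)
    if n == 0:
        raise ValueError("cannot parse an empty sequence")

    count = 0
    i = 0
    while i < n:
        k = 1
        # s[i:i+k] is copyable iff it occurs inside s[:i+k-1], i.e. a copy
        # can start before i and run forward (overlap into the word allowed)
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        # extension failed: k-1 copyable symbols + 1 inserted close the word;
        # a trailing fully-copyable word (i+k > n) counts as-is
        count += 1
        i += min(k, n - i)

    normalized = count / (n / np.log2(n)) if n >= 2 else float(count)
    return ComplexityResult(production_count=count, normalized=float(normalized), n=n)


def kc_feature(img: GrayImage | np.ndarray, method: str = "global_mean") -> float:
    """Single image-complexity scalar via the row-complexity-of-complexities scheme.

    Steps: (i) binarize the image; (ii) normalized Lempel-Ziv complexity of
    each row -> row-complexity vector; (iii) binarize that vector at its
    median (ties, values equal to the median, map to 1); (iv) normalized
    complexity of the resulting sequence.
    """
    bits = binarize(img, method=method)
    row_c = np.array([lz_complexity(row).normalized for row in bits])
    med = np.median(row_c)
    row_bits = (row_c >= med).astype(np.uint8)
    return lz_complexity(row_bits).normalized
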