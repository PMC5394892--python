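"""Wavelet-domain frequency features.

A 4-level separable 2-D discrete wavelet transform splits the image into a
deep approximation band (A4) and horizontal / vertical / diagonal detail
bands per level. The finest (level-1) details carry mostly acquisition noise
and are discarded; the frequency block is the mean and (population) variance
of A4 and of the nine retained detail subbands at levels 2-4, 20 values in
total.

The default basis is Haar with periodized boundary extension, which keeps
the transform orthogonal on dyadic image sizes (total coefficient energy
equals image energy) and makes hand-worked 2x2 block expansions exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .image import GrayImage, as_pixels

LEVELS = 4
RETAINED_DETAIL_LEVELS = (2, 3, 4)
_BANDS = ("H", "V", "D")

FREQUENCY_FEATURE_NAMES: tuple[str, ...] = ("A4_mean", "A4_var") + tuple(
    f"D{lvl}{band}_{stat}"
    for lvl in RETAINED_DETAIL_LEVELS
    for band in _BANDS
    for stat in ("mean", "var")
)

__all__ = ["WaveletPyramid", "dwt4", "frequency_block", "FREQUENCY_FEATURE_NAMES"]


@dataclass
class WaveletPyramid:
    """Multilevel 2-D DWT: deepest approximation plus per-level detail triples.

    ``details[lvl]`` is the ``(H, V, D)`` triple at decomposition level
    ``lvl`` (1 = finest, ``levels`` = coarsest).
    """

    approximation: np.ndarray
    details: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str = "haar"
    levels: int = LEVELS
    mode: str = "periodization"

    def __post_init__(self) -> None:
        if set(self.details) != set(range(1, self.levels + 1)):
            raise ValueError(
                f"expected detail triples for levels 1..{self.levels}, got {sorted(self.details)}"
            )


def dwt4(
    img: GrayImage | np.ndarray,
    wavelet_name: str = "haar",
    levels: int = LEVELS,
    mode: str = "periodization",
) -> WaveletPyramid:
    """Multilevel 2-D DWT, recursing on the approximation band only.

    Raises
    ------
    ValueError
        If either image side is too small for ``levels`` halvings
        (minimum ``2**levels`` pixels per side).
    """
    pix = as_pixels(img).astype(np.float64)
    min_side = 2**levels
    if min(pix.shape) < min_side:
        raise ValueError(
            f"image {pix.shape} too small for a {levels}-level transform "
            f"(needs >= {min_side} px per side)"
        )
    coeffs = pywt.wavedec2(pix, wavelet_name, mode=mode, level=levels)
    # pywt orders detail triples deepest-first; re-key by decomposition level
    details = {levels - k: tuple(coeffs[k + 1]) for k in range(levels)}
    return WaveletPyramid(
        approximation=coeffs[0],
        details=details,
        wavelet_name=wavelet_name,
        levels=levels,
        mode=mode,
    )


def frequency_block(pyr: WaveletPyramid) -> dict[str, float]:
    """Mean and population variance of A4 and the level 2-4 detail subbands.

    Level-1 details are discarded; the 20 values follow the frozen order of
    :data:`FREQUENCY_FEATURE_NAMES`.
    """
    if pyr.levels != LEVELS:
        raise ValueError(f"frequency block requires a {LEVELS}-level pyramid, got {pyr.levels}")
    out: dict[str, float] = {
        "A4_mean": float(pyr.approximation.mean()),
        "A4_var": float(pyr.approximation.var()),
    }
    for lvl in RETAINED_DETAIL_LEVELS:
        for band, sub in zip(_BANDS, pyr.details[lvl]):
            out[f"D{lvl}{band}_mean"] = float(sub.mean())
            out[f"D{lvl}{band}_var"] = float(sub.var())
    return out
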