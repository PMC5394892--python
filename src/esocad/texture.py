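"""Gray-level co-occurrence texture features.

The GLCM ``P(i, j | d, theta)`` is the joint distribution of gray-level pairs
at pixel displacement distance ``d`` and angle ``theta``. Four Haralick
statistics (contrast, correlation, energy, homogeneity) are computed at the
four standard angles {0, 45, 90, 135} degrees with ``d = 1``, yielding the
16-element texture block.

Angle-to-displacement convention, in (row, col) offsets:

====== ============
theta  (drow, dcol)
====== ============
0      (0, +d)
45     (-d, +d)
90     (-d, 0)
135    (-d, -d)
====== ============
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import GrayImage, as_pixels

logger = logging.getLogger(__name__)

ANGLES = (0, 45, 90, 135)
STATS = ("contrast", "correlation", "energy", "homogeneity")

#: displacement unit vectors per supported angle, (row, col)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

TEXTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{angle}" for stat in STATS for angle in ANGLES
)

__all__ = [
    "CooccurrenceMatrix",
    "quantize_levels",
    "glcm",
    "haralick_stats",
    "texture_block",
    "TEXTURE_FEATURE_NAMES",
    "ANGLES",
]


@dataclass
class CooccurrenceMatrix:
    """Normalized gray-level pair distribution at a fixed displacement."""

    P: np.ndarray
    d: int
    theta: int
    L: int

    @property
    def marginal_x(self) -> np.ndarray:
        """Row marginal p_x(i) = sum_j P(i, j)."""
        return self.P.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        """Column marginal p_y(j) = sum_i P(i, j)."""
        return self.P.sum(axis=0)

    def moments(self) -> tuple[float, float, float, float]:
        """(mu_x, mu_y, sigma_x, sigma_y) of the marginal level distributions."""
        levels = np.arange(self.L)
        px, py = self.marginal_x, self.marginal_y
        mu_x = float(levels @ px)
        mu_y = float(levels @ py)
        sigma_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
        sigma_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))
        return mu_x, mu_y, sigma_x, sigma_y


def quantize_levels(img: GrayImage | np.ndarray, L: int, source_levels: int | None = None) -> np.ndarray:
    """Uniformly bin intensities in ``[0, source_levels - 1]`` into ``L`` levels.

    The mapping ``v -> floor(v * L / source_levels)`` is monotone
    non-decreasing and surjective onto ``{0..L-1}`` when the input spans the
    full range; ``L == source_levels`` is the identity.
    """
    if L < 2:
        raise ValueError(f"need at least 2 quantization levels, got {L}")
    if source_levels is None:
        source_levels = img.levels if isinstance(img, GrayImage) else 256
    pix = as_pixels(img).astype(np.int64)
    out = pix * L // source_levels
    return np.minimum(out, L - 1)


def glcm(
    img: GrayImage | np.ndarray,
    d: int = 1,
    theta: int = 0,
    L: int = 32,
    symmetric: bool = True,
    normalize: bool = True,
) -> CooccurrenceMatrix:
    """Count gray-level pairs at displacement ``d`` along angle ``theta``.

    The input must already be quantized to levels ``{0..L-1}`` (see
    :func:`quantize_levels`). With ``symmetric=True`` each pixel pair is
    counted in both orderings, making ``P`` symmetric; with
    ``normalize=True`` the counts are scaled to sum to 1.
    """
    if theta not in _OFFSETS:
        raise ValueError(f"unsupported angle {theta}; choose from {sorted(_OFFSETS)}")
    if d < 1:
        raise ValueError(f"displacement distance must be >= 1, got {d}")
    pix = as_pixels(img)
    if pix.max() >= L:
        raise ValueError(f"image has level {pix.max()} >= L={L}; quantize first")
    dr, dc = (d * o for o in _OFFSETS[theta])
    rows, cols = pix.shape

    # source window and displaced window sharing valid extent
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    a = pix[r0:r1, c0:c1].ravel()
    b = pix[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()

    P = np.zeros((L, L), dtype=np.float64)
    np.add.at(P, (a, b), 1.0)
    if symmetric:
        P = P + P.T
    if normalize:
        total = P.sum()
        if total > 0:
            P = P / total
    return CooccurrenceMatrix(P=P, d=d, theta=theta, L=L)


def haralick_stats(G: CooccurrenceMatrix) -> dict[str, float]:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    contrast    = sum (i - j)^2 P(i, j)
    correlation = (sum i*j*P(i, j) - mu_x mu_y) / (sigma_x sigma_y)
    energy      = sum P(i, j)^2
    homogeneity = sum P(i, j) / (1 + |i - j|)

    For a degenerate single-level image both marginal deviations vanish and
    correlation is defined as 0 (logged).
    """
    P = G.P
    i, j = np.indices(P.shape)
    mu_x, mu_y, sigma_x, sigma_y = G.moments()
    contrast = float(((i - j) ** 2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    if sigma_x == 0.0 or sigma_y == 0.0:
        logger.info("degenerate GLCM (zero marginal deviation): correlation set to 0")
        correlation = 0.0
    else:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / (sigma_x * sigma_y))
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def texture_block(
    img: GrayImage | np.ndarray,
    d: int = 1,
    L: int = 32,
    symmetric: bool = True,
) -> dict[str, float]:
    """The 16 GLCM texture features in frozen order (stat-major, then angle).

    Intensities are quantized to ``L`` levels, one symmetric normalized GLCM
    is built per angle, and the four Haralick statistics are read off each.
    """
    q = quantize_levels(img, L)
    per_angle = {theta: haralick_stats(glcm(q, d=d, theta=theta, L=L, symmetric=symmetric)) for theta in ANGLES}
    return {f"{stat}_{theta}": per_angle[theta][stat] for stat in STATS for theta in ANGLES}
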