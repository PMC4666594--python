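"""Texture features of grayscale genomic images: HOG and GLCM statistics.

The classifier input is a compact 36-element histogram-of-oriented-gradients
descriptor: a 2x2 grid of cells, 9 unsigned orientation bins per cell, and a
single L2-normalised block covering all four cells. The geometry is the
minimum that still captures gradient texture — genomic images can be as
short as two rows.

Haralick gray-level co-occurrence statistics (contrast and homogeneity)
quantify how heavy or soft an image's texture is; they are used to compare
the two affine renderings of the same gene, not as classifier features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "HogConfig",
    "TextureStats",
    "hog_features",
    "glcm_matrix",
    "glcm_stats",
    "rank_by_value",
]


@dataclass(frozen=True)
class HogConfig:
    """2x2 cells x 9 unsigned orientation bins = 36 features.

    Gradients use centred [-1, 0, 1] filters with replicated borders;
    orientations are unsigned (theta in [0, 180) degrees, bin centres at
    0, 20, ..., 160 with wraparound); magnitude votes are split linearly
    between the two nearest bin centres; cells are a floor-split 2x2 grid;
    the single block of all four cells (row-major, bins contiguous per
    cell) is L2-normalised with epsilon.
    """

    cells: tuple[int, int] = (2, 2)
    bins: int = 9
    epsilon: float = 1e-6

    @property
    def n_features(self) -> int:
        return self.cells[0] * self.cells[1] * self.bins


def _gradients(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # centred differences with replicated borders
    padded = np.pad(gray.astype(float), 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    return gx, gy


def hog_features(gray: np.ndarray, cfg: HogConfig = HogConfig()) -> np.ndarray:
    """Extract the 36-element HOG descriptor from a grayscale image."""
    gray = np.asarray(gray)
    h, w = gray.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2 for gradients")
    gx, gy = _gradients(gray)
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0  # unsigned orientation

    nb = cfg.bins
    bin_width = 180.0 / nb
    pos = theta / bin_width  # in [0, nb)
    lower = np.floor(pos).astype(int) % nb
    frac = pos - np.floor(pos)
    upper = (lower + 1) % nb

    cr, cc = cfg.cells
    row_edges = [h * i // cr for i in range(cr + 1)]
    col_edges = [w * j // cc for j in range(cc + 1)]

    out = np.zeros((cr, cc, nb))
    for i in range(cr):
        for j in range(cc):
            rs, re = row_edges[i], row_edges[i + 1]
            cs, ce = col_edges[j], col_edges[j + 1]
            m = mag[rs:re, cs:ce].ravel()
            lo = lower[rs:re, cs:ce].ravel()
            up = upper[rs:re, cs:ce].ravel()
            f = frac[rs:re, cs:ce].ravel()
            hist = np.bincount(lo, weights=m * (1 - f), minlength=nb)
            hist += np.bincount(up, weights=m * f, minlength=nb)
            out[i, j] = hist
    v = out.ravel()  # row-major cells, bins contiguous per cell
    return v / np.sqrt(np.sum(v**2) + cfg.epsilon**2)


@dataclass(frozen=True)
class TextureStats:
    contrast: float
    homogeneity: float


def glcm_matrix(
    gray: np.ndarray, levels: int = 8, offset: tuple[int, int] = (0, 1)
) -> np.ndarray:
    """Probability-normalised co-occurrence matrix of requantised gray levels.

    Pixels in [0, 255] are uniformly binned into ``levels`` classes; pairs
    are counted at the given (row, col) offset, non-symmetric.
    """
    gray = np.asarray(gray)
    q = (gray.astype(int) * levels) // 256
    dr, dc = offset
    h, w = gray.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError("image too small for the co-occurrence offset")
    src = q[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    dst = q[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
    counts = np.zeros((levels, levels))
    np.add.at(counts, (src.ravel(), dst.ravel()), 1.0)
    return counts / counts.sum()


def glcm_stats(
    gray: np.ndarray, levels: int = 8, offset: tuple[int, int] = (0, 1)
) -> TextureStats:
    """Haralick contrast and homogeneity of the horizontal-neighbour GLCM.

    contrast = sum p(i,j) (i-j)^2; homogeneity = sum p(i,j) / (1 + |i-j|).
    A constant image gives contrast 0 and homogeneity 1.
    """
    p = glcm_matrix(gray, levels=levels, offset=offset)
    i, j = np.indices(p.shape)
    contrast = float(np.sum(p * (i - j) ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    return TextureStats(contrast=contrast, homogeneity=homogeneity)


def rank_by_value(values: Sequence[float], descending: bool = True) -> list[int]:
    """Competition ranks 1..n (rank 1 = largest when descending); ties share
    the minimum rank."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if descending:
        return [int(1 + np.sum(v > x)) for x in v]
    return [int(1 + np.sum(v < x)) for x in v]
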