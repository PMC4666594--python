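"""Rendering affine DNA signals as windowed RGB "genomic images".

The 3xN channel signal is sliced into overlapping windows: each window of
``W`` positions becomes one image row, consecutive windows advance by
``stride = W - O`` positions, so a sequence of length N yields
``H = floor((N - W) / stride) + 1`` rows. Each of the three HxW channel
matrices is min-max normalised to [0, 255] independently and the triple is
composed into an RGB image; a BT.601 luma grayscale is derived for feature
extraction. Defaults (W=200, O=50) follow common windowed genomic-signal
practice.

Quantisation details matter downstream (GLCM and HOG consume the 8-bit
pixels), so rounding is fixed to half-away-from-zero and a constant channel
maps to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .encoding import AffineSignal

__all__ = [
    "ImagingConfig",
    "GenomicImage",
    "window_signal",
    "normalize_to_gray",
    "compose_rgb",
    "to_grayscale",
    "signal_to_image",
    "save_png",
    "load_png",
    "BT601_WEIGHTS",
]

BT601_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class ImagingConfig:
    """Window geometry: width ``window``, ``overlap`` positions shared by
    consecutive windows. Trailing positions that do not fill a complete
    window are discarded unless ``pad=True`` (zero padding)."""

    window: int = 200
    overlap: int = 50
    pad: bool = False

    def __post_init__(self) -> None:
        if not (self.window > self.overlap >= 0):
            raise ValueError("require window > overlap >= 0")

    @property
    def stride(self) -> int:
        return self.window - self.overlap

    def n_windows(self, n: int) -> int:
        if n < self.window:
            raise ValueError(
                f"sequence length {n} shorter than one window ({self.window})"
            )
        return (n - self.window) // self.stride + 1


@dataclass(frozen=True)
class GenomicImage:
    """HxWx3 8-bit image plus provenance (transform kind and window config)."""

    rgb: np.ndarray
    transform: str
    config: ImagingConfig

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("rgb must be HxWx3")
        if rgb.min() < 0 or rgb.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        object.__setattr__(self, "rgb", rgb.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    @property
    def gray(self) -> np.ndarray:
        return to_grayscale(self)


def window_signal(
    s: AffineSignal, cfg: ImagingConfig = ImagingConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice each channel into H overlapping rows of width W."""
    n = s.n
    if cfg.pad:
        h = max(1, -(-(n - cfg.overlap) // cfg.stride)) if n < cfg.window else (
            (n - cfg.window + cfg.stride - 1) // cfg.stride + 1
        )
        needed = cfg.window + (h - 1) * cfg.stride
        channels = np.pad(s.channels, ((0, 0), (0, needed - n)))
    else:
        h = cfg.n_windows(n)
        channels = s.channels
    starts = np.arange(h) * cfg.stride
    cols = starts[:, None] + np.arange(cfg.window)[None, :]
    r, g, b = (channels[i][cols] for i in range(3))
    return r, g, b


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_to_gray(m: np.ndarray) -> np.ndarray:
    """Min-max normalise a real matrix to 8-bit levels.

    ``g = round(255 * (m - min) / (max - min))`` with half-away-from-zero
    rounding; a constant matrix maps to all zeros.
    """
    m = np.asarray(m, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("non-finite values in matrix")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros(m.shape, dtype=np.uint8)
    g = _round_half_away(255.0 * (m - lo) / (hi - lo))
    return g.astype(np.uint8)


def compose_rgb(
    r: np.ndarray,
    g: np.ndarray,
    b: np.ndarray,
    transform: str = "zcurve",
    config: ImagingConfig = ImagingConfig(),
) -> GenomicImage:
    """Stack three normalised matrices into an RGB image (r, g, b channel order)."""
    if not (r.shape == g.shape == b.shape):
        raise ValueError("channel shape mismatch")
    return GenomicImage(np.stack([r, g, b], axis=-1), transform, config)


def to_grayscale(
    img: GenomicImage, weights: tuple[float, float, float] = BT601_WEIGHTS
) -> np.ndarray:
    """BT.601 luma grayscale, rounded half away from zero, clamped to [0, 255]."""
    wr, wg, wb = weights
    rgb = img.rgb.astype(float)
    y = wr * rgb[..., 0] + wg * rgb[..., 1] + wb * rgb[..., 2]
    return np.clip(_round_half_away(y), 0, 255).astype(np.uint8)


def signal_to_image(s: AffineSignal, cfg: ImagingConfig = ImagingConfig()) -> GenomicImage:
    """Full signal -> image pipeline: window, per-channel normalise, compose."""
    r, g, b = window_signal(s, cfg)
    return compose_rgb(
        normalize_to_gray(r),
        normalize_to_gray(g),
        normalize_to_gray(b),
        transform=s.transform,
        config=cfg,
    )


def save_png(img: GenomicImage, path: str | Path) -> None:
    Image.fromarray(img.rgb, mode="RGB").save(str(path), format="PNG")


def load_png(path: str | Path, transform: str = "zcurve",
             config: ImagingConfig = ImagingConfig()) -> GenomicImage:
    arr = np.asarray(Image.open(str(path)).convert("RGB"))
    return GenomicImage(arr, transform, config)
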