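"""Fundus enhancement chain: green channel -> normalize -> CLAHE -> gamma.

The green channel carries the highest vessel/background contrast in fundus
photographs. Normalization is a per-image z-score over FOV-interior pixels
followed by a min–max rescale to [0, 1]; CLAHE equalizes background
brightness without amplifying noise; gamma correction (x ** (1/gamma),
gamma > 1) expands the dark portion where vessels live.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage import exposure

from .io_core import BinaryMask, ImageRecord


@dataclasses.dataclass
class PreprocessConfig:
    clahe_clip_limit: float = 0.02  # fraction of pixels per bin (skimage semantics)
    clahe_tile: int = 8             # tiles per image side
    gamma: float = 1.2
    normalize_mode: str = "per_image_zscore_rescaled"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1")


def to_green(image: ImageRecord | np.ndarray) -> np.ndarray:
    """Channel 1 of an RGB image; grayscale passes through with a warning."""
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    if pixels.ndim == 2:
        warnings.warn("grayscale input: green-channel extraction is a no-op", stacklevel=2)
        return pixels.copy()
    if pixels.ndim != 3 or pixels.shape[2] not in (3, 4):
        raise ValueError(f"expected an RGB image, got shape {pixels.shape}")
    return pixels[:, :, 1].copy()


def _normalize(green: np.ndarray, fov: np.ndarray) -> np.ndarray:
    inside = green[fov == 1]
    sd = inside.std()
    if sd < 1e-12:
        warnings.warn("constant image inside FOV; returning flat 0.5", stacklevel=3)
        return np.full_like(green, 0.5)
    z = (green - inside.mean()) / sd
    z_in = z[fov == 1]
    lo, hi = z_in.min(), z_in.max()
    return np.clip((z - lo) / (hi - lo), 0.0, 1.0)


def clahe(grid: np.ndarray, clip_limit: float, tile: int) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on the 8-bit
    quantization of the grid, returned to [0, 1]."""
    q = np.round(np.clip(grid, 0, 1) * 255).astype(np.uint8)
    h, w = q.shape
    kernel = (max(h // tile, 1), max(w // tile, 1))
    out = exposure.equalize_adapthist(q, kernel_size=kernel,
                                      clip_limit=float(min(max(clip_limit, 1e-4), 1.0)))
    return out.astype(np.float64)


def gamma_correct(grid: np.ndarray, gamma: float) -> np.ndarray:
    """x ** (1 / gamma) on [0, 1]; gamma > 1 brightens shadows, compresses highlights."""
    return np.clip(grid, 0.0, 1.0) ** (1.0 / gamma)


def enhance(green: np.ndarray, fov: BinaryMask | np.ndarray,
            cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain in order: normalize -> CLAHE -> gamma; output in [0, 1]."""
    cfg = cfg or PreprocessConfig()
    fov_grid = fov.grid if isinstance(fov, BinaryMask) else np.asarray(fov)
    if fov_grid.shape != green.shape:
        raise ValueError("FOV mask shape does not match the image")
    norm = _normalize(np.asarray(green, dtype=np.float64), fov_grid)
    eq = clahe(norm, cfg.clahe_clip_limit, cfg.clahe_tile)
    return gamma_correct(eq, cfg.gamma)
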