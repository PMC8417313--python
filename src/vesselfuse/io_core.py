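"""Image/mask I/O, patch extraction and reassembly, run configuration.

Images are held as float arrays in [0, 1]; masks as uint8 {0, 1} grids.
Patch coordinates are 0-based (row, col) of the top-left corner; a patch
covers the half-open square ``[r, r+size) x [c, c+size)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

logger = logging.getLogger("vesselfuse")

MASK_ROLES = ("vessel_truth", "fov", "optic_disc", "prediction")


@dataclasses.dataclass
class ImageRecord:
    """A loaded image: 2-D grayscale or 3-D RGB, intensities in [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixel grid, got ndim={p.ndim}")
        if p.shape[0] < 16 or p.shape[1] < 16:
            raise ValueError(f"image too small: {p.shape[:2]} (minimum 16x16)")
        if not np.isfinite(p).all():
            raise ValueError("image contains non-finite intensities")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = p

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class BinaryMask:
    """A {0,1} grid with a declared role (vessel_truth, fov, optic_disc, prediction)."""

    grid: np.ndarray
    role: str = "prediction"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, got {vals[:10]}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        self.grid = g.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclasses.dataclass
class PatchSet:
    """Square patches plus the coordinates needed to reassemble them."""

    patches: list[np.ndarray]
    coords: list[tuple[int, int]]
    patch_size: int
    stride: int
    source_shape: tuple[int, int]


@dataclasses.dataclass
class RunConfig:
    """All run-level knobs in one place; round-trips through YAML."""

    patch_size: int = 48
    stride: int = 24
    seed: int = 0
    # preprocessing
    clahe_clip_limit: float = 0.02
    clahe_tile: int = 8
    gamma: float = 1.2
    # loss
    loss_kind: str = "categorical_focal"
    loss_alpha: float = 0.25
    loss_gamma: float = 2.0
    # model
    depth: int = 2
    base_filters: int = 8
    # training
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    patches_per_image: int = 200
    # fusion
    fusion_method: str = "weighted_any"
    fusion_k: float = 1.25
    fusion_t: float = 0.5
    # morphology
    width_threshold: float = 2.2

    def __post_init__(self) -> None:
        if not (0 < self.fusion_t < 1):
            raise ValueError("fusion threshold t must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _decode(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:  # unreadable / corrupt
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    return arr


def _full_scale(arr: np.ndarray, path: Path) -> float:
    if arr.dtype == np.uint8 or arr.dtype == bool:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return 1.0
    if np.issubdtype(arr.dtype, np.integer):  # e.g. PNG "I" mode decoded as int32
        return 65535.0 if arr.max() > 255 else 255.0
    raise ValueError(f"unsupported bit depth / dtype {arr.dtype} in {path}")


def load_image(path: str | Path) -> ImageRecord:
    """Read a PNG/TIFF/JPEG/GIF/PPM image, scaled so full scale maps to 1.0."""
    arr = _decode(path)
    scale = _full_scale(arr, Path(path))
    pixels = np.asarray(arr, dtype=np.float64) / scale
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return ImageRecord(pixels=np.clip(pixels, 0.0, 1.0), source_path=str(path))


def load_mask(path: str | Path, role: str = "vessel_truth") -> BinaryMask:
    """Read a mask image and binarize at half full scale (anti-aliasing safe)."""
    arr = _decode(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    scale = _full_scale(arr, Path(path))
    grid = (np.asarray(arr, dtype=np.float64) > scale / 2).astype(np.uint8)
    if not grid.any():
        logger.warning("mask %s is empty (all zeros)", path)
        warnings.warn(f"mask {path} is empty (all zeros)", stacklevel=2)
    return BinaryMask(grid=grid, role=role)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit {0,255} PNG/TIFF."""
    Image.fromarray((mask.grid * 255).astype(np.uint8)).save(path)


def extract_patches(image: np.ndarray, patch_size: int, stride: int) -> PatchSet:
    """Tile a 2-D grid into square patches, zero-padding bottom/right to fit.

    Patches are enumerated row-major; the padded dimensions H', W' are the
    smallest values >= max(dim, patch_size) with (dim' - patch_size) % stride == 0,
    giving ``(1 + (H'-p)/s) * (1 + (W'-p)/s)`` patches.
    """
    if patch_size <= 0 or stride <= 0:
        raise ValueError(f"patch_size and stride must be positive, got {patch_size}, {stride}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("extract_patches expects a 2-D grid")
    h, w = image.shape

    def padded(dim: int) -> int:
        d = max(dim, patch_size)
        rem = (d - patch_size) % stride
        return d if rem == 0 else d + (stride - rem)

    hp, wp = padded(h), padded(w)
    canvas = np.zeros((hp, wp), dtype=image.dtype)
    canvas[:h, :w] = image
    patches: list[np.ndarray] = []
    coords: list[tuple[int, int]] = []
    for r in range(0, hp - patch_size + 1, stride):
        for c in range(0, wp - patch_size + 1, stride):
            patches.append(canvas[r : r + patch_size, c : c + patch_size].copy())
            coords.append((r, c))
    return PatchSet(patches=patches, coords=coords, patch_size=patch_size,
                    stride=stride, source_shape=(h, w))


def reassemble(patchset: PatchSet) -> np.ndarray:
    """Invert :func:`extract_patches`: overlaps averaged, padding cropped."""
    if not patchset.patches:
        raise ValueError("cannot reassemble an empty patch list")
    p = patchset.patch_size
    h, w = patchset.source_shape
    hp = max(r for r, _ in patchset.coords) + p
    wp = max(c for _, c in patchset.coords) + p
    acc = np.zeros((hp, wp), dtype=np.float64)
    cover = np.zeros((hp, wp), dtype=np.float64)
    for patch, (r, c) in zip(patchset.patches, patchset.coords):
        acc[r : r + p, c : c + p] += patch
        cover[r : r + p, c : c + p] += 1.0
    if (cover[:h, :w] == 0).any():
        raise ValueError("patch coords do not cover the source region")
    return (acc[:h, :w] / cover[:h, :w])
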