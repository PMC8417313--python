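"""Synthetic fundus-like images with exactly known vessel geometry.

The generator grows branching, tapering tubular trees by stamping Euclidean
disks of the local caliber along random-walk centerlines inside a circular
field of view, then renders a low-contrast green-dominant image with a smooth
radial background, optional central bright band along wide vessels, and
additive Gaussian noise. Ground-truth vessel mask, centerline and per-pixel
width map are known by construction, so the morphology, training, fusion and
evaluation stages can all be tested without external data.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io_core import BinaryMask


@dataclasses.dataclass
class VesselTreeSpec:
    """Parameters of the random vascular tree.

    Roots start on the field-of-view rim pointing inward with calibers drawn
    from ``root_width_range``; each branching event loses ``taper_rate``
    pixels of caliber, and segments also thin gradually along their length,
    so with ``taper_rate > 0`` terminal twigs drop below the 2.2 px
    thick/thin boundary and down to ``min_width`` (capillary scale).
    """

    image_size: int = 128
    n_roots: int = 3
    root_width_range: tuple[float, float] = (4.0, 9.0)
    taper_rate: float = 1.0
    branch_prob: float = 0.04
    min_width: float = 1.0
    tortuosity: float = 0.12
    max_segments: int = 30  # total segment budget per tree (keeps recursion bounded)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1 pixel")
        if max(self.root_width_range) >= self.image_size / 4:
            raise ValueError("root widths must stay below image_size / 4")
        if not (0 <= self.branch_prob <= 1):
            raise ValueError("branch_prob must lie in [0, 1]")


@dataclasses.dataclass
class SyntheticSample:
    """One generated image with exact geometric ground truth."""

    rgb: np.ndarray | None
    vessel_mask: BinaryMask
    fov_mask: BinaryMask
    true_width: np.ndarray
    true_centerline: BinaryMask


def _fov_circle(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    r = size / 2.0 - 2.0
    return ((yy - c) ** 2 + (xx - c) ** 2 <= r * r).astype(np.uint8)


class _Canvas:
    """Accumulates disk stamps; width at a pixel is the max over covering strokes."""

    def __init__(self, size: int, fov: np.ndarray):
        self.size = size
        self.fov = fov
        self.mask = np.zeros((size, size), dtype=np.uint8)
        self.width = np.zeros((size, size), dtype=np.float64)
        self.centerline: list[tuple[int, int]] = []

    def stamp(self, y: float, x: float, w: float) -> None:
        r = w / 2.0
        lo_y, hi_y = int(math.floor(y - r)), int(math.ceil(y + r))
        lo_x, hi_x = int(math.floor(x - r)), int(math.ceil(x + r))
        lo_y, hi_y = max(lo_y, 0), min(hi_y, self.size - 1)
        lo_x, hi_x = max(lo_x, 0), min(hi_x, self.size - 1)
        if lo_y > hi_y or lo_x > hi_x:
            return
        yy, xx = np.mgrid[lo_y : hi_y + 1, lo_x : hi_x + 1]
        inside = ((yy - y) ** 2 + (xx - x) ** 2 <= r * r) & (self.fov[yy, xx] == 1)
        sub = (slice(lo_y, hi_y + 1), slice(lo_x, hi_x + 1))
        self.mask[sub][inside] = 1
        self.width[sub][inside] = np.maximum(self.width[sub][inside], w)
        cy, cx = int(round(y)), int(round(x))
        if 0 <= cy < self.size and 0 <= cx < self.size and self.fov[cy, cx]:
            # capillary-scale disks (w ~ 1) can miss every pixel center; always
            # claim the rounded centerline pixel so thin twigs stay connected
            self.mask[cy, cx] = 1
            self.width[cy, cx] = max(self.width[cy, cx], w)
            self.centerline.append((cy, cx))


def _grow(canvas: _Canvas, rng: np.random.Generator, spec: VesselTreeSpec,
          y: float, x: float, angle: float, width: float, depth: int,
          budget: list[int]) -> None:
    """Walk one segment, stamping disks; taper along the way; maybe branch."""
    if depth > 8 or width < spec.min_width or budget[0] <= 0:
        return
    budget[0] -= 1
    length = float(rng.uniform(0.25, 0.5) * spec.image_size)
    n_steps = max(int(length / 0.6), 2)
    w0 = width
    w1 = max(spec.min_width, width - spec.taper_rate)
    step = 0.6
    c = (spec.image_size - 1) / 2.0
    r_fov = spec.image_size / 2.0 - 2.0
    for i in range(n_steps):
        t = i / max(n_steps - 1, 1)
        w = w0 + (w1 - w0) * t
        canvas.stamp(y, x, w)
        angle += float(rng.normal(0.0, spec.tortuosity))
        y += step * math.sin(angle)
        x += step * math.cos(angle)
        if (y - c) ** 2 + (x - c) ** 2 > (r_fov - 1) ** 2:
            return
        if spec.branch_prob > 0 and rng.random() < spec.branch_prob:
            side = 1.0 if rng.random() < 0.5 else -1.0
            child_angle = angle + side * float(rng.uniform(0.4, 0.9))
            child_width = max(spec.min_width, w - spec.taper_rate)
            _grow(canvas, rng, spec, y, x, child_angle, child_width, depth + 1, budget)
    # continue as a child segment (next branch level) until caliber bottoms out
    if w1 > spec.min_width:
        _grow(canvas, rng, spec, y, x, angle, max(spec.min_width, w1 - spec.taper_rate),
              depth + 1, budget)


def generate_tree(spec: VesselTreeSpec) -> SyntheticSample:
    """Grow the vascular tree geometry (no rendering). Deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    fov = _fov_circle(size)
    canvas = _Canvas(size, fov)
    c = (size - 1) / 2.0
    r_fov = size / 2.0 - 2.0
    for _ in range(spec.n_roots):
        theta = float(rng.uniform(0, 2 * math.pi))
        y0 = c + (r_fov - 3) * math.sin(theta)
        x0 = c + (r_fov - 3) * math.cos(theta)
        inward = theta + math.pi + float(rng.normal(0.0, 0.3))
        width = float(rng.uniform(*spec.root_width_range))
        _grow(canvas, rng, spec, y0, x0, inward, width, depth=0,
              budget=[spec.max_segments // max(spec.n_roots, 1)])
    if not canvas.mask.any():
        raise RuntimeError(
            "spec produced zero vessel pixels; increase n_roots/root widths or "
            "check that roots start inside the field of view")
    centerline = np.zeros((size, size), dtype=np.uint8)
    for cy, cx in canvas.centerline:
        centerline[cy, cx] = 1
    centerline &= canvas.mask
    return SyntheticSample(
        rgb=None,
        vessel_mask=BinaryMask(grid=canvas.mask, role="vessel_truth"),
        fov_mask=BinaryMask(grid=fov, role="fov"),
        true_width=canvas.width,
        true_centerline=BinaryMask(grid=centerline, role="vessel_truth"),
    )


def straight_tube(size: int = 64, width: float = 5.0, margin: int = 4) -> SyntheticSample:
    """A single horizontal constant-width tube through the image center, with
    a full-frame FOV — the degenerate fixture for width-recovery checks.

    Rasterized from the continuous capsule (pixel centers within width/2 of
    the centerline segment), not by disk stamping: for axis-aligned tubes the
    per-step disk union has a dotted boundary wherever the radius exactly
    equals an integer pixel offset.
    """
    fov = np.ones((size, size), dtype=np.uint8)
    y0 = size // 2
    yy, xx = np.mgrid[:size, :size]
    mask = ((np.abs(yy - y0) <= width / 2.0)
            & (xx >= margin) & (xx <= size - 1 - margin)).astype(np.uint8)
    widths = mask.astype(np.float64) * width
    centerline = np.zeros((size, size), dtype=np.uint8)
    centerline[y0, margin : size - margin] = 1
    return SyntheticSample(
        rgb=None,
        vessel_mask=BinaryMask(grid=mask, role="vessel_truth"),
        fov_mask=BinaryMask(grid=fov, role="fov"),
        true_width=widths,
        true_centerline=BinaryMask(grid=centerline, role="vessel_truth"),
    )


def render_fundus(sample: SyntheticSample, noise_sd: float = 0.03,
                  contrast: float = 0.25, bright_band: bool = True,
                  seed: int = 0) -> SyntheticSample:
    """Fill in the RGB channels over the generated geometry.

    Background is a smooth radial gradient inside the FOV; vessels are darker
    than background in the green channel by ``contrast``; vessels wider than
    4 px optionally carry a central bright stripe along their centerline
    (the classic central light reflex); Gaussian noise is added and the
    result clipped to [0, 1]. Masks are untouched.
    """
    rng = np.random.default_rng(seed)
    noise_sd = float(min(max(noise_sd, 0.0), 0.5))
    contrast = float(min(max(contrast, 0.0), 1.0))
    fov = sample.fov_mask.grid
    mask = sample.vessel_mask.grid
    size = fov.shape[0]
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[: fov.shape[0], : fov.shape[1]]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / (c * c + 1e-9)
    green = 0.55 + 0.15 * (1.0 - np.clip(r2, 0, 1))
    green[mask == 1] -= contrast
    if bright_band:
        band = (sample.true_centerline.grid == 1) & (sample.true_width > 4.0)
        green[band] += 0.6 * contrast
    green += rng.normal(0.0, noise_sd, size=green.shape)
    green = np.clip(green, 0.0, 1.0) * fov
    red = np.clip(green * 1.25 + 0.1, 0.0, 1.0) * fov
    blue = np.clip(green * 0.45, 0.0, 1.0) * fov
    rgb = np.stack([red, green, blue], axis=-1)
    return dataclasses.replace(sample, rgb=rgb)


def generate_dataset(n: int, size: int = 128, seed: int = 0,
                     spec_overrides: dict | None = None,
                     noise_sd: float = 0.03, contrast: float = 0.25) -> list[SyntheticSample]:
    """Generate ``n`` rendered samples with per-image seeds derived from ``seed``."""
    samples = []
    for i in range(n):
        overrides = dict(spec_overrides or {})
        spec = VesselTreeSpec(image_size=size, seed=seed * 10007 + i, **overrides)
        geom = generate_tree(spec)
        samples.append(render_fundus(geom, noise_sd=noise_sd, contrast=contrast,
                                     seed=spec.seed + 1))
    return samples
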