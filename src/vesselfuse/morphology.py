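"""Vessel-mask morphology: outline, peeling skeletonization, width estimation,
thick/thin separation, and construction of the three training objectives.

The skeleton is obtained by iteratively peeling the vessel outline while
preserving (a) end pixels — vessel pixels with exactly one 8-connected vessel
neighbor — and (b) non-simple pixels, whose removal would change the local
foreground/background topology. Vessels are treated as 8-connected foreground
over 4-connected background, the standard pairing for thin structures.

Per-pixel vessel width (caliber) is defined as twice the Euclidean distance
from a skeleton pixel to the nearest outline pixel; non-skeleton vessel pixels
inherit the width of their nearest skeleton pixel. A width threshold (default
2.2 px) then partitions the mask into thick and thin vessel pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_core import BinaryMask

#: 8-neighborhood offsets in raster order (the LUT bit order).
_NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def _build_simple_point_lut() -> np.ndarray:
    """Precompute, for each of the 256 neighborhood configurations, whether the
    center pixel is simple under (8,4) connectivity.

    A foreground pixel is simple iff its 8-neighborhood contains exactly one
    8-connected foreground component and exactly one 4-connected background
    component that touches a 4-neighbor of the center. Deleting a simple pixel
    never splits, merges, creates or destroys a component or hole.
    """
    offsets = _NEIGHBOR_OFFSETS
    four_neighbors = {(-1, 0), (0, -1), (0, 1), (1, 0)}
    lut = np.zeros(256, dtype=bool)
    for bits in range(256):
        fg = [offsets[i] for i in range(8) if bits >> i & 1]
        bg = [offsets[i] for i in range(8) if not bits >> i & 1]
        if not fg:  # isolated pixel: deletion removes a component
            continue

        def count(cells: list[tuple[int, int]], eight: bool) -> list[set[tuple[int, int]]]:
            cells_set = set(cells)
            seen: set[tuple[int, int]] = set()
            comps: list[set[tuple[int, int]]] = []
            for start in cells:
                if start in seen:
                    continue
                comp = {start}
                stack = [start]
                seen.add(start)
                while stack:
                    y, x = stack.pop()
                    for dy, dx in offsets:
                        q = (y + dy, x + dx)
                        if q in cells_set and q not in seen:
                            if eight or abs(dy) + abs(dx) == 1:
                                seen.add(q)
                                comp.add(q)
                                stack.append(q)
                comps.append(comp)
            return comps

        fg_comps = count(fg, eight=True)
        bg_comps = count(bg, eight=False)
        bg_touching = [c for c in bg_comps if c & four_neighbors]
        lut[bits] = len(fg_comps) == 1 and len(bg_touching) == 1
    return lut


_SIMPLE_LUT = _build_simple_point_lut()


@dataclasses.dataclass
class Outline:
    """Vessel boundary pixels: vessel pixels 8-adjacent to background."""

    grid: np.ndarray  # uint8 {0,1}


@dataclasses.dataclass
class Skeleton:
    """Centerline pixels (1–2 px wide) preserving the mask's topology."""

    grid: np.ndarray  # uint8 {0,1}


@dataclasses.dataclass
class WidthMap:
    """Per-pixel vessel width in pixels; 0 off-vessel."""

    grid: np.ndarray  # float64


@dataclasses.dataclass
class ObjectiveSet:
    """The three training targets for one label image."""

    original: BinaryMask
    thick_objective: BinaryMask
    thin_objective: BinaryMask


def _as_grid(mask: BinaryMask | np.ndarray) -> np.ndarray:
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask)
    return grid.astype(np.uint8)


def extract_outline(mask: BinaryMask | np.ndarray) -> Outline:
    """Mark vessel pixels with at least one background pixel among their 8
    neighbors; the image border counts as background."""
    grid = _as_grid(mask)
    padded = np.pad(grid, 1)  # border = background
    has_bg = np.zeros_like(grid, dtype=bool)
    h, w = grid.shape
    for dy, dx in _NEIGHBOR_OFFSETS:
        has_bg |= padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w] == 0
    return Outline(grid=((grid == 1) & has_bg).astype(np.uint8))


def _neighbor_bits(padded: np.ndarray, r: int, c: int) -> int:
    """Neighborhood configuration of padded[r, c] as an 8-bit code."""
    bits = 0
    for i, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS):
        if padded[r + dy, c + dx]:
            bits |= 1 << i
    return bits


_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.uint8)


#: directional subpass order: the background neighbor that qualifies a pixel
#: for deletion in that subpass (north, south, east, west).
_SUBPASS_DIRS = ((-1, 0), (1, 0), (0, 1), (0, -1))


def skeletonize(mask: BinaryMask | np.ndarray) -> Skeleton:
    """Iterative boundary peeling to a 1–2 px centerline.

    Outline pixels are peeled in order of their Euclidean distance to the
    background (so the skeleton settles on the medial ridge), and within each
    distance level in four directional subpasses (pixels whose north / south
    / east / west neighbor is currently background) to keep peeling symmetric
    — a one-sided scan drifts the centerline and leaves spurs on trailing
    borders. A pixel is deleted only if it is neither an end pixel (exactly
    one 8-connected vessel neighbor) nor non-simple (its removal would change
    the local foreground/background topology), so segments already <2 px wide
    survive. Sweeps repeat to a fixed point, which makes the operation
    idempotent by construction.
    """
    grid = _as_grid(mask)
    if not grid.any():
        return Skeleton(grid=np.zeros_like(grid, dtype=np.uint8))
    padded = np.pad(grid, 1).astype(np.uint8)
    h, w = grid.shape
    edt = np.pad(ndimage.distance_transform_edt(grid), 1)
    levels = np.unique(edt[1:-1, 1:-1][grid == 1])
    while True:
        changed = False
        for level in levels:
            for dy, dx in _SUBPASS_DIRS:
                core = padded[1 : 1 + h, 1 : 1 + w]
                border = ((core == 1) & (edt[1 : 1 + h, 1 : 1 + w] == level)
                          & (padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w] == 0))
                rows, cols = np.nonzero(border)
                for r, c in zip(rows + 1, cols + 1):  # sequential update within subpass
                    bits = _neighbor_bits(padded, r, c)
                    if int(_POPCOUNT[bits]) <= 1:  # end pixel or isolated pixel: keep
                        continue
                    if _SIMPLE_LUT[bits]:
                        padded[r, c] = 0
                        changed = True
        if not changed:
            break
    return Skeleton(grid=padded[1:-1, 1:-1].astype(np.uint8))


def _nearest_with_rowmajor_ties(query: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each query point, index of the nearest reference point (Euclidean);
    exact-distance ties resolved to the smallest row-major reference index.

    ``ref`` must already be sorted row-major.
    """
    tree = cKDTree(ref)
    k = min(len(ref), 8)
    dist, idx = tree.query(query, k=k)
    if k == 1:
        return np.atleast_1d(dist), np.atleast_1d(idx)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    best = np.empty(len(query), dtype=np.int64)
    bestd = dist[:, 0].copy()
    tol = 1e-9
    for i in range(len(query)):
        tied = idx[i][dist[i] <= bestd[i] + tol]
        if dist[i, -1] <= bestd[i] + tol and k < len(ref):
            # pathological many-way tie beyond k: fall back to brute force
            d2 = np.sum((ref - query[i]) ** 2, axis=1)
            m = d2.min()
            tied = np.nonzero(d2 <= m + tol)[0]
        best[i] = tied.min()
    return bestd, best


def compute_width_map(mask: BinaryMask | np.ndarray,
                      skeleton: Skeleton | None = None,
                      outline: Outline | None = None) -> WidthMap:
    """Per-pixel caliber: skeleton pixels get twice the Euclidean distance to
    the nearest outline pixel; other vessel pixels inherit from their nearest
    skeleton pixel (ties row-major). Off-vessel pixels are 0."""
    grid = _as_grid(mask)
    if skeleton is None:
        skeleton = skeletonize(grid)
    if outline is None:
        outline = extract_outline(grid)
    widths = np.zeros(grid.shape, dtype=np.float64)
    if not grid.any():
        return WidthMap(grid=widths)
    skel_pts = np.argwhere(skeleton.grid == 1)  # argwhere is row-major
    out_pts = np.argwhere(outline.grid == 1)
    if len(skel_pts) == 0:
        raise RuntimeError("nonempty mask produced an empty skeleton")
    d_out, _ = cKDTree(out_pts).query(skel_pts)
    skel_width = 2.0 * d_out
    widths[skel_pts[:, 0], skel_pts[:, 1]] = skel_width
    other = np.argwhere((grid == 1) & (skeleton.grid == 0))
    if len(other):
        _, nearest = _nearest_with_rowmajor_ties(other.astype(np.float64),
                                                 skel_pts.astype(np.float64))
        widths[other[:, 0], other[:, 1]] = skel_width[nearest]
    return WidthMap(grid=widths)


def separate_thick_thin(mask: BinaryMask | np.ndarray, widths: WidthMap,
                        threshold: float = 2.2) -> tuple[BinaryMask, BinaryMask]:
    """Partition vessel pixels: width >= threshold -> thick, else thin."""
    if threshold <= 0:
        raise ValueError(f"separation threshold must be positive, got {threshold}")
    grid = _as_grid(mask)
    thick = (grid == 1) & (widths.grid >= threshold)
    thin = (grid == 1) & ~thick
    return (BinaryMask(grid=thick.astype(np.uint8), role="vessel_truth"),
            BinaryMask(grid=thin.astype(np.uint8), role="vessel_truth"))


def build_objectives(label: BinaryMask | np.ndarray, threshold: float = 2.2) -> ObjectiveSet:
    """Build the three training targets from one ground-truth label.

    The thick objective keeps the thick vessels and replaces removed thin
    vessels by the skeleton; the thin objective keeps the thin vessels plus
    the skeleton. The skeleton union preserves the full vessel topology in
    both targets.
    """
    grid = _as_grid(label)
    skel = skeletonize(grid)
    if grid.any():
        widths = compute_width_map(grid, skeleton=skel)
        thick, thin = separate_thick_thin(grid, widths, threshold=threshold)
    else:
        zero = BinaryMask(grid=np.zeros_like(grid), role="vessel_truth")
        thick, thin = zero, dataclasses.replace(zero)
    thick_obj = ((thick.grid == 1) | (skel.grid == 1)).astype(np.uint8)
    thin_obj = ((thin.grid == 1) | (skel.grid == 1)).astype(np.uint8)
    return ObjectiveSet(
        original=BinaryMask(grid=grid, role="vessel_truth"),
        thick_objective=BinaryMask(grid=thick_obj, role="vessel_truth"),
        thin_objective=BinaryMask(grid=thin_obj, role="vessel_truth"),
    )
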