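"""Fusion of the three probability maps into the final binary segmentation.

Three mechanisms, all thresholding at t (inclusive, default 0.5):

* ``weighted_any`` (default): a pixel is vessel if min(k * p_original, 1) >= t
  or p_thick >= t or p_thin >= t. The original channel is up-weighted by
  k (default 1.25, i.e. an effective threshold of t / k = 0.4) because its
  label is the most complete; the thick and thin channels face the raw,
  stricter threshold. With ``strict_mode`` the same preference is expressed
  the other way round: the original channel faces t and the thick/thin
  channels face min(k * t, 1).
* ``majority``: vessel if at least 2 of the 3 raw probabilities >= t.
* ``mean``: vessel if the average of the 3 probabilities >= t.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_core import BinaryMask
from .segnet import ProbabilityMap, ProbabilityTriplet

FUSION_METHODS = ("weighted_any", "majority", "mean")


@dataclasses.dataclass
class FusionConfig:
    method: str = "weighted_any"
    k: float = 1.25
    t: float = 0.5
    strict_mode: bool = False

    def __post_init__(self) -> None:
        if self.method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.method!r}; expected {FUSION_METHODS}")
        if self.k < 1:
            raise ValueError("original-channel weight k must be >= 1")
        if not (0 < self.t < 1):
            raise ValueError("probability threshold t must lie in (0, 1)")


def _grid(m) -> np.ndarray:
    return m.grid if hasattr(m, "grid") else np.asarray(m)


def fuse(triplet: ProbabilityTriplet, cfg: FusionConfig | None = None,
         fov: BinaryMask | np.ndarray | None = None) -> BinaryMask:
    """Combine (p_original, p_thick, p_thin) into a binary prediction."""
    cfg = cfg or FusionConfig()
    po = _grid(triplet.p_original)
    pk = _grid(triplet.p_thick)
    pn = _grid(triplet.p_thin)
    if not (po.shape == pk.shape == pn.shape):
        raise ValueError("probability maps in a triplet must share one shape")
    if cfg.method == "weighted_any":
        if cfg.strict_mode:
            vessel = (po >= cfg.t) | (pk >= min(cfg.k * cfg.t, 1.0)) | (pn >= min(cfg.k * cfg.t, 1.0))
        else:
            vessel = (np.minimum(cfg.k * po, 1.0) >= cfg.t) | (pk >= cfg.t) | (pn >= cfg.t)
    elif cfg.method == "majority":
        vessel = ((po >= cfg.t).astype(int) + (pk >= cfg.t) + (pn >= cfg.t)) >= 2
    else:  # mean
        vessel = (po + pk + pn) / 3.0 >= cfg.t
    vessel = vessel.astype(np.uint8)
    if fov is not None:
        fg = _grid(fov)
        if fg.shape != vessel.shape:
            raise ValueError("FOV mask shape does not match the probability maps")
        vessel = vessel * (fg == 1)
    return BinaryMask(grid=vessel.astype(np.uint8), role="prediction")


def threshold_single(p: ProbabilityMap | np.ndarray, t: float = 0.5,
                     fov: BinaryMask | np.ndarray | None = None) -> BinaryMask:
    """Single-channel baseline: vessel iff probability >= t, masked by FOV."""
    if not (0 < t < 1):
        raise ValueError("threshold t must lie in (0, 1)")
    grid = _grid(p)
    vessel = (grid >= t).astype(np.uint8)
    if fov is not None:
        fg = _grid(fov)
        if fg.shape != vessel.shape:
            raise ValueError("FOV mask shape does not match the probability map")
        vessel = vessel * (fg == 1)
    return BinaryMask(grid=vessel.astype(np.uint8), role="prediction")
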