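"""Pixel-level segmentation evaluation inside the field of view.

Confusion counts; sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy Acc = (TP+TN)/total, F1 = 2TP/(2TP+FP+FN); AUC as the Mann–Whitney
rank statistic (probability a random vessel pixel outranks a random
background pixel, ties counting one half); a thin-vessel-restricted
evaluation that separates thick and thin truth vessels at a 3 px caliber
boundary; and per-image F1 mean/standard-deviation dispersion.

All metrics are computed over FOV-interior pixels only — the black exterior
would otherwise inflate specificity.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .io_core import BinaryMask
from .morphology import compute_width_map, separate_thick_thin, skeletonize


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class MetricsReport:
    se: float
    sp: float
    acc: float
    f1: float
    counts: ConfusionCounts
    auc: float | None = None
    scope: str = "all_vessels"  # all_vessels | thin_only


def _grid(m) -> np.ndarray:
    return m.grid if hasattr(m, "grid") else np.asarray(m)


def confusion(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray,
              fov: BinaryMask | np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN over FOV-interior pixels."""
    p, t, f = _grid(pred), _grid(truth), _grid(fov)
    if not (p.shape == t.shape == f.shape):
        raise ValueError("pred, truth and fov must share one shape")
    inside = f == 1
    p, t = p[inside] == 1, t[inside] == 1
    return ConfusionCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts, scope: str = "all_vessels") -> MetricsReport:
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    return MetricsReport(
        se=_safe_ratio(c.tp, c.tp + c.fn, "Se"),
        sp=_safe_ratio(c.tn, c.tn + c.fp, "Sp"),
        acc=(c.tp + c.tn) / c.total,
        f1=_safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
        counts=c, scope=scope,
    )


def auc_score(prob, truth: BinaryMask | np.ndarray, fov: BinaryMask | np.ndarray) -> float:
    """Rank-statistic AUC over FOV-interior pixels; exact under ties."""
    p, t, f = _grid(prob), _grid(truth), _grid(fov)
    inside = f == 1
    scores, labels = p[inside].astype(np.float64), t[inside] == 1
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: truth has a single class inside the FOV")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def thin_evaluation_region(truth: BinaryMask | np.ndarray, fov: BinaryMask | np.ndarray,
                           boundary: float = 3.0) -> np.ndarray:
    """The pixels over which thin-vessel metrics are scored: the thin part of
    the truth (caliber < boundary) dilated by 1 px, plus FOV background
    pixels within 2 px of it."""
    t, f = _grid(truth), _grid(fov)
    if not t.any():
        return np.zeros_like(t, dtype=bool)
    skel = skeletonize(t)
    widths = compute_width_map(t, skeleton=skel)
    _, thin = separate_thick_thin(t, widths, threshold=boundary)
    if not thin.grid.any():
        return np.zeros_like(t, dtype=bool)
    core = ndimage.binary_dilation(thin.grid == 1, structure=_disk(1))
    near = ndimage.binary_dilation(thin.grid == 1, structure=_disk(2))
    region = core | (near & (t == 0) & (f == 1))
    return region & (f == 1)


def thin_metrics(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray,
                 fov: BinaryMask | np.ndarray, boundary: float = 3.0) -> MetricsReport:
    """Se/Sp/Acc/F1 restricted to the neighborhood of thin truth vessels
    (caliber below ``boundary`` px)."""
    p, t, f = _grid(pred), _grid(truth), _grid(fov)
    if not (p.shape == t.shape == f.shape):
        raise ValueError("pred, truth and fov must share one shape")
    region = thin_evaluation_region(t, f, boundary=boundary)
    if not region.any():
        warnings.warn("truth contains no thin vessels; thin-scope report is all zero",
                      stacklevel=2)
        return MetricsReport(se=0.0, sp=0.0, acc=0.0, f1=0.0,
                             counts=ConfusionCounts(0, 0, 0, 0), scope="thin_only")
    c = confusion(p, t, region.astype(np.uint8))
    return metrics_from_counts(c, scope="thin_only")


def f1_dispersion(per_image: list[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of per-image F1 scores."""
    if len(per_image) < 2:
        raise ValueError("need at least two per-image F1 values")
    arr = np.asarray(per_image, dtype=np.float64)
    return float(arr.mean()), float(arr.std(ddof=1))
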