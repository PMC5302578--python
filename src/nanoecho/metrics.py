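"""Confusion counting and detection metrics with two-stage averaging.

Pixel-level counts are taken inside a rectangular region of interest on
the detection grid; sensitivity, specificity and the Dice similarity
coefficient (DSC) follow the standard definitions

    sensitivity [%] = 100 · TP / (TP + FN)
    specificity [%] = 100 · TN / (TN + FP)
    DSC        [%] = 100 · 2·TP / (2·TP + FN + FP)

Per-frame values are averaged over each acquisition's frame sequence and
then again across replicate phantoms (two-stage mean); the dispersion
reported is the SD across replicates.  Frames with an undefined
denominator are flagged (NaN) and excluded from the averages, with the
exclusion count carried along.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Rect",
    "MetricsResult",
    "AggregateResult",
    "confusion",
    "sensitivity",
    "specificity",
    "dsc",
    "frame_metrics",
    "aggregate",
]


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle on the detection grid."""

    lat_start: int
    lat_stop: int
    ax_start: int
    ax_stop: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.lat_start, self.lat_stop), slice(self.ax_start,
                                                           self.ax_stop)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(det_map: np.ndarray, mask: np.ndarray,
              roi: Rect | None = None) -> ConfusionCounts:
    """Exact pixel counts of a boolean detection map against ground truth.

    ``det_map`` and ``mask`` must share a grid; ``roi`` restricts the
    count to a rectangle of that grid (default: everything).
    """
    det_map = np.asarray(det_map, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if det_map.shape != mask.shape:
        raise ValueError(f"grid mismatch: map {det_map.shape} "
                         f"vs mask {mask.shape}")
    if roi is not None:
        s = roi.slices()
        det_map, mask = det_map[s], mask[s]
    tp = int(np.count_nonzero(det_map & mask))
    fp = int(np.count_nonzero(det_map & ~mask))
    fn = int(np.count_nonzero(~det_map & mask))
    tn = int(np.count_nonzero(~det_map & ~mask))
    return ConfusionCounts(tp, fp, fn, tn)


def sensitivity(c: ConfusionCounts) -> float:
    """100·TP/(TP+FN); NaN when no positives exist."""
    denom = c.tp + c.fn
    return 100.0 * c.tp / denom if denom else math.nan


def specificity(c: ConfusionCounts) -> float:
    """100·TN/(TN+FP); NaN when no negatives exist."""
    denom = c.tn + c.fp
    return 100.0 * c.tn / denom if denom else math.nan


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient, 100·2TP/(2TP+FN+FP); NaN if empty."""
    denom = 2 * c.tp + c.fn + c.fp
    return 100.0 * 2 * c.tp / denom if denom else math.nan


@dataclass(frozen=True)
class MetricsResult:
    """Sensitivity/specificity/DSC (percent; NaN = undefined)."""

    sensitivity: float
    specificity: float
    dsc: float
    level: str = "frame"
    n: int = 1


def frame_metrics(c: ConfusionCounts) -> MetricsResult:
    return MetricsResult(sensitivity(c), specificity(c), dsc(c))


@dataclass(frozen=True)
class AggregateResult:
    """Two-stage averaged metrics: mean over frames within each
    replicate, then mean ± SD across replicates."""

    sensitivity: float
    specificity: float
    dsc: float
    sensitivity_sd: float
    specificity_sd: float
    dsc_sd: float
    n_replicates: int
    n_frames: int
    n_undefined: dict[str, int]
    level: str = "replicate-set"


def _two_stage(values: np.ndarray, reps: np.ndarray) -> tuple[float, float, int]:
    """Mean of per-replicate means and SD across replicates (NaN-aware)."""
    rep_means = []
    n_undef = int(np.count_nonzero(np.isnan(values)))
    for r in sorted(set(reps.tolist())):
        v = values[reps == r]
        v = v[~np.isnan(v)]
        if v.size:
            rep_means.append(v.mean())
    if not rep_means:
        return math.nan, math.nan, n_undef
    rep_means = np.asarray(rep_means)
    sd = rep_means.std(ddof=0) if rep_means.size > 1 else 0.0
    return float(rep_means.mean()), float(sd), n_undef


def aggregate(per_frame: list[MetricsResult],
              replicate_ids: list[int] | None = None) -> AggregateResult:
    """Two-stage averaging of per-frame metrics.

    Frames are first averaged within each replicate, then the replicate
    means are averaged (the replicate-level SD is the error bar).  With
    a single replicate the SD is zero.  The result is invariant to the
    order of replicates and, within a replicate, of frames.
    """
    if not per_frame:
        raise ValueError("no frames to aggregate")
    if replicate_ids is None:
        replicate_ids = [0] * len(per_frame)
    if len(replicate_ids) != len(per_frame):
        raise ValueError("one replicate id per frame required")
    reps = np.asarray(replicate_ids)
    out, sds, undef = [], [], {}
    for name in ("sensitivity", "specificity", "dsc"):
        vals = np.array([getattr(m, name) for m in per_frame], dtype=float)
        mean, sd, n_undef = _two_stage(vals, reps)
        out.append(mean)
        sds.append(sd)
        undef[name] = n_undef
    return AggregateResult(out[0], out[1], out[2], sds[0], sds[1], sds[2],
                           n_replicates=len(set(replicate_ids)),
                           n_frames=len(per_frame), n_undefined=undef)
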