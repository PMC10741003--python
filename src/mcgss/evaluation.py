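"""Activity maps and threshold segmentation into healthy vs pathological tissue.

A voxel's activity is the maximum over the cardiac cycle of the L1 norm of
its current density.  In the normalized current unit, healthy voxels of the
initialized model reach 1 by construction, so absolute thresholds in
[0.6, 1.0] separate quiescent (pathological) from active tissue.  Pathological
is the positive class of all scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def activity_map(J: np.ndarray) -> np.ndarray:
    """Per-voxel ``max_n ||j_v(n)||_1`` for a trajectory ``(Nm, 3*Nv)``."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[1] % 3:
        raise ValueError("trajectory must be (Nm, 3*Nv)")
    if J.shape[0] == 0:
        return np.zeros(J.shape[1] // 3)
    l1 = np.abs(J.reshape(J.shape[0], -1, 3)).sum(axis=2)
    return l1.max(axis=0)


@dataclass(frozen=True)
class SegmentationReport:
    labels: np.ndarray  # True = pathological (positive class)
    threshold: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    dice: float = float("nan")
    recall: float = float("nan")
    precision: float = float("nan")


def segment(activity: np.ndarray, threshold: float) -> SegmentationReport:
    """Label voxels with activity strictly below ``threshold`` as pathological."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    labels = np.asarray(activity, dtype=float) < threshold
    return SegmentationReport(labels=labels, threshold=float(threshold))


def score(report: SegmentationReport, truth: np.ndarray) -> SegmentationReport:
    """Fill in confusion counts, DICE, recall and precision against the true
    pathological mask."""
    truth = np.asarray(truth, dtype=bool)
    pred = report.labels
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    if tp + fn == 0:
        warnings.warn("no positive voxels in truth; metrics undefined", stacklevel=2)
        dice = recall = precision = float("nan")
    else:
        dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return SegmentationReport(
        labels=pred,
        threshold=report.threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        dice=dice,
        recall=recall,
        precision=precision,
    )


def threshold_sweep(
    activity: np.ndarray,
    truth: np.ndarray,
    lo: float = 0.6,
    hi: float = 1.0,
    step: float = 0.01,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Evaluate DICE on a threshold grid; returns (best threshold, grid, curve).

    Ties resolve toward the lowest threshold.
    """
    if lo >= hi:
        raise ValueError("sweep requires lo < hi")
    n = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    curve = np.array([score(segment(activity, t), truth).dice for t in grid])
    best = int(np.nanargmax(curve))
    return float(grid[best]), grid, curve
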