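"""Count-based evaluation of a segmentation run.

Detections are compared to ground truth by greedy one-to-one nearest
centroid matching within a radius; true negatives follow the convention
that every component removed by postprocessing was a correctly rejected
noise object, i.e. TN = count before postprocessing minus count after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EntrosegError


@dataclass
class EvalResult:
    """Confusion counts and the derived percentages.

    A percentage whose denominator is zero is ``None`` (reported as
    not-available, never as 0).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None

    def to_dict(self):
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def match_detections(detected, truth, max_dist: float):
    """Greedy one-to-one nearest-neighbour matching of centroid lists.

    Pairs within ``max_dist`` are accepted in order of increasing distance,
    each centroid used at most once.  Returns (TP, FP, FN).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    detected = np.atleast_2d(np.asarray(detected, dtype=np.float64).reshape(-1, 2))
    truth = np.atleast_2d(np.asarray(truth, dtype=np.float64).reshape(-1, 2))
    if detected.shape[0] == 0 or truth.shape[0] == 0:
        return 0, detected.shape[0], truth.shape[0]
    dists = cdist(detected, truth)
    pairs = [
        (dists[i, j], i, j)
        for i in range(detected.shape[0])
        for j in range(truth.shape[0])
        if dists[i, j] <= max_dist
    ]
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    return tp, detected.shape[0] - tp, truth.shape[0] - tp


def true_negatives(count_before_post: int, count_after_post: int) -> int:
    """TN = components removed by postprocessing (count before minus after)."""
    if count_after_post < 0 or count_before_post < 0:
        raise ValueError("counts must be non-negative")
    if count_after_post > count_before_post:
        raise EntrosegError(
            "count after postprocessing exceeds count before; "
            "true-negative convention violated"
        )
    return count_before_post - count_after_post


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def evaluate(tp: int, fp: int, fn: int, tn: int) -> EvalResult:
    """Accuracy, precision, sensitivity and specificity (percentages)."""
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise EntrosegError("empty evaluation: all confusion counts are zero")
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=_pct(tp + tn, tp + tn + fp + fn),
        precision=_pct(tp, tp + fp),
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
    )
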