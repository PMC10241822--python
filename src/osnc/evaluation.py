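"""Accuracy metrics and mask-agreement scoring.

Scene-level scoring follows the recognition-accuracy convention:
M_s = n_i / N correct calls out of N samples in one experiment, and
the average M over P experiments.  A "correct" call for a synthetic
scene is the defect-present/absent decision read off the predicted
mask: a scene is flagged defective when some defect-labeled connected
component reaches a minimum area (default 20 px), which suppresses
salt-noise false alarms.

Pixel-level scoring maps predicted cluster ids onto truth labels by
the best one-to-one overlap assignment (Hungarian on the confusion
matrix) before computing pixel accuracy and per-class IoU, since an
unsupervised segmentation has no reason to emit labels in the truth's
numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import measure

from osnc.errors import ParameterError, ShapeError

__all__ = [
    "EvalResult",
    "single_accuracy",
    "mean_accuracy",
    "mask_agreement",
    "defect_present",
]


@dataclass
class EvalResult:
    pixel_accuracy: float
    per_class_iou: dict[int, float]
    mapping: dict[int, int]  # predicted label -> truth label


def single_accuracy(n_i: int, N: int) -> float:
    """Single recognition accuracy rate M_s = n_i / N."""
    if N <= 0:
        raise ParameterError("N must be > 0")
    if not 0 <= n_i <= N:
        raise ParameterError(f"n_i={n_i} outside [0, {N}]")
    return n_i / N


def mean_accuracy(values, P: int | None = None) -> float:
    """Average recognition accuracy M over P experiments."""
    vals = list(values)
    if P is None:
        P = len(vals)
    if P <= 0 or len(vals) != P:
        raise ParameterError("P must equal the number of experiment values and be > 0")
    return float(sum(vals)) / P


def mask_agreement(pred: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Score a predicted mask against ground truth after label mapping.

    Predicted labels are matched one-to-one to truth labels by
    maximizing total overlap; unmatched predicted labels count as
    wrong everywhere.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p_labels = np.unique(pred)
    t_labels = np.unique(truth)
    conf = np.zeros((p_labels.size, t_labels.size), dtype=np.int64)
    for a, pl in enumerate(p_labels):
        sel = pred == pl
        for b, tl in enumerate(t_labels):
            conf[a, b] = np.count_nonzero(truth[sel] == tl)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    mapping = {int(p_labels[a]): int(t_labels[b]) for a, b in zip(rows, cols)}

    mapped = np.full(pred.shape, -1, dtype=np.int64)
    for pl, tl in mapping.items():
        mapped[pred == pl] = tl
    accuracy = float(np.mean(mapped == truth))
    iou: dict[int, float] = {}
    for tl in t_labels:
        inter = np.count_nonzero((mapped == tl) & (truth == tl))
        union = np.count_nonzero((mapped == tl) | (truth == tl))
        iou[int(tl)] = inter / union if union else 1.0
    return EvalResult(pixel_accuracy=accuracy, per_class_iou=iou, mapping=mapping)


def defect_present(mask: np.ndarray, defect_label: int = 2, min_area: int = 20) -> bool:
    """Scene-level defect call: any defect component of at least min_area px."""
    blobs = measure.label(np.asarray(mask) == defect_label, connectivity=2)
    if blobs.max() == 0:
        return False
    sizes = np.bincount(blobs.ravel())[1:]
    return bool((sizes >= min_area).any())
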