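"""Object-level evaluation of a segmentation against ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegmentationScore", "object_f1"]


@dataclass
class SegmentationScore:
    f1: float
    precision: float
    recall: float
    n_true: int
    n_pred: int
    n_matched: int
    count_error_fraction: float


def object_f1(
    true_labels: np.ndarray, pred_labels: np.ndarray, iou_threshold: float = 0.5
) -> SegmentationScore:
    """Object F1 at an IoU threshold.

    A (true, predicted) pair is a match when its intersection-over-union
    reaches ``iou_threshold``; at thresholds ≥ 0.5 matches are necessarily
    one-to-one, so F1 = 2·TP / (n_true + n_pred).
    """
    true_labels = np.asarray(true_labels).ravel()
    pred_labels = np.asarray(pred_labels).ravel()
    n_true = int(true_labels.max())
    n_pred = int(pred_labels.max())
    if n_true == 0 or n_pred == 0:
        matched = 0
    else:
        both = (true_labels > 0) & (pred_labels > 0)
        pair_ids = true_labels[both].astype(np.int64) * (n_pred + 1) + pred_labels[both]
        pairs, inter = np.unique(pair_ids, return_counts=True)
        t_ids = pairs // (n_pred + 1)
        p_ids = pairs % (n_pred + 1)
        area_t = np.bincount(true_labels, minlength=n_true + 1)
        area_p = np.bincount(pred_labels, minlength=n_pred + 1)
        union = area_t[t_ids] + area_p[p_ids] - inter
        iou = inter / union
        matched = int((iou >= iou_threshold).sum())
    precision = matched / n_pred if n_pred else 0.0
    recall = matched / n_true if n_true else 0.0
    f1 = 2 * matched / (n_true + n_pred) if (n_true + n_pred) else 0.0
    count_err = abs(n_pred - n_true) / n_true if n_true else np.inf
    return SegmentationScore(f1, precision, recall, n_true, n_pred, matched, count_err)
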