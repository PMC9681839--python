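"""Evaluation stack: box IoU, average precision / mAP, pixel-wise scores.

Detection quality follows the classical PASCAL-style protocol: detections
are sorted by confidence, greedily matched to the unmatched ground truth of
highest IoU at a fixed threshold (default 0.5), and AP is the area under the
stepwise precision–recall envelope (all-point interpolation; an 11-point
variant is provided for comparison).  Semantic maps are scored with
per-class pixel precision / recall / F1; macro averages include the
background class (five classes), matching the reporting convention of the
reference tables bundled in :mod:`pics.benchmarks`.  Repeated-split results
are aggregated as arithmetic mean ± population (divide-by-n) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "box_iou",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "pixel_scores",
    "macro_f1",
    "aggregate",
    "PRCurve",
    "ClassScores",
]


@dataclass
class PRCurve:
    """Confidence-ordered cumulative precision/recall for one class."""

    precision: np.ndarray
    recall: np.ndarray
    class_id: int = 0


@dataclass
class ClassScores:
    """Per-class pixel precision/recall/F1 with support counts."""

    precision: dict
    recall: dict
    f1: dict
    support: dict


def box_iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ValueError(f"degenerate box: {a} / {b}")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def _match_greedy(dets, gts, iou_thr):
    """Greedy confidence-descending matching; returns TP flags in det order.

    ``dets``: (box, confidence) pairs, ``gts``: list of boxes.  Each ground
    truth may be claimed once; later detections on a claimed GT are false
    positives.  ``gts`` may span several images when boxes carry an image
    key: pass ``(image_id, box)`` tuples for both to scope the matching.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    matched = [False] * len(gts)
    tp = [False] * len(dets)
    for i in order:
        (img, box), _conf = dets[i]
        best, best_iou = -1, iou_thr
        for j, (gimg, gbox) in enumerate(gts):
            if gimg != img or matched[j]:
                continue
            iou = box_iou(box, gbox)
            if iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            matched[best] = True
            tp[i] = True
    return tp, order


def average_precision(
    dets, gts, iou_thr: float = 0.5, interpolation: str = "all_point"
):
    """AP for one class and its PR curve.

    ``dets``: iterable of ``(image_id, box, confidence)``; ``gts``: iterable
    of ``(image_id, box)``.  Returns ``(ap, PRCurve)``; with no ground truth
    and no detections AP is undefined and ``None`` is returned.
    """
    dets = [((img, tuple(b)), float(c)) for img, b, c in dets]
    gts = [(img, tuple(b)) for img, b in gts]
    if not gts and not dets:
        return None, PRCurve(np.array([]), np.array([]))
    if not gts:
        return 0.0, PRCurve(np.zeros(len(dets)), np.zeros(len(dets)))
    if not dets:
        return 0.0, PRCurve(np.array([]), np.array([]))
    tp, order = _match_greedy(dets, gts, iou_thr)
    tp_sorted = np.array([tp[i] for i in order], dtype=float)
    cum_tp = np.cumsum(tp_sorted)
    cum_fp = np.cumsum(1.0 - tp_sorted)
    precision = cum_tp / (cum_tp + cum_fp)
    recall = cum_tp / len(gts)
    if interpolation == "all_point":
        ap = _ap_all_point(precision, recall)
    elif interpolation == "11_point":
        ap = _ap_11_point(precision, recall)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return float(ap), PRCurve(precision, recall)


def _ap_all_point(precision, recall):
    # area under the stepwise envelope max_{r' >= r} p(r')
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def _ap_11_point(precision, recall):
    env = np.maximum.accumulate(precision[::-1])[::-1]
    pts = []
    for r in np.linspace(0, 1, 11):
        mask = recall >= r - 1e-12
        pts.append(env[mask][0] if mask.any() else 0.0)
    return float(np.mean(pts))


def mean_ap(per_class_aps) -> float:
    """Equal-weight mean of per-class APs (``None`` entries excluded)."""
    aps = [a for a in per_class_aps if a is not None]
    if not aps:
        raise ValueError("no defined per-class APs to average")
    return float(np.mean(aps))


def evaluate_detections(detections, ground_truth, iou_thr: float = 0.5, classes=(1, 2, 3, 4)):
    """Per-class AP and mAP over a set of images.

    ``detections``: iterable of ``(image_id, box, class_id, confidence)``;
    ``ground_truth``: iterable of ``(image_id, box, class_id)``.  Classes
    absent from both predictions and ground truth have undefined AP and are
    excluded from the mean.
    """
    per_class = {}
    curves = {}
    for k in classes:
        dets_k = [(i, b, c) for i, b, cls, c in detections if cls == k]
        gts_k = [(i, b) for i, b, cls in ground_truth if cls == k]
        ap, curve = average_precision(dets_k, gts_k, iou_thr)
        curve.class_id = k
        per_class[k] = ap
        curves[k] = curve
    return {
        "per_class_ap": per_class,
        "mAP": mean_ap(per_class.values()),
        "pr_curves": curves,
    }


def pixel_scores(pred: np.ndarray, gt: np.ndarray, classes=(0, 1, 2, 3, 4)) -> ClassScores:
    """Per-class pixel precision, recall and F1 between two label maps.

    Classes absent from both maps score 1.0 with support 0 (no errors were
    possible); they are reported so the macro average stays well-defined.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    precision, recall, f1, support = {}, {}, {}, {}
    for k in classes:
        p_mask = pred == k
        g_mask = gt == k
        tp = int(np.sum(p_mask & g_mask))
        fp = int(np.sum(p_mask & ~g_mask))
        fn = int(np.sum(~p_mask & g_mask))
        support[k] = tp + fn
        if tp + fp + fn == 0:
            precision[k] = recall[k] = f1[k] = 1.0
            continue
        precision[k] = tp / (tp + fp) if tp + fp else 0.0
        recall[k] = tp / (tp + fn) if tp + fn else 0.0
        pr = precision[k] + recall[k]
        f1[k] = 2 * precision[k] * recall[k] / pr if pr > 0 else 0.0
    return ClassScores(precision=precision, recall=recall, f1=f1, support=support)


def macro_f1(scores: ClassScores, include_absent: bool = True) -> float:
    """Macro average of per-class F1 (background included)."""
    keys = [k for k in scores.f1 if include_absent or scores.support[k] > 0]
    return float(np.mean([scores.f1[k] for k in keys]))


def aggregate(values) -> tuple[float, float]:
    """Arithmetic mean and population (divide-by-n) standard deviation."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list")
    return float(values.mean()), float(values.std(ddof=0))
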