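"""Semantic-map generation: box–mask fusion and pixel-wise majority voting.

A semantic map assigns each pixel one of five labels (0 background,
1 neutrophil, 2 eosinophil, 3 lymphocyte, 4 monocyte).  It is produced by
combining a binary WBC mask with classified detector boxes:

* mask = 0  ->  background;
* mask = 1 inside exactly one box  ->  that box's class;
* mask = 1 inside two or more boxes  ->  the class of the covering box with
  the highest confidence (exact ties: smallest label);
* mask = 1 inside no box  ->  background.

An ensemble of such maps (one per independently trained detector/segmenter
pair) is combined by pixel-wise majority voting; vote ties resolve to the
smallest competing label, a background-favoring convention that is the
conservative choice for screening.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fuse", "majority_vote", "SEMANTIC_LEGEND"]

SEMANTIC_LEGEND = {
    0: "background",
    1: "neutrophil",
    2: "eosinophil",
    3: "lymphocyte",
    4: "monocyte",
}


def _as_box_arrays(detections, shape, warn):
    """Split detections into clipped coordinate/class/conf arrays."""
    h, w = shape
    boxes, classes, confs = [], [], []
    for det in detections:
        x0, y0, x1, y1 = det.box
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            if warn:
                import warnings

                warnings.warn(f"box {det.box} extends outside {w}x{h} image; clipping")
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, w), min(y1, h)
        boxes.append((x0, y0, x1, y1))
        classes.append(det.wbc_class)
        confs.append(det.confidence)
    return boxes, classes, confs


def fuse(binary_mask: np.ndarray, detections) -> np.ndarray:
    """Fuse a {0,1} mask with classified boxes into a semantic map.

    Box membership is half-open in pixel coordinates: pixel (x, y) lies in
    the box iff ``x_min <= x < x_max`` and ``y_min <= y < y_max``.
    ``detections`` need ``box``, ``wbc_class`` and ``confidence`` attributes.
    """
    mask = np.asarray(binary_mask)
    if mask.ndim != 2:
        raise ValueError("binary_mask must be 2-D")
    h, w = mask.shape
    boxes, classes, confs = _as_box_arrays(detections, (h, w), warn=True)

    out = np.zeros((h, w), dtype=np.uint8)
    if not boxes:
        return out
    # winner per pixel = covering box of max confidence; exact confidence
    # ties resolve to the smallest class label
    best_conf = np.full((h, w), -np.inf)
    best_cls = np.zeros((h, w), dtype=np.int64)
    order = sorted(range(len(boxes)), key=lambda i: (-confs[i], classes[i]))
    for i in order:
        x0, y0, x1, y1 = boxes[i]
        xs0, ys0 = int(np.ceil(x0)), int(np.ceil(y0))
        xs1, ys1 = int(np.ceil(x1)), int(np.ceil(y1))
        region = np.s_[ys0:ys1, xs0:xs1]
        take = best_conf[region] < confs[i]
        best_cls[region] = np.where(take, classes[i], best_cls[region])
        best_conf[region] = np.where(take, confs[i], best_conf[region])
    covered = np.isfinite(best_conf)
    fg = (mask == 1) & covered
    out[fg] = best_cls[fg]
    return out


def majority_vote(maps) -> np.ndarray:
    """Pixel-wise mode across semantic maps; ties -> smallest label.

    Permutation-invariant in the map list and idempotent on unanimous input.
    """
    maps = [np.asarray(m) for m in maps]
    if not maps:
        raise ValueError("majority_vote needs at least one map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("all maps must share one shape")
    stack = np.stack(maps)
    n_labels = int(stack.max()) + 1
    counts = np.zeros((n_labels,) + shape, dtype=np.int32)
    for lab in range(n_labels):
        counts[lab] = np.sum(stack == lab, axis=0)
    # argmax returns the first (smallest) label on ties
    return counts.argmax(axis=0).astype(np.uint8)
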