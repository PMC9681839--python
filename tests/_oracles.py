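"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives the quantity by the most literal possible procedure
(per-pixel loops, per-cutoff confusion recounting) and shares no code with
the implementations it checks.
"""

from __future__ import annotations

import numpy as np

from pics.metrics import box_iou


def fuse_oracle(mask, detections):
    """Per-pixel literal evaluation of the box-mask fusion rules."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if mask[y, x] != 1:
                continue
            covering = [
                d for d in detections
                if d.box[0] <= x < d.box[2] and d.box[1] <= y < d.box[3]
            ]
            if not covering:
                continue
            best = max(covering, key=lambda d: (d.confidence, -d.wbc_class))
            out[y, x] = best.wbc_class
    return out


def vote_oracle(votes):
    """Mode of a 1-D label vector; ties -> smallest label."""
    values, counts = np.unique(np.asarray(votes), return_counts=True)
    return int(values[counts == counts.max()].min())


def ap_oracle(dets, gts, iou_thr=0.5):
    """AP by per-cutoff confusion recounting.

    For every prefix of the confidence-ranked detection list the greedy
    matching is recomputed from scratch, giving one (precision, recall)
    point; AP is the integral of the running-max precision envelope over
    recall.  ``dets``: (image_id, box, confidence); ``gts``: (image_id, box).
    """
    if not gts:
        return 0.0 if dets else None
    ranked = sorted(dets, key=lambda d: -d[2])
    points = []
    for k in range(1, len(ranked) + 1):
        prefix = ranked[:k]
        claimed = set()
        tp = 0
        for img, box, _conf in prefix:
            best_j, best_iou = None, iou_thr
            for j, (gimg, gbox) in enumerate(gts):
                if gimg != img or j in claimed:
                    continue
                iou = box_iou(box, gbox)
                if iou >= best_iou:
                    best_j, best_iou = j, iou
            if best_j is not None:
                claimed.add(best_j)
                tp += 1
        points.append((tp / len(gts), tp / k))
    # integrate the right-max precision envelope over recall
    ap = 0.0
    prev_recall = 0.0
    for i, (recall, _) in enumerate(points):
        if recall > prev_recall:
            envelope = max(p for r, p in points[i:])
            ap += (recall - prev_recall) * envelope
            prev_recall = recall
    return ap


def random_detection_instance(rng, max_gt=4, max_det=6, size=32):
    """A random small detection problem for oracle comparisons."""
    from pics.detection import Detection

    gts, dets = [], []
    for img in range(int(rng.integers(1, 3))):
        for _ in range(int(rng.integers(0, max_gt + 1))):
            x0, y0 = rng.uniform(0, size - 8, 2)
            w, h = rng.uniform(4, 10, 2)
            gts.append((img, (x0, y0, x0 + w, y0 + h)))
        for _ in range(int(rng.integers(0, max_det + 1))):
            if gts and rng.random() < 0.6:  # perturb a GT box
                _, (x0, y0, x1, y1) = gts[rng.integers(0, len(gts))]
                jitter = rng.uniform(-3, 3, 4)
                box = (x0 + jitter[0], y0 + jitter[1],
                       max(x0 + jitter[0] + 2, x1 + jitter[2]),
                       max(y0 + jitter[1] + 2, y1 + jitter[3]))
            else:
                x0, y0 = rng.uniform(0, size - 8, 2)
                w, h = rng.uniform(4, 10, 2)
                box = (x0, y0, x0 + w, y0 + h)
            dets.append((img, box, float(rng.random())))
    return dets, gts
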