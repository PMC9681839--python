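"""WBC localization and classification with a compact anchor-based detector.

The full-scale study design uses a large pretrained detector; the
reproducible substance is its *training contract* — a compound focal
(classification) + smooth-L1 (box regression) loss, Adam optimization,
early stopping when validation mAP stops increasing for ``patience_epochs``
consecutive epochs, and selection of the highest-validation-mAP weights.
This module implements that contract around a small single-scale anchor
detector (three stride-2 convolution levels, per-anchor class sigmoids and
center/size box offsets); any detector exposing ``forward`` / ``state`` /
``load_state`` can be substituted.

Box regression targets are the classical normalized offsets
``(dx, dy, dw, dh) = ((gx - ax)/aw, (gy - ay)/ah, log(gw/aw), log(gh/ah))``
relative to the matched anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pics import harness, metrics
from pics._nn import Adam, BatchNorm2d, Conv2d, ReLU, Sequential

__all__ = [
    "Detection",
    "DetectorTrainConfig",
    "focal_value",
    "smooth_l1_value",
    "AnchorDetector",
    "train_detector",
    "detect",
    "nms",
]

_EPS = 1e-7


@dataclass
class Detection:
    """Axis-aligned box (x_min, y_min, x_max, y_max), 0-based half-open."""

    box: tuple[float, float, float, float]
    wbc_class: int
    confidence: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class DetectorTrainConfig:
    batch_size: int = 8
    learning_rate: float = 5e-5
    patience_epochs: int = 10
    max_epochs: int = 60
    base_channels: int = 8
    anchor_sizes: tuple[float, ...] = (16.0, 24.0, 34.0)
    focal_alpha: float = 0.25
    focal_gamma: float = 1.5
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    box_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be nonnegative")


def focal_value(p, y, alpha: float = 0.25, gamma: float = 1.5) -> float:
    """Mean focal loss over a batch of (probability, {0,1} target) pairs.

    For a positive target: ``-alpha (1-p)^gamma log p``; for a negative:
    ``-(1-alpha) p^gamma log(1-p)``.  ``gamma = 0, alpha = 0.5`` halves the
    ordinary binary cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    pos = -alpha * (1 - p) ** gamma * np.log(p)
    neg = -(1 - alpha) * p**gamma * np.log(1 - p)
    return float(np.mean(np.where(y == 1, pos, neg)))


def smooth_l1_value(r) -> float:
    """Huber-style loss: 0.5 r^2 for |r| < 1, |r| - 0.5 otherwise (mean)."""
    r = np.abs(np.asarray(r, dtype=np.float64))
    return float(np.mean(np.where(r < 1.0, 0.5 * r * r, r - 0.5)))


def _focal_grad_logit(p, y, alpha, gamma):
    """d(focal)/d(logit), elementwise (no batch normalization applied)."""
    p = np.clip(p, _EPS, 1 - _EPS)
    q = 1.0 - p
    # y=1: dL/dp = alpha * gamma * q^(g-1) * log p - alpha * q^g / p
    dpos = alpha * (gamma * q ** max(gamma - 1, 0) * np.log(p) - q**gamma / p)
    # y=0: dL/dp = -(1-alpha) * (gamma * p^(g-1) * log q * (-1)? )
    dneg = -(1 - alpha) * (gamma * p ** max(gamma - 1, 0) * np.log(q) - p**gamma / q)
    dldp = np.where(y == 1, dpos, dneg)
    return dldp * p * q  # chain through sigmoid


def _smooth_l1_grad(r):
    return np.clip(r, -1.0, 1.0)


class AnchorDetector:
    """Single-scale anchor head on a three-level stride-8 backbone."""

    stride = 8

    def __init__(self, base: int = 8, anchor_sizes=(16.0, 24.0, 34.0),
                 n_classes: int = 4, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        b = base
        self.anchor_sizes = tuple(float(s) for s in anchor_sizes)
        self.n_classes = n_classes
        self.backbone = Sequential(
            Conv2d(3, b, 3, stride=2, rng=rng), BatchNorm2d(b), ReLU(),
            Conv2d(b, 2 * b, 3, stride=2, rng=rng), BatchNorm2d(2 * b), ReLU(),
            Conv2d(2 * b, 4 * b, 3, stride=2, rng=rng), BatchNorm2d(4 * b), ReLU(),
        )
        a = len(self.anchor_sizes)
        self.head = Conv2d(4 * b, a * (n_classes + 4), 3, rng=rng)
        # bias so initial class probabilities sit near 0.01 (focal-loss warmup)
        bias = self.head.b.value.reshape(a, n_classes + 4)
        bias[:, : n_classes] = -np.log(99.0)
        self._blocks = [self.backbone, self.head]

    def params(self):
        return [p for blk in self._blocks for p in blk.params()]

    def state(self):
        return [a for blk in self._blocks for a in blk.state()]

    def load_state(self, state):
        i = 0
        for blk in self._blocks:
            n = len(blk.state())
            blk.load_state(state[i : i + n])
            i += n

    def forward(self, x, train=False):
        """Returns (class_logits, box_offsets): (N, A, C) and (N, A, 4)."""
        h = self.backbone.forward(x, train)
        out = self.head.forward(h, train)
        n, _, fh, fw = out.shape
        a, c = len(self.anchor_sizes), self.n_classes
        out = out.reshape(n, a, c + 4, fh, fw).transpose(0, 3, 4, 1, 2)
        out = out.reshape(n, fh * fw * a, c + 4)
        self._feat_shape = (fh, fw)
        return out[..., :c], out[..., c:]

    def backward(self, g_cls, g_box):
        fh, fw = self._feat_shape
        n = g_cls.shape[0]
        a, c = len(self.anchor_sizes), self.n_classes
        g = np.concatenate([g_cls, g_box], axis=2)
        g = g.reshape(n, fh, fw, a, c + 4).transpose(0, 3, 4, 1, 2)
        g = g.reshape(n, a * (c + 4), fh, fw).astype(np.float32)
        self.backbone.backward(self.head.backward(g))

    def anchors(self, image_hw) -> np.ndarray:
        """(A_total, 4) anchor boxes (x0, y0, x1, y1) for an image size."""
        h, w = image_hw
        fh, fw = h // self.stride, w // self.stride
        cy = (np.arange(fh) + 0.5) * self.stride
        cx = (np.arange(fw) + 0.5) * self.stride
        boxes = []
        for y in cy:
            for x in cx:
                for s in self.anchor_sizes:
                    boxes.append((x - s / 2, y - s / 2, x + s / 2, y + s / 2))
        return np.asarray(boxes)


def _assign_targets(anchors, gt_boxes, gt_classes, pos_iou, neg_iou, n_classes):
    """Per-anchor class targets (C one-hot / -1 ignore rows) and box targets."""
    na = len(anchors)
    cls_t = np.zeros((na, n_classes), dtype=np.float64)
    ignore = np.zeros(na, dtype=bool)
    box_t = np.zeros((na, 4), dtype=np.float64)
    positive = np.zeros(na, dtype=bool)
    if len(gt_boxes):
        ious = np.zeros((na, len(gt_boxes)))
        for j, gb in enumerate(gt_boxes):
            for i, ab in enumerate(anchors):
                ious[i, j] = metrics.box_iou(ab, gb)
        best_gt = ious.argmax(axis=1)
        best_iou = ious.max(axis=1)
        positive = best_iou >= pos_iou
        for j in range(len(gt_boxes)):
            positive[ious[:, j].argmax()] = True  # best anchor per GT
            best_gt[ious[:, j].argmax()] = j
        ignore = (~positive) & (best_iou >= neg_iou)
        for i in np.nonzero(positive)[0]:
            gb = gt_boxes[best_gt[i]]
            ab = anchors[i]
            aw, ah = ab[2] - ab[0], ab[3] - ab[1]
            acx, acy = (ab[0] + ab[2]) / 2, (ab[1] + ab[3]) / 2
            gw, gh = gb[2] - gb[0], gb[3] - gb[1]
            gcx, gcy = (gb[0] + gb[2]) / 2, (gb[1] + gb[3]) / 2
            box_t[i] = ((gcx - acx) / aw, (gcy - acy) / ah,
                        np.log(gw / aw), np.log(gh / ah))
            cls_t[i, gt_classes[best_gt[i]] - 1] = 1.0
    return cls_t, box_t, positive, ignore


def train_detector(images, annotations, train_ids, val_ids,
                   config: DetectorTrainConfig, val_map_fn=None):
    """Train the detector; stop when val mAP stalls, keep the best-mAP weights.

    ``images``: [0, 1] HxWx3 arrays; ``annotations[i]``: list of
    ``(box, class_id)`` ground truth for image i.  ``val_map_fn(model, epoch)``
    may replace the built-in validation-mAP pass.  Returns
    ``(model, FitResult)``; raises if the training set holds no annotations.
    """
    if not train_ids or not val_ids:
        raise ValueError("train and validation sets must be nonempty")
    if not any(annotations[i] for i in train_ids):
        raise ValueError("no annotated WBCs in the training set")
    rng = np.random.default_rng(config.seed)
    model = AnchorDetector(base=config.base_channels, anchor_sizes=config.anchor_sizes,
                           rng=np.random.default_rng(rng.integers(2**31)))
    opt = Adam(model.params(), lr=config.learning_rate)
    hw = np.asarray(images[train_ids[0]]).shape[:2]
    anchors = model.anchors(hw)
    targets = {}
    for i in list(train_ids):
        boxes = [b for b, _ in annotations[i]]
        classes = [c for _, c in annotations[i]]
        targets[i] = _assign_targets(anchors, boxes, classes,
                                     config.pos_iou, config.neg_iou, model.n_classes)

    def to_x(i):
        return np.asarray(images[i], dtype=np.float32).transpose(2, 0, 1)

    def train_epoch(_epoch):
        order = rng.permutation(len(train_ids))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = [train_ids[j] for j in order[start : start + config.batch_size]]
            x = np.stack([to_x(i) for i in idx])
            cls_t = np.stack([targets[i][0] for i in idx])
            box_t = np.stack([targets[i][1] for i in idx])
            pos = np.stack([targets[i][2] for i in idx])
            ign = np.stack([targets[i][3] for i in idx])

            opt.zero_grad()
            logits, offsets = model.forward(x, train=True)
            p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            n_pos = max(int(pos.sum()), 1)
            valid = (~ign)[..., None]
            loss_cls = float(np.sum(np.where(
                valid,
                np.where(cls_t == 1,
                         -config.focal_alpha * (1 - np.clip(p, _EPS, 1 - _EPS)) ** config.focal_gamma
                         * np.log(np.clip(p, _EPS, None)),
                         -(1 - config.focal_alpha) * np.clip(p, _EPS, 1 - _EPS) ** config.focal_gamma
                         * np.log(np.clip(1 - p, _EPS, None))),
                0.0)) / n_pos)
            g_cls = np.where(valid,
                             _focal_grad_logit(p, cls_t, config.focal_alpha, config.focal_gamma),
                             0.0) / n_pos
            r = offsets - box_t
            loss_box = float(np.sum(np.where(pos[..., None],
                                             np.where(np.abs(r) < 1, 0.5 * r * r, np.abs(r) - 0.5),
                                             0.0)) / (4 * n_pos))
            g_box = np.where(pos[..., None], _smooth_l1_grad(r), 0.0) / (4 * n_pos)
            model.backward(g_cls.astype(np.float32),
                           (config.box_loss_weight * g_box).astype(np.float32))
            opt.step()
            losses.append(loss_cls + config.box_loss_weight * loss_box)
        return float(np.mean(losses))

    def evaluate(epoch):
        if val_map_fn is not None:
            return float(val_map_fn(model, epoch))
        dets, gts = [], []
        for i in val_ids:
            for d in detect(model, images[i], score_threshold=0.05):
                dets.append((i, d.box, d.wbc_class, d.confidence))
            for b, c in annotations[i]:
                gts.append((i, tuple(b), c))
        if not gts:
            return 0.0
        return metrics.evaluate_detections(dets, gts)["mAP"]

    result = harness.fit_loop(train_epoch, evaluate, snapshot=model.state,
                              max_epochs=config.max_epochs,
                              patience=config.patience_epochs, mode="max")
    model.load_state(result.best_state)
    return model, result


def nms(boxes, scores, iou_thr: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = sorted(range(len(boxes)), key=lambda i: -scores[i])
    keep = []
    for i in order:
        if all(metrics.box_iou(boxes[i], boxes[j]) < iou_thr for j in keep):
            keep.append(i)
    return keep


def detect(model: AnchorDetector, image, score_threshold: float = 0.5,
           nms_iou: float = 0.5) -> list[Detection]:
    """Decode, threshold and class-wise NMS; confidence-descending output."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    h, w = img.shape[:2]
    logits, offsets = model.forward(img.transpose(2, 0, 1)[None], train=False)
    p = 1.0 / (1.0 + np.exp(-np.clip(logits[0], -60, 60)))
    anchors = model.anchors((h, w))
    results: list[Detection] = []
    for k in range(model.n_classes):
        scores = p[:, k]
        sel = np.nonzero(scores >= score_threshold)[0]
        if score_threshold >= 1.0 or len(sel) == 0:
            continue
        boxes = []
        for i in sel:
            ax0, ay0, ax1, ay1 = anchors[i]
            aw, ah = ax1 - ax0, ay1 - ay0
            acx, acy = (ax0 + ax1) / 2, (ay0 + ay1) / 2
            dx, dy, dw, dh = offsets[0, i]
            dw, dh = np.clip(dw, -4, 4), np.clip(dh, -4, 4)
            bw, bh = aw * np.exp(dw), ah * np.exp(dh)
            bcx, bcy = acx + dx * aw, acy + dy * ah
            x0, x1 = bcx - bw / 2, bcx + bw / 2
            y0, y1 = bcy - bh / 2, bcy + bh / 2
            x0, y0 = max(x0, 0.0), max(y0, 0.0)
            x1, y1 = min(x1, float(w)), min(y1, float(h))
            if x1 - x0 < 1.0 or y1 - y0 < 1.0:
                boxes.append(None)
            else:
                boxes.append((x0, y0, x1, y1))
        valid = [j for j, b in enumerate(boxes) if b is not None]
        kept = nms([boxes[j] for j in valid], [scores[sel[j]] for j in valid], nms_iou)
        for j in kept:
            results.append(Detection(box=boxes[valid[j]], wbc_class=k + 1,
                                     confidence=float(scores[sel[valid[j]]])))
    results.sort(key=lambda d: -d.confidence)
    return results
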