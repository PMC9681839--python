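"""Binary WBC-vs-background segmentation with a compact U-Net.

The network has five convolution blocks on the contracting side (four of
them followed by 2x2 max pooling, the fifth acting as the bottleneck, so the
input only needs to be divisible by 2^4) and four up-sampling blocks with
skip connections on the expanding side.  Each block is ``convs_per_block``
3x3 convolution + batch-norm + rectifier stages (default 2) with channel
doubling per level.  A 1x1 convolution with a sigmoid head yields a per-pixel
WBC probability, trained against {0, 1} masks with mean-squared-error loss;
early stopping monitors validation MSE with the lowest-loss snapshot kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pics import harness
from pics._nn import Adam, BatchNorm2d, Conv2d, MaxPool2d, ReLU, Sequential, Sigmoid, Upsample2x

__all__ = ["SegTrainConfig", "UNet", "mse_value", "train_segmenter", "segment"]


@dataclass(frozen=True)
class SegTrainConfig:
    learning_rate: float = 3e-5
    batch_size: int = 2
    patience: int = 5
    binarize_threshold: float = 0.5
    max_epochs: int = 100
    base_channels: int = 8
    convs_per_block: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.convs_per_block not in (1, 2):
            raise ValueError("convs_per_block must be 1 or 2")


def mse_value(pred, target) -> float:
    """Mean squared per-pixel difference."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def _conv_block(in_ch, out_ch, n_convs, rng):
    layers = []
    for i in range(n_convs):
        layers += [Conv2d(in_ch if i == 0 else out_ch, out_ch, 3, rng=rng),
                   BatchNorm2d(out_ch), ReLU()]
    return Sequential(*layers)


class UNet:
    """5 contracting blocks (4 pooled) / 4 expanding blocks with skips."""

    def __init__(self, base: int = 8, in_ch: int = 3, convs_per_block: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        b = base
        chans = [b, 2 * b, 4 * b, 8 * b, 16 * b]
        self.down = []
        c_in = in_ch
        for c in chans[:4]:
            self.down.append(_conv_block(c_in, c, convs_per_block, rng))
            c_in = c
        self.pool = [MaxPool2d() for _ in range(4)]
        self.bottleneck = _conv_block(chans[3], chans[4], convs_per_block, rng)
        self.up_sample = [Upsample2x() for _ in range(4)]
        self.up = []
        c_in = chans[4]
        for c in reversed(chans[:4]):
            self.up.append(_conv_block(c_in + c, c, convs_per_block, rng))
            c_in = c
        self.head = Sequential(Conv2d(b, 1, 1, pad=0, rng=rng), Sigmoid())
        self._blocks = self.down + [self.bottleneck] + self.up + [self.head]

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
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError(f"spatial size must be divisible by 16, got {x.shape[2:]}")
        skips = []
        h = x
        for blk, pool in zip(self.down, self.pool):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_chans = []
        for blk, up, skip in zip(self.up, self.up_sample, reversed(skips)):
            h = up.forward(h, train)
            self._skip_chans.append(h.shape[1])
            h = blk.forward(np.concatenate([h, skip], axis=1), train)
        return self.head.forward(h, train)

    def backward(self, gy):
        g = self.head.backward(gy)
        gskips = []
        for blk, up, c in zip(reversed(self.up), reversed(self.up_sample),
                              reversed(self._skip_chans)):
            gcat = blk.backward(g)
            gskips.append(gcat[:, c:])
            g = up.backward(gcat[:, :c])
        g = self.bottleneck.backward(g)
        # gskips is ordered like self.down (collected shallow-most first);
        # walk back down the contracting path, merging skip gradients
        for i in range(3, -1, -1):
            g = self.pool[i].backward(g) + gskips[i]
            g = self.down[i].backward(g)
        return g


def train_segmenter(images, masks, train_ids, val_ids, config: SegTrainConfig,
                    val_loss_fn=None):
    """Train the U-Net; early stop on validation MSE (patience rule, min snapshot).

    ``images``: [0, 1] HxWx3 arrays; ``masks``: {0, 1} HxW arrays.
    ``val_loss_fn(model, epoch) -> float`` may replace the built-in validation
    pass (used to exercise the stopping rule in isolation).  Returns
    ``(model, FitResult)``.
    """
    if not train_ids or not val_ids:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    model = UNet(base=config.base_channels, convs_per_block=config.convs_per_block,
                 rng=np.random.default_rng(rng.integers(2**31)))
    opt = Adam(model.params(), lr=config.learning_rate)

    def to_x(i):
        return np.asarray(images[i], dtype=np.float32).transpose(2, 0, 1)

    def train_epoch(_epoch):
        order = rng.permutation(len(train_ids))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = [train_ids[j] for j in order[start : start + config.batch_size]]
            x = np.stack([to_x(i) for i in idx])
            t = np.stack([np.asarray(masks[i], dtype=np.float32) for i in idx])[:, None]
            opt.zero_grad()
            p = model.forward(x, train=True)
            g = (2.0 * (p - t) / p.size).astype(np.float32)
            model.backward(g)
            opt.step()
            losses.append(mse_value(p, t))
        return float(np.mean(losses))

    def evaluate(epoch):
        if val_loss_fn is not None:
            return float(val_loss_fn(model, epoch))
        losses = []
        for i in val_ids:
            p = model.forward(to_x(i)[None], train=False)[0, 0]
            losses.append(mse_value(p, np.asarray(masks[i], dtype=np.float64)))
        return float(np.mean(losses))

    result = harness.fit_loop(train_epoch, evaluate, snapshot=model.state,
                              max_epochs=config.max_epochs,
                              patience=config.patience, mode="min")
    model.load_state(result.best_state)
    return model, result


def segment(model: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Probability map thresholded into a {0, 1} mask; ties go to foreground."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = np.repeat(x[..., None], 3, axis=2)
    p = model.forward(x.transpose(2, 0, 1)[None], train=False)[0, 0]
    return (p >= threshold).astype(np.uint8)
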