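"""Conditional-GAN phase -> Wright-stain brightfield translation.

The generator G maps a normalized phase image x (plus noise z, realized as
train-time dropout in the decoder) to a color image; the discriminator D
sees the (x, image) pair and outputs patch-wise real probabilities.  They
play the adversarial game

    L_cGAN(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x, z)))]

which the discriminator ascends; the generator descends the second term
combined with a pixel-wise L1 term weighted by ``lambda_l1`` (default 100,
the pix2pix convention) for stable training.  The training harness keeps the
weights with the lowest validation loss.

The networks are deliberately compact (depth-3 encoder–decoder with skip
connections, two-level patch discriminator): the reproducible substance is
the objective and the harness contract, not backbone scale, and both
generator and discriminator sizes are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pics import harness
from pics._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout,
    LeakyReLU,
    ReLU,
    Sequential,
    Sigmoid,
    Tanh,
    Upsample2x,
)

__all__ = [
    "TranslationTrainConfig",
    "cgan_value",
    "l1_value",
    "generator_objective",
    "Generator",
    "PatchDiscriminator",
    "train_translator",
    "translate",
    "normalize_phase",
]

_EPS = 1e-7  # probability clamp inside logs


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def cgan_value(d_real, d_fake) -> float:
    """mean(log d_real) + mean(log(1 - d_fake)); the discriminator ascends this."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability batch")
    return float(np.mean(np.log(_clamp(d_real))) + np.mean(np.log1p(-_clamp(d_fake))))


def l1_value(pred, target) -> float:
    """Mean absolute pixel difference over all pixels and channels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(pred - target)))


def generator_objective(d_fake, pred, target, lambda_l1: float = 100.0) -> float:
    """mean(log(1 - d_fake)) + lambda_l1 * L1(pred, target); G minimizes this."""
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if d_fake.size == 0:
        raise ValueError("empty probability batch")
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be nonnegative")
    return float(np.mean(np.log1p(-_clamp(d_fake))) + lambda_l1 * l1_value(pred, target))


@dataclass(frozen=True)
class TranslationTrainConfig:
    learning_rate: float = 2e-4
    batch_size: int = 2
    input_size: tuple[int, int] = (512, 512)
    lambda_l1: float = 100.0
    max_epochs: int = 50
    patience: int | None = None  # None: fixed epoch budget, best-val snapshot
    base_channels: int = 8
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        h, w = self.input_size
        if h <= 0 or w <= 0 or h % 8 or w % 8:
            raise ValueError("input_size must be positive and divisible by 8")


class Generator:
    """Depth-3 encoder–decoder with skip connections and tanh output in [-1, 1]."""

    def __init__(self, base: int = 8, in_ch: int = 3, out_ch: int = 3,
                 dropout: float = 0.5, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        b = base
        self.e1 = Sequential(Conv2d(in_ch, b, 3, stride=2, rng=rng), LeakyReLU())
        self.e2 = Sequential(Conv2d(b, 2 * b, 3, stride=2, rng=rng), BatchNorm2d(2 * b), LeakyReLU())
        self.e3 = Sequential(Conv2d(2 * b, 4 * b, 3, stride=2, rng=rng), BatchNorm2d(4 * b), LeakyReLU())
        self.d3 = Sequential(Upsample2x(), Conv2d(4 * b, 2 * b, 3, rng=rng), BatchNorm2d(2 * b),
                             ReLU(), Dropout(dropout, rng))
        self.d2 = Sequential(Upsample2x(), Conv2d(4 * b, b, 3, rng=rng), BatchNorm2d(b), ReLU())
        self.d1 = Sequential(Upsample2x(), Conv2d(2 * b, out_ch, 3, rng=rng), Tanh())
        self._blocks = [self.e1, self.e2, self.e3, self.d3, self.d2, self.d1]

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
        h1 = self.e1.forward(x, train)
        h2 = self.e2.forward(h1, train)
        h3 = self.e3.forward(h2, train)
        u3 = self.d3.forward(h3, train)
        u2 = self.d2.forward(np.concatenate([u3, h2], axis=1), train)
        y = self.d1.forward(np.concatenate([u2, h1], axis=1), train)
        self._split = (u3.shape[1], u2.shape[1])
        return y

    def backward(self, gy):
        c3, c2 = self._split
        g = self.d1.backward(gy)
        gu2, gh1 = g[:, :c2], g[:, c2:]
        g = self.d2.backward(gu2)
        gu3, gh2 = g[:, :c3], g[:, c3:]
        gh3 = self.d3.backward(gu3)
        gh2 = gh2 + self.e3.backward(gh3)
        gh1 = gh1 + self.e2.backward(gh2)
        return self.e1.backward(gh1)


class PatchDiscriminator(Sequential):
    """Two-level patch discriminator on the concatenated (x, image) pair."""

    def __init__(self, base: int = 8, in_ch: int = 6, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        b = base
        super().__init__(
            Conv2d(in_ch, b, 3, stride=2, rng=rng),
            LeakyReLU(),
            Conv2d(b, 2 * b, 3, stride=2, rng=rng),
            BatchNorm2d(2 * b),
            LeakyReLU(),
            Conv2d(2 * b, 1, 3, rng=rng),
            Sigmoid(),
        )


def normalize_phase(phi: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Rescale a phase map to [0, 1] by dataset percentiles (1st–99th)."""
    if hi <= lo:
        return np.zeros_like(phi, dtype=np.float64)
    return np.clip((phi - lo) / (hi - lo), 0.0, 1.0)


def _to_nchw(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    return img.transpose(2, 0, 1)


def _resize_to(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == tuple(size):
        return img
    from skimage.transform import resize

    return resize(img, size, order=1, preserve_range=True, anti_aliasing=True)


def train_translator(pairs, train_ids, val_ids, config: TranslationTrainConfig):
    """Train the cGAN on (input, target) image pairs; keep lowest-val-loss weights.

    ``pairs`` is a sequence of ``(x, y)`` with values in [0, 1] (HxW or
    HxWx3); images are resized to ``config.input_size`` and mapped to
    [-1, 1].  Returns ``(generator, FitResult)``; the fit log carries the
    combined GAN + L1 objective per epoch (train and validation).
    """
    if not train_ids or not val_ids:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)

    def prep(i):
        x, y = pairs[i]
        x = _resize_to(np.asarray(x, dtype=np.float64), config.input_size)
        y = _resize_to(np.asarray(y, dtype=np.float64), config.input_size)
        return (_to_nchw(x) * 2 - 1), (_to_nchw(y) * 2 - 1)

    train_data = [prep(i) for i in train_ids]
    val_data = [prep(i) for i in val_ids]

    gen = Generator(base=config.base_channels, dropout=config.dropout,
                    rng=np.random.default_rng(rng.integers(2**31)))
    disc = PatchDiscriminator(base=config.base_channels,
                              rng=np.random.default_rng(rng.integers(2**31)))
    opt_g = Adam(gen.params(), lr=config.learning_rate, beta1=0.5)
    opt_d = Adam(disc.params(), lr=config.learning_rate, beta1=0.5)
    lam = config.lambda_l1

    def train_epoch(_epoch):
        order = rng.permutation(len(train_data))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = np.stack([train_data[i][0] for i in idx])
            y = np.stack([train_data[i][1] for i in idx])

            # --- discriminator ascends cgan_value -------------------------
            opt_d.zero_grad()
            fake = gen.forward(x, train=True)  # no G grads used this step
            d_real = disc.forward(np.concatenate([x, y], axis=1), train=True)
            g_real = (-1.0 / (_clamp(d_real) * d_real.size)).astype(np.float32)
            disc.backward(g_real)
            d_fake = disc.forward(np.concatenate([x, fake], axis=1), train=True)
            g_fake = (1.0 / ((1.0 - _clamp(d_fake)) * d_fake.size)).astype(np.float32)
            disc.backward(g_fake)
            opt_d.step()

            # --- generator descends log(1 - D) + lambda * L1 --------------
            opt_g.zero_grad()
            fake = gen.forward(x, train=True)
            pair = np.concatenate([x, fake], axis=1)
            d_fake = disc.forward(pair, train=True)
            gd = (-1.0 / ((1.0 - _clamp(d_fake)) * d_fake.size)).astype(np.float32)
            g_pair = disc.backward(gd)
            g_fake_img = g_pair[:, x.shape[1] :]
            g_l1 = (lam * np.sign(fake - y) / fake.size).astype(np.float32)
            gen.backward(g_fake_img + g_l1)
            opt_g.step()
            losses.append(generator_objective(d_fake, fake, y, lam))
        return float(np.mean(losses))

    def evaluate(_epoch):
        losses = []
        for x, y in val_data:
            xb = x[None]
            fake = gen.forward(xb, train=False)
            d_fake = disc.forward(np.concatenate([xb, fake], axis=1), train=False)
            losses.append(generator_objective(d_fake, fake, y[None], lam))
        return float(np.mean(losses))

    result = harness.fit_loop(
        train_epoch,
        evaluate,
        snapshot=gen.state,
        max_epochs=config.max_epochs,
        patience=config.patience,
        mode="min",
    )
    gen.load_state(result.best_state)
    return gen, result


def translate(gen: Generator, image: np.ndarray,
              input_size: tuple[int, int] | None = None) -> np.ndarray:
    """Apply a trained generator to one [0, 1] image; returns HxWx3 in [0, 1]."""
    img = np.asarray(image, dtype=np.float64)
    if input_size is not None:
        img = _resize_to(img, input_size)
    x = (_to_nchw(img) * 2 - 1)[None]
    y = gen.forward(x, train=False)[0]
    return np.clip((y.transpose(1, 2, 0) + 1) / 2, 0.0, 1.0)
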