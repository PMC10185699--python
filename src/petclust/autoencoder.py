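"""Convolutional autoencoder compressing 64 x 128 MIPs into 3072 features.

Architecture: the encoder is three 3x3 convolution stages with 16, 20 and
24 filters, each followed by ReLU and 2x2 max-pooling, taking a
128 x 64 x 1 image down to a 16 x 8 spatial map with 24 channels — 3072
values, the feature vector.  The decoder mirrors it
with four 3x3 convolutions (24, 20, 16, 1 filters), 2x2 nearest-neighbor
up-sampling after each of the first three, ReLU on the first three and a
sigmoid on the last, reconstructing the input shape with values in (0, 1).
Same padding throughout (required: three 2x2 poolings of 128 x 64 must land
on 16 x 8 to flatten to 3072).

Training uses Adam (default learning rate 0.01), batch size 4, 100 epochs,
and a 1:1 train/test split whose test half is monitoring only — features
are afterwards extracted for every subject from the same trained model.
The loss is per-pixel binary cross-entropy by default (natural for a
sigmoid output on [0, 1] images); mean squared error is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mip import MIPImage, MIP_HEIGHT, MIP_WIDTH
from . import nn

__all__ = [
    "AEArchitecture", "TrainConfig", "ConvAutoencoder", "TrainResult",
    "build_autoencoder", "train_autoencoder", "encode_features",
    "FEATURE_DIM",
]

FEATURE_DIM = 3072


@dataclass(frozen=True)
class AEArchitecture:
    """Filter counts of the encoder and decoder convolution stages."""

    encoder_filters: tuple[int, ...] = (16, 20, 24)
    decoder_filters: tuple[int, ...] = (24, 20, 16, 1)
    kernel: int = 3
    input_shape: tuple[int, int] = (MIP_HEIGHT, MIP_WIDTH)  # (H, W)

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        h, w = self.input_shape
        f = 2 ** len(self.encoder_filters)
        return (self.encoder_filters[-1], h // f, w // f)

    @property
    def feature_dim(self) -> int:
        c, h, w = self.bottleneck_shape
        return c * h * w


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for autoencoder training."""

    learning_rate: float = 0.01
    batch_size: int = 4
    epochs: int = 100
    split_fraction: float = 0.5
    loss: str = "bce"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.loss not in ("bce", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}; use 'bce' or 'mse'")


class ConvAutoencoder:
    """The network: stacked NumPy layers with explicit backprop."""

    def __init__(self, arch: AEArchitecture = AEArchitecture(), seed: int = 0):
        if arch.feature_dim != FEATURE_DIM:
            raise ValueError(
                f"architecture bottleneck {arch.bottleneck_shape} flattens to "
                f"{arch.feature_dim} values, expected {FEATURE_DIM}"
            )
        h, w = arch.input_shape
        f = 2 ** len(arch.encoder_filters)
        if h % f or w % f:
            raise ValueError(f"input shape {arch.input_shape} not divisible by {f}")
        self.arch = arch
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.enc_convs, self.enc_relus, self.pools = [], [], []
        c_in = 1
        for c_out in arch.encoder_filters:
            self.enc_convs.append(nn.Conv2D(c_in, c_out, rng, arch.kernel))
            self.enc_relus.append(nn.ReLU())
            self.pools.append(nn.MaxPool2())
            c_in = c_out
        self.dec_convs, self.dec_relus, self.ups = [], [], []
        for i, c_out in enumerate(arch.decoder_filters):
            self.dec_convs.append(nn.Conv2D(c_in, c_out, rng, arch.kernel))
            if i < len(arch.decoder_filters) - 1:
                self.dec_relus.append(nn.ReLU())
                self.ups.append(nn.Upsample2())
            c_in = c_out

    @property
    def parameters(self):
        out = []
        for conv in self.enc_convs + self.dec_convs:
            out.extend(conv.params)
        return out

    # ---- forward / backward -------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        expected = (x.shape[0], 1) + self.arch.input_shape
        if x.shape != expected:
            raise ValueError(f"expected batch shaped {expected}, got {x.shape}")
        return x

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Bottleneck activations, flattened to ``(N, 3072)``."""
        x = self._check_batch(x)
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            x = pool.forward(relu.forward(conv.forward(x)))
        return x.reshape(x.shape[0], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full pass; returns pre-sigmoid logits of the reconstruction."""
        x = self._check_batch(x)
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            x = pool.forward(relu.forward(conv.forward(x)))
        for i, conv in enumerate(self.dec_convs[:-1]):
            x = self.ups[i].forward(self.dec_relus[i].forward(conv.forward(x)))
        return self.dec_convs[-1].forward(x)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Decoder output in (0, 1), same shape as the input batch."""
        return nn.sigmoid(self.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dec_convs[-1].backward(dlogits)
        for i in reversed(range(len(self.dec_convs) - 1)):
            d = self.ups[i].backward(d)
            d = self.dec_relus[i].backward(d)
            d = self.dec_convs[i].backward(d)
        for conv, relu, pool in zip(reversed(self.enc_convs),
                                    reversed(self.enc_relus),
                                    reversed(self.pools)):
            d = pool.backward(d)
            d = relu.backward(d)
            d = conv.backward(d)

    def loss_on(self, x: np.ndarray, loss: str = "bce") -> float:
        x = self._check_batch(x)
        fn = nn.bce_loss_and_grad if loss == "bce" else nn.mse_loss_and_grad
        value, _ = fn(self.forward(x), x)
        return value

    # ---- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, conv in enumerate(self.enc_convs):
            state[f"enc{i}_W"], state[f"enc{i}_b"] = conv.W, conv.b
        for i, conv in enumerate(self.dec_convs):
            state[f"dec{i}_W"], state[f"dec{i}_b"] = conv.W, conv.b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.enc_convs):
            conv.W[...] = state[f"enc{i}_W"]
            conv.b[...] = state[f"enc{i}_b"]
        for i, conv in enumerate(self.dec_convs):
            conv.W[...] = state[f"dec{i}_W"]
            conv.b[...] = state[f"dec{i}_b"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, arch: AEArchitecture = AEArchitecture()) -> "ConvAutoencoder":
        model = cls(arch)
        with np.load(path) as data:
            model.load_state_dict(dict(data))
        return model


@dataclass
class TrainResult:
    history: pd.DataFrame  # columns: epoch, train_loss, test_loss
    train_indices: np.ndarray
    test_indices: np.ndarray


def build_autoencoder(arch: AEArchitecture = AEArchitecture(), seed: int = 0) -> ConvAutoencoder:
    """Instantiate the autoencoder with seeded weight initialization."""
    return ConvAutoencoder(arch, seed=seed)


def split_indices(n: int, fraction: float, rng: np.random.Generator):
    """Shuffled train/test split; a 1:1 split differs in size by at most 1."""
    perm = rng.permutation(n)
    n_train = int(np.ceil(n * fraction))
    return perm[:n_train], perm[n_train:]


def _stack(mips) -> np.ndarray:
    imgs = []
    for m in mips:
        px = m.pixels if isinstance(m, MIPImage) else np.asarray(m, dtype=float)
        if px.shape != (MIP_HEIGHT, MIP_WIDTH):
            raise ValueError(
                f"image shaped {px.shape}, expected ({MIP_HEIGHT}, {MIP_WIDTH})"
            )
        imgs.append(px)
    return np.stack(imgs)


def train_autoencoder(model: ConvAutoencoder, mips, cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Train in place; returns per-epoch train/test reconstruction losses.

    The cohort is split 1:1 (sizes differing by at most one) into a
    training half used for gradient steps and a test half scored after each
    epoch for monitoring.  Deterministic given ``cfg.seed``: the split, the
    per-epoch shuffling and nothing else consume the seeded generator.
    """
    x = _stack(mips)
    if len(x) < 2:
        raise ValueError("need at least 2 images to train")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("image values outside [0, 1]; normalize MIPs first")
    rng = np.random.default_rng(cfg.seed)
    train_idx, test_idx = split_indices(len(x), cfg.split_fraction, rng)
    x_train, x_test = x[train_idx], x[test_idx]

    loss_fn = nn.bce_loss_and_grad if cfg.loss == "bce" else nn.mse_loss_and_grad
    opt = nn.Adam(model.parameters, lr=cfg.learning_rate)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        batch_losses = []
        for start in range(0, len(x_train), cfg.batch_size):
            batch = x_train[order[start:start + cfg.batch_size]][:, None]
            logits = model.forward(batch)
            loss, dlogits = loss_fn(logits, batch)
            model.backward(dlogits)
            opt.step()
            batch_losses.append(loss)
        test_loss = model.loss_on(x_test, cfg.loss) if len(x_test) else np.nan
        rows.append((epoch, float(np.mean(batch_losses)), float(test_loss)))
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "test_loss"])
    return TrainResult(history=history, train_indices=train_idx, test_indices=test_idx)


def encode_features(model: ConvAutoencoder, mips, batch_size: int = 16) -> np.ndarray:
    """Extract the 3072-value bottleneck for every image, preserving order."""
    x = _stack(mips)
    chunks = [model.encode(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    feats = np.vstack(chunks)
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite values in encoded features")
    return feats
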