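"""The depth-of-anesthesia regressor: a 1-D deep residual shrinkage network
with channel-wise thresholds (DRSN-CW) and a 1x1-convolution head.

The four EEG channels enter as the channel dimension of a (4, 712) feature
map.  Stacked residual shrinkage units (ELU activations, learned channel-wise
soft thresholds) reduce it to a 1 x W x 16 representation; a 1x1 convolution
collapses the 16 channels, global average pooling yields a single value v,
and the prediction is squashed into the open interval (0, 100):

    p = 100 / (1 + exp(-v)).

Training minimizes mean squared error between p and the PSI label with Adam
(batch 64, initial learning rate 0.005 decaying by 10% every 20 epochs, L2
regularization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    RSBU,
    Adam,
    BatchNorm,
    Conv1d,
    ELU,
    GlobalAvgPool,
    Sequential,
    ShrinkageModule,
    soft_threshold,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Prediction",
    "ThresholdVector",
    "DRSNRegressor",
    "build_model",
    "channel_thresholds",
    "soft_threshold",
    "train",
    "predict_psi",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    lr: float = 0.005
    lr_decay: float = 0.9
    lr_decay_every: int = 20
    max_epochs: int = 256
    weight_decay: float = 1e-4
    seed: int = 0

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate of a 0-based epoch: lr * decay^(epoch // every)."""
        return self.lr * self.lr_decay ** (epoch // self.lr_decay_every)


@dataclass
class ModelConfig:
    """Architecture: each stack opens with a strided convolutional RSBU-CW and
    is followed by an identity RSBU-CW; the last stack must emit 16 channels."""

    in_channels: int = 4
    channels_per_stack: tuple[int, ...] = (8, 8, 16, 16)
    kernel_size: int = 3
    stride: int = 2
    training: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> None:
        problems = []
        if self.channels_per_stack[-1] != 16:
            problems.append("channels_per_stack must end at 16")
        if self.kernel_size < 1:
            problems.append("kernel_size must be >= 1")
        if self.training.lr <= 0:
            problems.append("training.lr must be positive")
        if problems:
            raise ValueError("invalid ModelConfig: " + "; ".join(problems))


@dataclass
class Prediction:
    v: float
    p: float


@dataclass
class ThresholdVector:
    """Per-channel thresholds and the intermediates that produce them."""

    x_avg: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray


def channel_thresholds(x: np.ndarray, module: ShrinkageModule) -> ThresholdVector:
    """Evaluate a shrinkage module's threshold path on a feature map.

    x_avg is the per-channel mean magnitude; alpha = sigmoid(z) with z from
    the two-layer FC net; tau = alpha * x_avg, so 0 <= tau <= x_avg.
    """
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    a, alpha, tau = module.thresholds(np.asarray(x, dtype=float), train=False)
    return ThresholdVector(x_avg=a, alpha=alpha, tau=tau)


class DRSNRegressor:
    """DRSN-CW feature extractor + 1x1-convolution regression head."""

    def __init__(self, config: ModelConfig | None = None, ablate_soft_threshold: bool = False,
                 dtype=np.float32):
        self.config = config or ModelConfig()
        self.config.validate()
        self.ablated = ablate_soft_threshold
        self.dtype = dtype  # float32 keeps training fast; gradients are exact either way
        rng = np.random.default_rng(self.config.training.seed)
        k, s = self.config.kernel_size, self.config.stride
        blocks: list = []
        cin = self.config.in_channels
        for cout in self.config.channels_per_stack:
            blocks.append(RSBU(cin, cout, k, stride=s, ablate=ablate_soft_threshold,
                               rng=rng, dtype=dtype))
            blocks.append(RSBU(cout, cout, k, stride=1, ablate=ablate_soft_threshold,
                               rng=rng, dtype=dtype))
            cin = cout
        blocks += [BatchNorm(cin, dtype=dtype), ELU()]
        self.body = Sequential(*blocks)
        self.head = Conv1d(cin, 1, 1, 1, rng, dtype)  # the 1x1 convolution
        self.pool = GlobalAvgPool()
        self.loss_history: list[float] = []
        self._trained = False

    # -- forward/backward ---------------------------------------------------

    def params(self):
        return self.body.params() + self.head.params()

    def forward_v(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Pre-activation values v for a batch (B, C, W)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (batch, {self.config.in_channels}, width) input, got {x.shape}"
            )
        r = self.body.forward(x, train)
        y = self.head.forward(r, train)          # (B, 1, W)
        return self.pool.forward(y, train)[:, 0]  # (B,)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """PSI predictions in (0, 100) for a batch, in evaluation mode."""
        out = []
        for i in range(0, len(x), 256):
            v = self.forward_v(x[i : i + 256], train=False)
            out.append(100.0 / (1.0 + np.exp(-v)))
        return np.concatenate(out)

    def _backward_from_v(self, gv: np.ndarray) -> None:
        g = self.pool.backward(gv[:, None])
        g = self.head.backward(g)
        self.body.backward(g)


def build_model(config: ModelConfig | None = None, ablate_soft_threshold: bool = False) -> DRSNRegressor:
    """Construct the regressor; the ablated variant drops only the
    soft-thresholding modules (layer shapes are unchanged)."""
    return DRSNRegressor(config, ablate_soft_threshold)


def predict_psi(model: DRSNRegressor, x: np.ndarray) -> Prediction:
    """Predict a single standardized (4, W) sample."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("predict_psi expects one (channels, width) sample")
    v = float(model.forward_v(x[None], train=False)[0])
    return Prediction(v=v, p=100.0 / (1.0 + np.exp(-v)))


def train(
    model: DRSNRegressor,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> list[float]:
    """Fit the model with Adam on MSE((p, PSI)); returns per-epoch losses.

    Deterministic given ``config.seed`` (initialization and shuffling both
    derive from it).
    """
    cfg = config or model.config.training
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ValueError("empty training set")
    if np.any(y < 0) or np.any(y > 100):
        raise ValueError("labels must lie in [0, 100]")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(x)
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(n)
        total = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            v = model.forward_v(xb, train=True)
            p = 100.0 / (1.0 + np.exp(-v))
            err = p - yb
            total += float(np.sum(err**2))
            # dL/dv = 2/B (p - y) * dp/dv, with dp/dv = p (100 - p) / 100
            gv = (2.0 / len(idx)) * err * p * (100.0 - p) / 100.0
            model._backward_from_v(gv)
            opt.step()
        model.loss_history.append(total / n)
        if verbose:
            print(f"epoch {epoch + 1}: mse={model.loss_history[-1]:.3f} lr={opt.lr:.5f}")
    model._trained = True
    return model.loss_history
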