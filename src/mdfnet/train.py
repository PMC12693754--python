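"""Training regimen: AdamW, warm-up/plateau/decay schedule, best-F1 checkpoint.

The learning rate ramps linearly from the floor to the peak over the warm-up
epochs, stays at the peak through the plateau, then decays geometrically
(log-linearly) to its final value over the decay epochs — continuous at both
joins, hitting the floor at epoch 0, the peak at the first plateau epoch and
the final value at the last epoch.  Validation F1 is computed at sample level
each epoch and the parameter snapshot with the highest value is kept (ties
resolved to the earliest epoch).  L2 regularization is realised as AdamW
decoupled weight decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import MDFNet, ModelConfig, FeatureShapes, classification_loss, LABEL_TO_INDEX
from .synth import ConfigurationError
from .transforms import WaveletConfig, stack_domain_features

__all__ = ["TrainConfig", "TrainResult", "lr_schedule", "AdamW", "train_model",
           "sample_f1"]

logger = logging.getLogger("mdfnet.train")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 512
    epochs: int = 500
    beta1: float = 0.9
    beta2: float = 0.99
    lr_floor: float = 1e-9
    lr_peak: float = 1e-5
    lr_final: float = 1e-7
    warmup_epochs: int = 100
    plateau_epochs: int = 200
    decay_epochs: int = 200
    weight_decay: float = 0.01
    label_smoothing: float = 0.1
    class_weights: tuple[float, float] = (0.8, 1.2)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.warmup_epochs + self.plateau_epochs + self.decay_epochs != self.epochs:
            raise ConfigurationError(
                "warmup + plateau + decay epochs must equal total epochs"
            )
        if not (self.lr_floor <= self.lr_final <= self.lr_peak):
            raise ConfigurationError("need lr_floor <= lr_final <= lr_peak")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be >= 1")

    @classmethod
    def scaled(cls, epochs: int = 50, lr_peak: float = 1e-3,
               batch_size: int = 128, rng_seed: int = 0) -> "TrainConfig":
        """A proportionally scaled-down schedule for desk-scale runs.

        The 1:2:2 warm-up/plateau/decay split is preserved and the learning
        rate endpoints are rescaled with the peak, so the relative shape of
        the schedule (and roughly the total optimizer displacement per unit
        data) matches the full regimen at a fraction of the cost.
        """
        ratio = lr_peak / 1e-5
        warm = max(1, epochs // 5)
        plat = max(1, (epochs - warm) // 2)
        decay = epochs - warm - plat
        return cls(
            batch_size=batch_size, epochs=epochs,
            lr_floor=1e-9 * ratio, lr_peak=lr_peak, lr_final=1e-7 * ratio,
            warmup_epochs=warm, plateau_epochs=plat, decay_epochs=decay,
            rng_seed=rng_seed,
        )


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise warm-up / plateau / geometric-decay learning rate."""
    cfg.validate()
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.warmup_epochs:
        frac = epoch / cfg.warmup_epochs
        return cfg.lr_floor + (cfg.lr_peak - cfg.lr_floor) * frac
    if epoch < cfg.warmup_epochs + cfg.plateau_epochs:
        return cfg.lr_peak
    start = cfg.warmup_epochs + cfg.plateau_epochs
    if cfg.decay_epochs == 1:
        return cfg.lr_final
    frac = (epoch - start) / (cfg.decay_epochs - 1)
    return float(cfg.lr_peak * (cfg.lr_final / cfg.lr_peak) ** frac)


class AdamW:
    """AdamW with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], beta1: float = 0.9,
                 beta2: float = 0.99, weight_decay: float = 0.01, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                            + self.weight_decay * p.data)


def sample_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 with PD (=1) as the positive class; 0 when precision+recall = 0."""
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


@dataclass
class TrainResult:
    model: MDFNet
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_f1: float
    history: pd.DataFrame = field(repr=False)


def _predict_in_batches(model: MDFNet, features: dict[str, np.ndarray],
                        batch_size: int = 512) -> np.ndarray:
    n = len(next(iter(features.values())))
    out = np.empty(n)
    for lo in range(0, n, batch_size):
        chunk = {k: v[lo:lo + batch_size] for k, v in features.items()}
        out[lo:lo + batch_size] = model.predict_proba(chunk)
    return out


def train_model(
    train_segments,
    val_segments,
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    wavelet_cfg: WaveletConfig = WaveletConfig(),
) -> TrainResult:
    """Train MDF-Net on segment lists; keep the best-validation-F1 snapshot."""
    train_cfg.validate()
    train_subjects = {s.subject_id for s in train_segments}
    val_subjects = {s.subject_id for s in val_segments}
    overlap = train_subjects & val_subjects
    if overlap:
        raise ValueError(f"subject leakage between train and val: {sorted(overlap)[:5]}")

    X_train, y_train, _ = stack_domain_features(train_segments, wavelet_cfg)
    X_val, y_val, _ = stack_domain_features(val_segments, wavelet_cfg)
    n_ch, n_time = X_train["time"].shape[1:]
    shapes = FeatureShapes(
        n_channels=n_ch, n_time=n_time,
        n_freq=X_train["freq"].shape[2], n_wavelet=X_train["wavelet"].shape[2],
    )
    model = MDFNet(model_cfg, shapes, rng_seed=train_cfg.rng_seed)
    opt = AdamW(model.params, train_cfg.beta1, train_cfg.beta2, train_cfg.weight_decay)

    n = len(y_train)
    best_f1, best_epoch, best_state = -1.0, -1, model.state_dict()
    rows = []
    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(epoch, train_cfg)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(train_cfg.rng_seed), 0xE90C, epoch])
        )
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            batch = {k: v[idx] for k, v in X_train.items()}
            model.zero_grad()
            logits, _ = model.forward(batch, training=True, rng=rng)
            loss = classification_loss(
                logits, y_train[idx],
                class_weights=train_cfg.class_weights,
                smoothing=train_cfg.label_smoothing,
            )
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
        probs = _predict_in_batches(model, X_val, train_cfg.batch_size)
        preds = (probs >= 0.5).astype(int)
        f1 = sample_f1(y_val, preds)
        rows.append({"epoch": epoch, "lr": lr,
                     "train_loss": float(np.mean(losses)), "val_f1": f1})
        if f1 > best_f1:  # strict: ties keep the earliest epoch
            best_f1, best_epoch = f1, epoch
            best_state = model.state_dict()
        logger.debug("epoch %d lr=%.3g loss=%.4f val_f1=%.4f", epoch, lr,
                     rows[-1]["train_loss"], f1)

    model.load_state_dict(best_state)
    return TrainResult(model=model, best_state=best_state, best_epoch=best_epoch,
                       best_f1=best_f1, history=pd.DataFrame(rows))
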