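"""MDF-Net: a multi-domain fusion network for EEG classification.

Three parallel branches consume the per-segment domain features:

* **T (temporal)** — a temporal convolutional network with causal dilated
  convolutions (TTCN).  Three residual blocks with output channels
  (64, 128, 64), kernel 3 and dilations (1, 2, 4); each block computes
  ``y = GELU(F(x) + R(x))`` where ``F`` is the dilated causal conv and ``R``
  a 1x1 conv whenever the channel dimension changes.  A learnable
  channel-attention gate on the raw 32-channel input supplies the per-channel
  attention map, and a temporal attention pooling head
  ``alpha_t = softmax_t(w^T Y(:, t))``, ``f = sum_t alpha_t Y(:, t)``
  collapses time.
* **F / W (frequency / wavelet)** — Cmix mixer branches.  After a 1x1 input
  projection (32 -> 64 channels) each of three stages applies a residual
  token mix across coefficients, ``g = x + GELU(x W_token)``, followed by a
  residual channel mix, ``g + GELU(W_channel g)``, with 1x1 projections
  between stages realising the (64, 128, 64) channel schedule.  Attention
  pooling over the coefficient axis yields the branch vector.

The pooled 64-d branch vectors of the enabled branches are concatenated and
mapped by a single linear head to 2 logits (HC vs PD).  The loss is
class-weighted cross-entropy on label-smoothed targets.

All attention weight vectors are softmax outputs, hence non-negative and
summing to one; they are returned on every forward pass for analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, einsum2, parameter
from .synth import ConfigurationError
from .transforms import DomainFeatures

__all__ = [
    "ModelConfig",
    "FeatureShapes",
    "MDFNet",
    "LABEL_TO_INDEX",
    "causal_dilated_conv",
    "ttcn_block",
    "temporal_attention_pool",
    "cmix_forward",
    "attention_pool",
    "classification_loss",
    "save_checkpoint",
    "load_checkpoint",
]

LABEL_TO_INDEX = {"HC": 0, "PD": 1}


@dataclass(frozen=True)
class ModelConfig:
    ttcn_channels: tuple[int, ...] = (64, 128, 64)
    ttcn_kernel: int = 3
    ttcn_dilation_base: int = 2
    dropout: float = 0.2
    cmix_channels: tuple[int, ...] = (64, 128, 64)
    branches_enabled: tuple[str, ...] = ("T", "F", "W")
    n_classes: int = 2

    def validate(self) -> None:
        if not self.branches_enabled:
            raise ConfigurationError("at least one branch must be enabled")
        if any(b not in ("T", "F", "W") for b in self.branches_enabled):
            raise ConfigurationError(f"unknown branch in {self.branches_enabled}")
        if not self.ttcn_channels or not self.cmix_channels:
            raise ConfigurationError("channel tuples must be non-empty")
        if self.ttcn_kernel < 1:
            raise ConfigurationError("kernel size must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must be in [0, 1)")

    def dilations(self) -> tuple[int, ...]:
        # d_i = base^(i-1) for blocks i = 1..n
        return tuple(self.ttcn_dilation_base**i for i in range(len(self.ttcn_channels)))


@dataclass(frozen=True)
class FeatureShapes:
    """Input dimensions the parameter shapes depend on."""

    n_channels: int = 32
    n_time: int = 20
    n_freq: int = 11
    n_wavelet: int = 26


# --------------------------------------------------------------------------- #
# functional building blocks (Tensor in, Tensor out; batch-first [B, C, L])
# --------------------------------------------------------------------------- #
def _causal_conv(x: Tensor, weight: Tensor, bias: Tensor, dilation: int) -> Tensor:
    """Causal dilated 1-D convolution: output at t sees inputs at <= t only.

    The last kernel tap is aligned with the current time step, so a kernel
    [0, ..., 0, 1] is the identity.
    """
    k = weight.shape[2]
    t_len = x.shape[2]
    xp = x.pad_left((k - 1) * dilation)
    out = None
    for i in range(k):
        tap = einsum2("oc,bct->bot", weight[:, :, i], xp[:, :, i * dilation:i * dilation + t_len])
        out = tap if out is None else out + tap
    return out + bias.reshape(1, -1, 1)


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    return einsum2("oc,bcl->bol", weight, x) + bias.reshape(1, -1, 1)


def _ttcn_block(x: Tensor, conv_w: Tensor, conv_b: Tensor,
                res_w: Tensor | None, res_b: Tensor | None, dilation: int) -> Tensor:
    f = _causal_conv(x, conv_w, conv_b, dilation)
    r = x if res_w is None else _conv1x1(x, res_w, res_b)
    return (f + r).gelu()


def _temporal_attention_pool(y: Tensor, w: Tensor) -> tuple[Tensor, Tensor]:
    scores = einsum2("bct,c->bt", y, w)
    alpha = scores.softmax(axis=-1)
    pooled = einsum2("bct,bt->bc", y, alpha)
    return pooled, alpha

_attention_pool = _temporal_attention_pool  # same operation, coefficient axis


def _cmix_stage(x: Tensor, token_w: Tensor, token_b: Tensor,
                chan_w: Tensor, chan_b: Tensor) -> Tensor:
    g_token = x + (einsum2("bcf,fg->bcg", x, token_w) + token_b).gelu()
    g_chan = g_token + (einsum2("dc,bcf->bdf", chan_w, g_token) + chan_b.reshape(1, -1, 1)).gelu()
    return g_chan


# --------------------------------------------------------------------------- #
# single-matrix convenience wrappers (the shapes the math is written in)
# --------------------------------------------------------------------------- #
def causal_dilated_conv(x: np.ndarray, weight: np.ndarray, dilation: int,
                        bias: np.ndarray | None = None) -> np.ndarray:
    """Causal dilated conv of a [C, T] matrix with a [C_out, C, k] kernel."""
    w = Tensor(weight)
    b = Tensor(np.zeros(weight.shape[0]) if bias is None else bias)
    out = _causal_conv(Tensor(x[None]), w, b, dilation)
    return out.data[0]


def ttcn_block(x: np.ndarray, conv_w: np.ndarray, conv_b: np.ndarray,
               res_w: np.ndarray | None, res_b: np.ndarray | None,
               dilation: int) -> np.ndarray:
    """One residual TTCN block, y = GELU(F(x) + R(x)), on a [C, T] matrix."""
    out = _ttcn_block(
        Tensor(x[None]), Tensor(conv_w), Tensor(conv_b),
        None if res_w is None else Tensor(res_w),
        None if res_b is None else Tensor(res_b), dilation,
    )
    return out.data[0]


def temporal_attention_pool(y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attention pooling over time of a [C, T] map; returns (f_time, alpha)."""
    if not np.isfinite(y).all() or not np.isfinite(w).all():
        raise ValueError("non-finite attention inputs")
    pooled, alpha = _temporal_attention_pool(Tensor(np.asarray(y)[None]), Tensor(w))
    return pooled.data[0], alpha.data[0]


def attention_pool(m: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attention pooling over the coefficient axis of a [C, F] matrix."""
    return temporal_attention_pool(m, u)


def cmix_forward(x: np.ndarray, token_w: np.ndarray, token_b: np.ndarray,
                 chan_w: np.ndarray, chan_b: np.ndarray) -> np.ndarray:
    """One Cmix mixing stage (residual token mix then channel mix) on [C, F]."""
    out = _cmix_stage(Tensor(np.asarray(x)[None]), Tensor(token_w), Tensor(token_b),
                      Tensor(chan_w), Tensor(chan_b))
    return out.data[0]


# --------------------------------------------------------------------------- #
# loss
# --------------------------------------------------------------------------- #
def classification_loss(
    logits: Tensor,
    labels: np.ndarray,
    class_weights: tuple[float, float] = (0.8, 1.2),
    smoothing: float = 0.1,
) -> Tensor:
    """Class-weighted cross-entropy on label-smoothed targets.

    Targets are (1 - eps) on the true class with eps spread uniformly over
    all classes; the reduction is the weighted mean over the batch with
    per-sample weight taken from ``class_weights[label]``.
    """
    if not (0 <= smoothing < 1):
        raise ConfigurationError(f"smoothing must be in [0, 1), got {smoothing}")
    if any(w <= 0 for w in class_weights):
        raise ConfigurationError("class weights must be positive")
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    targets = np.full((n, k), smoothing / k)
    targets[np.arange(n), labels] += 1.0 - smoothing
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    logp = logits.log_softmax(axis=-1)
    per_sample = (Tensor(targets) * logp).sum(axis=-1) * (-1.0)
    return (per_sample * Tensor(w / w.sum())).sum()


# --------------------------------------------------------------------------- #
# the full network
# --------------------------------------------------------------------------- #
class MDFNet:
    """The multi-domain fusion network with toggleable branches."""

    def __init__(self, config: ModelConfig = ModelConfig(),
                 shapes: FeatureShapes = FeatureShapes(), rng_seed: int = 0):
        config.validate()
        self.config = config
        self.shapes = shapes
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xABD]))
        self._build()

    # ------------------------------------------------------------- parameters
    def _add(self, name: str, shape: tuple[int, ...], fan_in: int, fan_out: int,
             scale: float | None = None) -> None:
        if scale is None:
            scale = np.sqrt(2.0 / (fan_in + fan_out))
        self.params[name] = parameter(self._rng.normal(0.0, scale, size=shape))

    def _add_zeros(self, name: str, shape: tuple[int, ...]) -> None:
        self.params[name] = parameter(np.zeros(shape))

    def _build(self) -> None:
        cfg, sh = self.config, self.shapes
        c_in = sh.n_channels
        if "T" in cfg.branches_enabled:
            self._add("t.chan_att_v", (sh.n_time,), sh.n_time, 1, scale=0.01)
            prev = c_in
            for i, (cout, d) in enumerate(zip(cfg.ttcn_channels, cfg.dilations())):
                self._add(f"t.block{i}.conv_w", (cout, prev, cfg.ttcn_kernel),
                          prev * cfg.ttcn_kernel, cout)
                self._add_zeros(f"t.block{i}.conv_b", (cout,))
                if prev != cout:
                    self._add(f"t.block{i}.res_w", (cout, prev), prev, cout)
                    self._add_zeros(f"t.block{i}.res_b", (cout,))
                prev = cout
            self._add("t.att_w", (prev,), prev, 1, scale=0.01)
        for br, length in (("f", sh.n_freq), ("w", sh.n_wavelet)):
            if br.upper() not in cfg.branches_enabled:
                continue
            self._add(f"{br}.proj_w", (cfg.cmix_channels[0], c_in), c_in, cfg.cmix_channels[0])
            self._add_zeros(f"{br}.proj_b", (cfg.cmix_channels[0],))
            prev = cfg.cmix_channels[0]
            for s, cdim in enumerate(cfg.cmix_channels):
                if cdim != prev:
                    self._add(f"{br}.stage{s}.proj_w", (cdim, prev), prev, cdim)
                    self._add_zeros(f"{br}.stage{s}.proj_b", (cdim,))
                self._add(f"{br}.stage{s}.token_w", (length, length), length, length)
                self._add_zeros(f"{br}.stage{s}.token_b", (length,))
                self._add(f"{br}.stage{s}.chan_w", (cdim, cdim), cdim, cdim)
                self._add_zeros(f"{br}.stage{s}.chan_b", (cdim,))
                prev = cdim
            self._add(f"{br}.att_u", (prev,), prev, 1, scale=0.01)
        fusion_in = 0
        if "T" in cfg.branches_enabled:
            fusion_in += cfg.ttcn_channels[-1]
        fusion_in += cfg.cmix_channels[-1] * sum(b in cfg.branches_enabled for b in ("F", "W"))
        self._add("fusion_w", (cfg.n_classes, fusion_in), fusion_in, cfg.n_classes,
                  scale=0.01)
        self._add_zeros("fusion_b", (cfg.n_classes,))

    # ---------------------------------------------------------------- forward
    def _dropout(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if not training or p == 0:
            return x
        if rng is None:
            raise ValueError("training-mode forward requires an rng for dropout")
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def _forward_temporal(self, x: Tensor, training: bool,
                          rng: np.random.Generator | None) -> tuple[Tensor, Tensor, Tensor]:
        p = self.params
        scores = einsum2("bct,t->bc", x, p["t.chan_att_v"])
        alpha_ch = scores.softmax(axis=-1)
        n_ch = x.shape[1]
        gated = x * alpha_ch.reshape(x.shape[0], n_ch, 1) * float(n_ch)
        h = gated
        for i, d in enumerate(self.config.dilations()):
            res_w = p.get(f"t.block{i}.res_w")
            res_b = p.get(f"t.block{i}.res_b")
            h = _ttcn_block(h, p[f"t.block{i}.conv_w"], p[f"t.block{i}.conv_b"],
                            res_w, res_b, d)
            h = self._dropout(h, training, rng)
        pooled, alpha_t = _temporal_attention_pool(h, p["t.att_w"])
        return pooled, alpha_ch, alpha_t

    def _forward_cmix(self, br: str, x: Tensor, training: bool,
                      rng: np.random.Generator | None) -> tuple[Tensor, Tensor]:
        p = self.params
        h = _conv1x1(x, p[f"{br}.proj_w"], p[f"{br}.proj_b"])
        for s in range(len(self.config.cmix_channels)):
            if f"{br}.stage{s}.proj_w" in p:
                h = _conv1x1(h, p[f"{br}.stage{s}.proj_w"], p[f"{br}.stage{s}.proj_b"])
            h = _cmix_stage(h, p[f"{br}.stage{s}.token_w"], p[f"{br}.stage{s}.token_b"],
                            p[f"{br}.stage{s}.chan_w"], p[f"{br}.stage{s}.chan_b"])
            h = self._dropout(h, training, rng)
        pooled, alpha = _attention_pool(h, p[f"{br}.att_u"])
        return pooled, alpha

    def forward(self, features: dict[str, np.ndarray] | DomainFeatures,
                training: bool = False,
                rng: np.random.Generator | None = None) -> tuple[Tensor, dict[str, np.ndarray]]:
        """Run the enabled branches and the fusion head.

        `features` maps 'time'/'freq'/'wavelet' to [B, C, L] arrays (a single
        DomainFeatures bundle is promoted to a batch of one).  Returns the
        [B, n_classes] logits Tensor and the per-branch attention weights.
        """
        if isinstance(features, DomainFeatures):
            features = {
                "time": features.time[None],
                "freq": features.freq[None],
                "wavelet": features.wavelet[None],
            }
        cfg = self.config
        needed = {"T": "time", "F": "freq", "W": "wavelet"}
        pooled_vecs: list[Tensor] = []
        attn: dict[str, np.ndarray] = {}
        for branch in ("T", "F", "W"):
            if branch not in cfg.branches_enabled:
                continue
            key = needed[branch]
            if key not in features or features[key] is None:
                raise ConfigurationError(f"branch {branch} enabled but '{key}' feature missing")
            x = Tensor(np.asarray(features[key], dtype=np.float64))
            if branch == "T":
                pooled, alpha_ch, alpha_t = self._forward_temporal(x, training, rng)
                attn["channel"] = alpha_ch.data
                attn["time"] = alpha_t.data
            else:
                pooled, alpha = self._forward_cmix(branch.lower(), x, training, rng)
                attn[key] = alpha.data
            pooled_vecs.append(pooled)
        fused = pooled_vecs[0] if len(pooled_vecs) == 1 else concat(pooled_vecs, axis=-1)
        logits = einsum2("bf,of->bo", fused, self.params["fusion_w"]) + self.params["fusion_b"]
        return logits, attn

    def predict_proba(self, features: dict[str, np.ndarray]) -> np.ndarray:
        """PD-class probability per sample (eval mode)."""
        logits, _ = self.forward(features, training=False)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return (e / e.sum(axis=-1, keepdims=True))[:, LABEL_TO_INDEX["PD"]]

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: np.array(v.data, copy=True) for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ConfigurationError("checkpoint parameter names do not match model")
        for k, v in state.items():
            if self.params[k].data.shape != v.shape:
                raise ConfigurationError(f"shape mismatch for {k}")
            self.params[k].data = np.array(v, dtype=np.float64, copy=True)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def save_checkpoint(model: MDFNet, path: str | Path) -> Path:
    """Serialize parameters (.npz) with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "config": {
            "ttcn_channels": list(model.config.ttcn_channels),
            "ttcn_kernel": model.config.ttcn_kernel,
            "ttcn_dilation_base": model.config.ttcn_dilation_base,
            "dropout": model.config.dropout,
            "cmix_channels": list(model.config.cmix_channels),
            "branches_enabled": list(model.config.branches_enabled),
            "n_classes": model.config.n_classes,
        },
        "shapes": {
            "n_channels": model.shapes.n_channels,
            "n_time": model.shapes.n_time,
            "n_freq": model.shapes.n_freq,
            "n_wavelet": model.shapes.n_wavelet,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> MDFNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(
        ttcn_channels=tuple(sidecar["config"]["ttcn_channels"]),
        ttcn_kernel=sidecar["config"]["ttcn_kernel"],
        ttcn_dilation_base=sidecar["config"]["ttcn_dilation_base"],
        dropout=sidecar["config"]["dropout"],
        cmix_channels=tuple(sidecar["config"]["cmix_channels"]),
        branches_enabled=tuple(sidecar["config"]["branches_enabled"]),
        n_classes=sidecar["config"]["n_classes"],
    )
    shapes = FeatureShapes(**sidecar["shapes"])
    model = MDFNet(cfg, shapes)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
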