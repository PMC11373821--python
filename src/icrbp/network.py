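"""The classifier architecture: LKCNN -> CBAM-1D -> BiGRU -> dense softmax.

The model consumes the channel-concatenated five-scheme feature matrix of a
fragment, shape ``(length, channels)``.  Five parallel kernel-3 convolutions
first reparametrize each scheme's block to a common width; their outputs are
concatenated and pushed through a convolution stack whose middle layers use
large kernels (7 and 5) to widen the effective receptive field.  A hybrid
attention block then reweights channels (global max pooling and a
conv-then-average-pool branch through a shared bottleneck MLP) and positions
(channel-wise max/mean, one wide convolution, sigmoid).  A bidirectional GRU
reads the refined map position by position; its full output sequence is
flattened into a dense softmax head.

Ablation switches reproduce the variant models used to probe each block's
contribution: dropping the conv stack, the attention block or the BiGRU,
replacing the large kernels with kernel 3, reverting the channel branch to
plain global average pooling, and adding or removing two kernel-1 layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat
from ._layers import (
    Adam, BatchNorm1d, BiGRU, Conv1d, Dense, Dropout, Layer,
    avg_pool1d, global_avg_pool, global_max_pool, log_softmax, max_pool1d,
)
from .encoders import EncodingConfig

ABLATION_FLAGS = frozenset({
    "no_lkcnn", "no_cbam", "no_bigru",
    "cbam_standard", "lkcnn_plain_cnn", "plus2_layers", "minus2_layers",
})


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Complete architecture description.

    Widths default to the full-size architecture (128 filters per scheme;
    512/256/128-wide stack; hidden size 128; dropout 0.8).  ``small()``
    returns a width-reduced preset for CPU-scale experiments.
    """

    per_scheme_filters: int = 128
    per_scheme_kernel: int = 3
    width_a: int = 512          # first kernel-1 layer
    width_b: int = 256          # mid-stack layers, incl. the large kernels
    width_c: int = 128          # tail layers
    large_kernels: tuple[int, int] = (7, 5)
    cbam_reduction: int = 16
    cbam_channel_activation: str = "relu"   # or "sigmoid" (original CBAM)
    cbam_channel_conv_kernel: int = 3
    spatial_kernel: int = 7
    gru_hidden: int = 128
    dropout_rate: float = 0.8
    n_classes: int = 2
    ablation: frozenset = frozenset()

    def __post_init__(self):
        flags = frozenset(self.ablation)
        object.__setattr__(self, "ablation", flags)
        unknown = flags - ABLATION_FLAGS
        if unknown:
            raise ConfigurationError(f"unknown ablation flags {sorted(unknown)}")
        if {"plus2_layers", "minus2_layers"} <= flags:
            raise ConfigurationError("plus2_layers and minus2_layers are exclusive")
        if self.cbam_channel_activation not in ("relu", "sigmoid"):
            raise ConfigurationError("cbam_channel_activation must be relu|sigmoid")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.n_classes != 2:
            raise ConfigurationError("binary classification only")

    @classmethod
    def small(cls, ablation=frozenset()) -> "ModelConfig":
        """Width-reduced preset (same topology) for single-CPU training."""
        return cls(
            per_scheme_filters=16, width_a=64, width_b=32, width_c=16,
            gru_hidden=32, dropout_rate=0.25, ablation=frozenset(ablation),
        )

    def with_ablation(self, *flags: str) -> "ModelConfig":
        return replace(self, ablation=frozenset(self.ablation) | set(flags))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


class _ConvStage(Layer):
    def __init__(self, conv: Conv1d, pool: str | None = None,
                 bn: BatchNorm1d | None = None, name: str = ""):
        super().__init__()
        self.conv = conv
        self.pool = pool
        self.bn = bn
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        y = y.relu()
        if self.pool == "avg":
            y = avg_pool1d(y, 2)
        elif self.pool == "max":
            y = max_pool1d(y, 2)
        return y


def build_lkcnn(cfg: ModelConfig, in_channels: int,
                rng: np.random.Generator) -> list[_ConvStage]:
    """Assemble the post-concatenation convolution stack as ordered stages.

    The default stack: kernel-1 (width_a) -> average pool 2 -> kernel-1
    (width_b) + batch norm -> kernel-7 (width_b) -> kernel-5 (width_b) + max
    pool -> kernel-3 (width_c) + max pool -> kernel-1 (width_c).  Ablations:
    ``minus2_layers`` drops the first and last kernel-1 layers;
    ``plus2_layers`` inserts two extra kernel-1 layers after the batch-norm
    stage; ``lkcnn_plain_cnn`` replaces the large kernels with kernel 3;
    ``no_lkcnn`` returns an empty stack (callers bypass it).
    """
    flags = cfg.ablation
    if "no_lkcnn" in flags:
        return []
    k_big, k_mid = cfg.large_kernels
    if "lkcnn_plain_cnn" in flags:
        k_big = k_mid = 3
    minus2 = "minus2_layers" in flags

    stages: list[_ConvStage] = []
    c = in_channels

    def add(n_out, kernel, pool=None, with_bn=False, name=""):
        nonlocal c
        bn = BatchNorm1d(n_out) if with_bn else None
        stages.append(_ConvStage(Conv1d(c, n_out, kernel, rng), pool, bn, name))
        c = n_out

    if not minus2:
        add(cfg.width_a, 1, name="conv1_a")
    stages.append(_PoolStage("avg"))
    add(cfg.width_b, 1, with_bn=True, name="conv1_b_bn")
    if "plus2_layers" in flags:
        add(cfg.width_b, 1, name="conv1_extra1")
        add(cfg.width_b, 1, name="conv1_extra2")
    add(cfg.width_b, k_big, name="conv_large")
    add(cfg.width_b, k_mid, pool="max", name="conv_mid_pool")
    add(cfg.width_c, 3, pool="max", name="conv3_pool")
    if not minus2:
        add(cfg.width_c, 1, name="conv1_tail")
    return stages


class _PoolStage(Layer):
    def __init__(self, kind: str):
        super().__init__()
        self.kind = kind
        self.name = f"{kind}_pool"

    def __call__(self, x: Tensor) -> Tensor:
        return avg_pool1d(x, 2) if self.kind == "avg" else max_pool1d(x, 2)


class ChannelAttention(Layer):
    """Channel reweighting from two pooled descriptors through a shared MLP.

    One descriptor is the global max over positions; the other is a global
    average taken after a channel-preserving 1D convolution over positions
    (plain global average pooling under the ``cbam_standard`` ablation).
    The summed MLP outputs pass through the configured activation and scale
    each channel.
    """

    def __init__(self, n_ch: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        hidden = max(n_ch // cfg.cbam_reduction, 1)
        self.mlp1 = Dense(n_ch, hidden, rng)
        self.mlp2 = Dense(hidden, n_ch, rng)
        self.activation = cfg.cbam_channel_activation
        if self.activation == "relu":
            # start with the gate open: a zero-initialized bias lets an early
            # all-negative MLP output zero every channel and stall training
            self.mlp2.b.data[:] = 0.5
        self.standard = "cbam_standard" in cfg.ablation
        self.conv = None if self.standard else Conv1d(
            n_ch, n_ch, cfg.cbam_channel_conv_kernel, rng
        )

    def __call__(self, x: Tensor) -> Tensor:
        d_max = global_max_pool(x)
        avg_src = x if self.conv is None else self.conv(x)
        d_avg = global_avg_pool(avg_src)
        s = self.mlp2(self.mlp1(d_max).relu()) + self.mlp2(self.mlp1(d_avg).relu())
        w = s.relu() if self.activation == "relu" else s.sigmoid()
        B, C = w.shape
        return x * w.reshape(B, 1, C)


class SpatialAttention(Layer):
    """Position reweighting: channel-wise max/mean -> wide conv -> sigmoid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv1d(2, 1, cfg.spatial_kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        d = concat([x.max(axis=2, keepdims=True), x.mean(axis=2, keepdims=True)],
                   axis=2)
        w = self.conv(d).sigmoid()          # (B, L, 1)
        return x * w


class BiGRUHead(Layer):
    """BiGRU over positions, flatten, dropout, dense softmax (2 classes)."""

    def __init__(self, in_len: int, in_ch: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.no_bigru = "no_bigru" in cfg.ablation
        if self.no_bigru:
            flat = in_len * in_ch
            self.gru = None
        else:
            self.gru = BiGRU(in_ch, cfg.gru_hidden, rng)
            flat = in_len * 2 * cfg.gru_hidden
        self.flat_dim = flat
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.dense = Dense(flat, cfg.n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        if self.gru is not None:
            x = self.gru(x)
        B = x.shape[0]
        v = self.dropout(x.reshape(B, self.flat_dim))
        return self.dense(v)

    def __call__(self, x: Tensor) -> Tensor:
        return log_softmax(self.logits(x)).exp()


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


def lkcnn_min_length(cfg: ModelConfig) -> int:
    """Smallest input length surviving the stack's three pooling halvings."""
    return 1 if "no_lkcnn" in cfg.ablation else 8


class Model(Layer):
    """Forward contract: (batch, length, total_channels) -> class probabilities."""

    def __init__(self, cfg: ModelConfig, encoding: EncodingConfig,
                 input_length: int, seed: int = 0):
        super().__init__()
        if input_length < lkcnn_min_length(cfg):
            raise ConfigurationError(
                f"input length {input_length} too short; the pooling stages "
                f"require at least {lkcnn_min_length(cfg)} positions"
            )
        self.cfg = cfg
        self.encoding = encoding
        self.input_length = input_length
        self.seed = seed
        rng = np.random.default_rng(seed)

        channels = encoding.scheme_channels()
        self.scheme_slices = []
        off = 0
        for name in ("KNF", "DOC2VEC", "EIIP", "CCN", "ANF"):
            n = channels[name]
            self.scheme_slices.append((name, off, off + n))
            off += n
        self.total_channels = off

        self.scheme_convs = [
            Conv1d(b - a, cfg.per_scheme_filters, cfg.per_scheme_kernel, rng)
            for _, a, b in self.scheme_slices
        ]
        concat_ch = 5 * cfg.per_scheme_filters
        self.lkcnn = build_lkcnn(cfg, concat_ch, rng)

        # trace shapes through the stack to size the head
        L, C = input_length, concat_ch
        for st in self.lkcnn:
            if isinstance(st, _PoolStage):
                L //= 2
            else:
                C = st.conv.n_out
                if st.pool is not None:
                    L //= 2
        self.out_length, self.out_channels = L, C

        self.use_cbam = "no_cbam" not in cfg.ablation
        if self.use_cbam:
            self.channel_attn = ChannelAttention(C, cfg, rng)
            self.spatial_attn = SpatialAttention(cfg, rng)
        self.head = BiGRUHead(L, C, cfg, rng)

    # -- forward -----------------------------------------------------------
    def _features(self, x: Tensor) -> Tensor:
        outs = []
        for conv, (_, a, b) in zip(self.scheme_convs, self.scheme_slices):
            outs.append(conv(x[:, :, a:b]).relu())
        y = concat(outs, axis=2)
        for st in self.lkcnn:
            y = st(y)
        if self.use_cbam:
            y = self.channel_attn(y)
            y = self.spatial_attn(y)
        return y

    def _check_input(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.input_length or x.shape[2] != self.total_channels:
            raise ConfigurationError(
                f"expected input (batch, {self.input_length}, "
                f"{self.total_channels}), got {x.shape}"
            )
        return Tensor(x)

    def logits(self, x: np.ndarray) -> Tensor:
        return self.head.logits(self._features(self._check_input(x)))

    def forward(self, x: np.ndarray) -> Tensor:
        """Class probabilities, shape (batch, 2), rows summing to 1."""
        return log_softmax(self.logits(x)).exp()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode positive-class probabilities as a plain array."""
        mode = self.training
        self.set_training(False)
        try:
            return self.forward(x).data[:, 1].copy()
        finally:
            self.set_training(mode)

    # -- reporting / persistence --------------------------------------------
    def summary(self) -> str:
        lines = [
            f"input: ({self.input_length} x {self.total_channels}) "
            f"[5 schemes -> {self.cfg.per_scheme_filters} filters each]",
        ]
        for st in self.lkcnn:
            if isinstance(st, _PoolStage):
                lines.append(f"  {st.name}")
            else:
                extras = []
                if st.bn is not None:
                    extras.append("bn")
                if st.pool:
                    extras.append(f"{st.pool}_pool")
                suffix = f" + {'+'.join(extras)}" if extras else ""
                lines.append(
                    f"  {st.name}: conv k={st.conv.kernel} -> {st.conv.n_out}{suffix}"
                )
        lines.append(
            f"attention: {'channel+spatial' if self.use_cbam else 'bypassed'}"
        )
        head = "flatten" if self.head.no_bigru else f"bigru({self.cfg.gru_hidden})"
        lines.append(f"head: {head} -> dense({self.cfg.n_classes})")
        lines.append(f"parameters: {self.n_parameters()}")
        return "\n".join(lines)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        bn_state = {}
        for i, st in enumerate(self.lkcnn):
            if isinstance(st, _ConvStage) and st.bn is not None:
                bn_state[f"bn{i}_mean"] = st.bn.running_mean
                bn_state[f"bn{i}_var"] = st.bn.running_var
        meta = {
            "model_config": {**asdict(self.cfg), "ablation": sorted(self.cfg.ablation)},
            "encoding_config": asdict(self.encoding),
            "input_length": self.input_length,
            "seed": self.seed,
        }
        np.savez_compressed(path, meta=json.dumps(meta), **arrays, **bn_state)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            mc = meta["model_config"]
            mc["ablation"] = frozenset(mc["ablation"])
            mc["large_kernels"] = tuple(mc["large_kernels"])
            ec = meta["encoding_config"]
            ec["k_values"] = tuple(ec["k_values"])
            model = cls(ModelConfig(**mc), EncodingConfig(**ec),
                        meta["input_length"], meta["seed"])
            for i, p in enumerate(model.parameters()):
                p.data = z[f"p{i}"].copy()
            for i, st in enumerate(model.lkcnn):
                if isinstance(st, _ConvStage) and st.bn is not None:
                    st.bn.running_mean = z[f"bn{i}_mean"].copy()
                    st.bn.running_var = z[f"bn{i}_var"].copy()
        return model


def assemble_model(cfg: ModelConfig, encoding: EncodingConfig,
                   input_length: int = 101, seed: int = 0) -> Model:
    """Build the full classifier (honoring ablation flags) with seeded weights."""
    return Model(cfg, encoding, input_length, seed)
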