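"""The CNN / self-attention / BiLSTM emotion classifier (CSBN) and its
ablation variants.

The full network takes a differential-entropy feature vector (length
C·B, 512 for 128 channels x 4 bands), runs it through a seven-convolution
1-D CNN with three multiplicative residual wrappings and max/avg pooling,
reads the final (64, 2) feature map as a length-2 sequence of 64-dim
features, applies single-head scaled dot-product self-attention, feeds the
attended sequence to a 3-layer BiLSTM (128/64/64 hidden units), and
classifies the final BiLSTM state with a softmax head.

Ablation variants: ``CNN`` (conv stack -> flatten -> softmax), ``BiLSTM``
(input reshaped to a sequence -> BiLSTM -> softmax), ``CNN-BiLSTM`` (the
full model without attention), ``CSBN`` (everything).

Kernel sizes of the reference stack are chosen so the symbolic shape
trace reproduces the reference stage-output table exactly; see
:func:`default_model_spec` and ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for callers)
    AvgPool1d,
    BatchNorm1d,
    BiLSTM,
    Conv1d,
    Linear,
    MaxPool1d,
    Module,
    SelfAttention,
    SpatialDropout1d,
    Tensor,
)

__all__ = [
    "ArchitectureError", "ConvStage", "PoolStage", "NormStage", "DropStage",
    "ModelSpec", "default_model_spec", "model_spec_for_input", "shape_trace",
    "AttentionParams", "LSTMCellParams", "self_attention", "lstm_step",
    "bilstm_forward", "multiplicative_residual", "softmax_head",
    "CSBNModel", "build_model", "VARIANTS",
]

VARIANTS = ("CSBN", "CNN", "BiLSTM", "CNN-BiLSTM")


class ArchitectureError(ValueError):
    """A stage of the network cannot be realized for the given input."""


@dataclass(frozen=True)
class ConvStage:
    name: str
    filters: int
    kernel: int
    stride: int
    padding: int = 0
    activation: str = "relu"


@dataclass(frozen=True)
class PoolStage:
    name: str
    kind: str  # "max" | "avg"
    size: int
    stride: int


@dataclass(frozen=True)
class NormStage:
    name: str


@dataclass(frozen=True)
class DropStage:
    name: str


@dataclass
class ModelSpec:
    """Declarative description of one network build."""

    input_len: int
    stages: list
    residual_pairs: list[tuple[str, str]]
    d_k: int
    d_v: int
    bilstm_sizes: list[int]
    n_classes: int = 2
    dropout_rate: float = 0.3
    variant: str = "CSBN"
    bilstm_input_steps: int = 8  # sequence layout of the BiLSTM-only variant

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = [
            {**asdict(s), "stage_kind": type(s).__name__} for s in self.stages
        ]
        return d


def default_model_spec(variant: str = "CSBN", n_classes: int = 2) -> ModelSpec:
    """The reference stack for a 512-length DE vector (128 ch x 4 bands)."""
    stages = [
        ConvStage("Convolution-1", 32, kernel=2, stride=2),
        ConvStage("Convolution-2", 32, kernel=6, stride=2),
        PoolStage("Pool_1", "max", 2, 2),
        NormStage("BN_1"),
        DropStage("Drop_1"),
        ConvStage("Convolution-3", 64, kernel=5, stride=2),
        ConvStage("Convolution-4", 64, kernel=6, stride=2),
        PoolStage("Pool_2", "avg", 2, 2),
        NormStage("BN_2"),
        DropStage("Drop_2"),
        ConvStage("Convolution-5", 128, kernel=3, stride=1),
        ConvStage("Convolution-6", 128, kernel=2, stride=1),
        PoolStage("Pool_3", "avg", 2, 1),
        NormStage("BN_3"),
        DropStage("Drop_3"),
        ConvStage("Convolution-7", 64, kernel=3, stride=1, padding=1),
        NormStage("BN_4"),
    ]
    return ModelSpec(
        input_len=512,
        stages=stages,
        residual_pairs=[
            ("Convolution-1", "Convolution-2"),
            ("Convolution-3", "Convolution-4"),
            ("Convolution-5", "Convolution-6"),
        ],
        d_k=64,
        d_v=64,
        bilstm_sizes=[128, 64, 64],
        n_classes=n_classes,
        variant=variant,
    )


def model_spec_for_input(input_len: int, variant: str = "CSBN",
                         n_classes: int = 2) -> ModelSpec:
    """A spec adapted to ``input_len``: the reference stack at 512,
    otherwise a scaled-down stack with the same motifs.

    The scaled stack halves the length with stride-2 kernel-2 convolutions
    (consecutive pairs wrapped in a multiplicative residual, followed by
    batch norm and spatial dropout), then one stride-1 convolution brings
    the length to 2; attention width and BiLSTM sizes scale with the final
    filter count.
    """
    if input_len == 512:
        return default_model_spec(variant, n_classes)
    if input_len < 8:
        raise ArchitectureError(f"input length {input_len} too short (< 8)")

    filters_cycle = [16, 16, 32, 32, 64, 64]
    stages: list = []
    residual_pairs: list[tuple[str, str]] = []
    cur = input_len
    ci = 0
    while cur > 4:
        f = filters_cycle[min(ci, len(filters_cycle) - 1)]
        ci += 1
        stages.append(ConvStage(f"Convolution-{ci}", f, kernel=2, stride=2))
        cur = (cur - 2) // 2 + 1
        if ci % 2 == 0:
            residual_pairs.append((f"Convolution-{ci - 1}", f"Convolution-{ci}"))
            bi = ci // 2
            stages.append(NormStage(f"BN_{bi}"))
            stages.append(DropStage(f"Drop_{bi}"))
    final_filters = 32 if input_len <= 64 else 64
    ci += 1
    stages.append(ConvStage(f"Convolution-{ci}", final_filters,
                            kernel=cur - 1, stride=1))
    stages.append(NormStage(f"BN_{ci}"))
    d = final_filters
    return ModelSpec(
        input_len=input_len,
        stages=stages,
        residual_pairs=residual_pairs,
        d_k=d,
        d_v=d,
        bilstm_sizes=[2 * d, d, d],
        n_classes=n_classes,
        variant=variant,
        bilstm_input_steps=_bilstm_steps(input_len),
    )


def _bilstm_steps(input_len: int) -> int:
    for steps in (8, 4, 2):
        if input_len % steps == 0 and input_len // steps >= 2:
            return steps
    return 1


def _conv_out_len(L: int, kernel: int, stride: int, padding: int) -> int:
    return (L + 2 * padding - kernel) // stride + 1


def shape_trace(spec: ModelSpec) -> list[tuple[str, tuple[int, int]]]:
    """Symbolic forward-shape computation, no weights involved.

    Returns ``[(stage_name, (channels, length)), ...]`` for every stage;
    raises :class:`ArchitectureError` naming the first stage whose output
    length would fall below 1.
    """
    channels, length = 1, spec.input_len
    trace = []
    for stage in spec.stages:
        if isinstance(stage, ConvStage):
            length = _conv_out_len(length, stage.kernel, stage.stride, stage.padding)
            channels = stage.filters
        elif isinstance(stage, PoolStage):
            length = _conv_out_len(length, stage.size, stage.stride, 0)
        # norm/dropout preserve shape
        if length < 1:
            raise ArchitectureError(
                f"stage {stage.name!r} produces length {length} < 1 "
                f"for input_len={spec.input_len}"
            )
        trace.append((stage.name, (channels, length)))
    return trace


# ---------------------------------------------------------------------------
# functional forms (NumPy in / NumPy out), used directly and as test surface
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Learnable projections of scaled dot-product self-attention."""

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray

    @property
    def d_k(self) -> int:
        return self.w_q.shape[1]

    @property
    def d_v(self) -> int:
        return self.w_v.shape[1]

    def __post_init__(self):
        if self.w_q.shape != self.w_k.shape:
            raise ValueError("W_q and W_k must project to the same d_k")


def _stable_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def self_attention(X: np.ndarray, params: AttentionParams):
    """Attention(Q,K,V) = softmax(Q K^T / sqrt(d_k)) V for one sequence.

    ``X`` is (n, d_model); returns (output (n, d_v), weights (n, n)).
    """
    X = np.asarray(X, dtype=np.float64)
    q = X @ params.w_q
    k = X @ params.w_k
    v = X @ params.w_v
    weights = _stable_softmax(q @ k.T / np.sqrt(params.d_k), axis=-1)
    return weights @ v, weights


@dataclass
class LSTMCellParams:
    """Gate weights/biases; each W acts on the concatenation [h_prev, x]."""

    w_f: np.ndarray
    w_i: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.w_f.shape[1]

    @classmethod
    def random(cls, input_size: int, hidden_size: int,
               rng: np.random.Generator, scale: float = 0.2):
        cat = input_size + hidden_size
        def w():
            return scale * rng.standard_normal((cat, hidden_size))
        def b():
            return scale * rng.standard_normal(hidden_size)
        return cls(w(), w(), w(), w(), b(), b(), b(), b())


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              params: LSTMCellParams):
    """One LSTM update: forget/input/output gates on [h_prev, x_t], cell
    state c_t = f⊙c_prev + i⊙tanh(·), output h_t = o⊙tanh(c_t)."""
    z = np.concatenate([h_prev, x_t], axis=-1)
    f = _logistic(z @ params.w_f + params.b_f)
    i = _logistic(z @ params.w_i + params.b_i)
    o = _logistic(z @ params.w_o + params.b_o)
    c_t = f * c_prev + i * np.tanh(z @ params.w_c + params.b_c)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def bilstm_forward(X: np.ndarray, layer_sizes: list[int] | None = None, *,
                   module: BiLSTM | None = None, seed: int = 0) -> np.ndarray:
    """Run a stacked BiLSTM over ``X`` (T, D) or (N, T, D) and return the
    final concatenated forward/backward states (…, 2*H_last).

    Supply ``module`` to reuse weights across calls; otherwise a fresh
    seeded BiLSTM is built from ``layer_sizes``.
    """
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1] < 1:
        raise ValueError("empty sequence")
    if module is None:
        if layer_sizes is None:
            raise ValueError("layer_sizes required when no module is given")
        rng = np.random.default_rng(seed)
        module = BiLSTM(X.shape[2], list(layer_sizes), rng=rng)
    out = module(Tensor(X)).data
    return out[0] if single else out


def multiplicative_residual(x, f_block, h_adjust):
    """x_{l+1} = h(x_l) ⊙ F(x_l): elementwise product of the shape-adjusted
    skip path and the main (two-convolution) path.

    ``f_block`` and ``h_adjust`` are callables; works on NumPy arrays,
    scalars, or autograd Tensors.
    """
    f_out = f_block(x)
    h_out = h_adjust(x)
    f_shape = getattr(f_out, "shape", ())
    h_shape = getattr(h_out, "shape", ())
    if f_shape != h_shape:
        raise ArchitectureError(
            f"skip path shape {h_shape} does not match main path {f_shape}"
        )
    return h_out * f_out


def softmax_head(H: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Y = softmax(W·H + b); numerically stable, rows sum to 1."""
    H = np.asarray(H, dtype=np.float64)
    logits = H @ np.asarray(W, dtype=np.float64).T + b
    return _stable_softmax(logits, axis=-1)


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

class _ResidualPairBlock(Module):
    """conv_a -> relu -> conv_b -> relu, multiplied by a 1x1-conv skip.

    The skip convolution's stride is the largest one whose output is at
    least as long as the main path; the skip output is then left-cropped
    to the main path's length (exact for most geometries).
    """

    def __init__(self, conv_a: Conv1d, conv_b: Conv1d, in_channels: int,
                 out_channels: int, in_len: int, out_len: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv_a = conv_a
        self.conv_b = conv_b
        if out_len > 1:
            stride = max(1, (in_len - 1) // (out_len - 1))
        else:
            stride = in_len
        self.h_conv = Conv1d(in_channels, out_channels, kernel=1,
                             stride=stride, rng=rng)
        self.out_len = out_len

    def forward(self, x: Tensor) -> Tensor:
        f_out = self.conv_b(self.conv_a(x).relu()).relu()
        h_out = self.h_conv(x)
        h_out = h_out[:, :, : self.out_len]
        if h_out.shape != f_out.shape:
            raise ArchitectureError(
                f"skip path shape {h_out.shape} != main path {f_out.shape}"
            )
        return h_out * f_out


class CSBNModel(Module):
    """A built network for one :class:`ModelSpec` variant.

    ``forward`` maps a feature batch (N, input_len) to class logits;
    ``predict_proba`` applies the softmax head in inference mode.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence(seed + 1))

        trace = shape_trace(spec)
        shapes = dict(trace)
        self.blocks: list[Module] = []
        use_cnn = spec.variant in ("CSBN", "CNN", "CNN-BiLSTM")
        if use_cnn:
            self._build_cnn(spec, shapes, rng)
            final_channels, final_len = trace[-1][1]
        self.use_attention = spec.variant == "CSBN"
        self.use_bilstm = spec.variant in ("CSBN", "CNN-BiLSTM", "BiLSTM")

        if spec.variant == "CNN":
            self.head = Linear(final_channels * final_len, spec.n_classes, rng=rng)
        elif spec.variant == "BiLSTM":
            steps = spec.bilstm_input_steps
            if spec.input_len % steps:
                raise ArchitectureError(
                    f"input_len {spec.input_len} not divisible into {steps} steps"
                )
            self.seq_feat = spec.input_len // steps
            self.bilstm = BiLSTM(self.seq_feat, spec.bilstm_sizes, rng=rng)
            self.head = Linear(self.bilstm.output_size, spec.n_classes, rng=rng)
        else:  # CSBN or CNN-BiLSTM: CNN output read as a sequence
            d_model = final_channels
            if self.use_attention:
                self.attention = SelfAttention(d_model, spec.d_k, spec.d_v, rng=rng)
                lstm_in = spec.d_v
            else:
                lstm_in = d_model
            self.bilstm = BiLSTM(lstm_in, spec.bilstm_sizes, rng=rng)
            self.head = Linear(self.bilstm.output_size, spec.n_classes, rng=rng)

    def _build_cnn(self, spec: ModelSpec, shapes: dict, rng) -> None:
        pair_of = dict(spec.residual_pairs)
        second = {b for _, b in spec.residual_pairs}
        channels, length = 1, spec.input_len
        stages = {s.name: s for s in spec.stages}
        skip_next = None
        for stage in spec.stages:
            if stage.name == skip_next:
                skip_next = None
                continue
            if isinstance(stage, ConvStage):
                if stage.name in pair_of:
                    b_name = pair_of[stage.name]
                    b_stage = stages[b_name]
                    conv_a = Conv1d(channels, stage.filters, stage.kernel,
                                    stage.stride, stage.padding, rng=rng)
                    conv_b = Conv1d(stage.filters, b_stage.filters, b_stage.kernel,
                                    b_stage.stride, b_stage.padding, rng=rng)
                    out_ch, out_len = shapes[b_name]
                    self.blocks.append(
                        _ResidualPairBlock(conv_a, conv_b, channels, out_ch,
                                           length, out_len, rng=rng)
                    )
                    channels, length = out_ch, out_len
                    skip_next = b_name
                else:
                    conv = Conv1d(channels, stage.filters, stage.kernel,
                                  stage.stride, stage.padding, rng=rng)
                    self.blocks.append(_ConvRelu(conv))
                    channels, length = shapes[stage.name]
            elif isinstance(stage, PoolStage):
                cls = MaxPool1d if stage.kind == "max" else AvgPool1d
                self.blocks.append(cls(stage.size, stage.stride))
                channels, length = channels, shapes[stage.name][1]
            elif isinstance(stage, NormStage):
                self.blocks.append(BatchNorm1d(channels))
            elif isinstance(stage, DropStage):
                self.blocks.append(
                    SpatialDropout1d(spec.dropout_rate, rng=self.dropout_rng)
                )

    def _cnn_forward(self, x: Tensor) -> Tensor:
        h = x.reshape(x.shape[0], 1, x.shape[1])
        for block in self.blocks:
            h = block(h)
        return h

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        spec = self.spec
        if spec.variant == "CNN":
            h = self._cnn_forward(x)
            flat = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
            return self.head(flat)
        if spec.variant == "BiLSTM":
            seq = x.reshape(x.shape[0], spec.bilstm_input_steps, self.seq_feat)
            return self.head(self.bilstm(seq))
        h = self._cnn_forward(x)                      # (N, F, L)
        seq = h.transpose(0, 2, 1)                    # (N, L, F): positions as steps
        if self.use_attention:
            seq = self.attention(seq)
        return self.head(self.bilstm(seq))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(np.asarray(X, dtype=np.float64)).data
        finally:
            self.train(was_training)
        return _stable_softmax(logits, axis=-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


class _ConvRelu(Module):
    def __init__(self, conv: Conv1d):
        super().__init__()
        self.conv = conv

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


def build_model(spec: ModelSpec, seed: int = 0) -> CSBNModel:
    """Assemble a trainable network for the spec's variant; deterministic
    for a fixed (spec, seed)."""
    shape_trace(spec)  # validate before building
    return CSBNModel(spec, seed=seed)
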