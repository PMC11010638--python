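"""Layers of the EEG emotion classifier, built on the autograd core.

Weight initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator``, so two builds from the same seed share
identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    avg_pool1d,
    batch_norm,
    concat,
    conv1d,
    max_pool1d,
    softmax,
)

__all__ = [
    "Module", "Conv1d", "Linear", "BatchNorm1d", "SpatialDropout1d",
    "MaxPool1d", "AvgPool1d", "ReLU", "SelfAttention", "LSTMCell",
    "BiLSTM", "Sequential",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: parameter traversal + train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, *, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel
        self.weight = Tensor(
            glorot_uniform(rng, (out_channels, in_channels, kernel),
                           fan_in, out_channels * kernel),
            requires_grad=True, name="conv.weight",
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True,
                           name="conv.bias")

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            glorot_uniform(rng, (in_features, out_features),
                           in_features, out_features),
            requires_grad=True, name="linear.weight",
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True,
                           name="linear.bias")

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True, name="bn.gamma")
        self.beta = Tensor(np.zeros(channels), requires_grad=True, name="bn.beta")
        self.running = {"mean": np.zeros(channels), "var": np.ones(channels)}

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.eps, self.running,
                          self.momentum, self.training)


class SpatialDropout1d(Module):
    """Channel-wise dropout on (N, C, L); a fresh mask per call from the
    module's own generator (seeded at construction)."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        n, c, _ = x.data.shape
        keep = (self.rng.random((n, c, 1)) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class MaxPool1d(Module):
    def __init__(self, size: int, stride: int | None = None):
        super().__init__()
        self.size = size
        self.stride = size if stride is None else stride

    def forward(self, x: Tensor) -> Tensor:
        return max_pool1d(x, self.size, self.stride)


class AvgPool1d(Module):
    def __init__(self, size: int, stride: int | None = None):
        super().__init__()
        self.size = size
        self.stride = size if stride is None else stride

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool1d(x, self.size, self.stride)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention.

    Projects the input sequence X (N, T, d_model) to queries/keys/values,
    weights = row-softmax(Q K^T / sqrt(d_k)), output = weights @ V.
    """

    def __init__(self, d_model: int, d_k: int | None = None,
                 d_v: int | None = None, *, rng: np.random.Generator):
        super().__init__()
        self.d_k = d_k or d_model
        self.d_v = d_v or d_model
        self.w_q = Tensor(glorot_uniform(rng, (d_model, self.d_k), d_model, self.d_k),
                          requires_grad=True, name="attn.w_q")
        self.w_k = Tensor(glorot_uniform(rng, (d_model, self.d_k), d_model, self.d_k),
                          requires_grad=True, name="attn.w_k")
        self.w_v = Tensor(glorot_uniform(rng, (d_model, self.d_v), d_model, self.d_v),
                          requires_grad=True, name="attn.w_v")

    def forward(self, x: Tensor, return_weights: bool = False):
        q = x @ self.w_q
        k = x @ self.w_k
        v = x @ self.w_v
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_k))
        weights = softmax(scores, axis=-1)
        out = weights @ v
        if return_weights:
            return out, weights
        return out


class LSTMCell(Module):
    """One LSTM cell with the conventional forget/input/output gating.

    Gates act on the concatenation [h_prev, x_t]; cell state
    c_t = f⊙c_prev + i⊙tanh(W_c·[h,x]+b_c), output h_t = o⊙tanh(c_t).
    """

    def __init__(self, input_size: int, hidden_size: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        cat = input_size + hidden_size
        def w(name):
            return Tensor(glorot_uniform(rng, (cat, hidden_size), cat, hidden_size),
                          requires_grad=True, name=name)
        self.w_f, self.w_i, self.w_o, self.w_c = (
            w("lstm.w_f"), w("lstm.w_i"), w("lstm.w_o"), w("lstm.w_c"))
        self.b_f = Tensor(np.zeros(hidden_size), requires_grad=True, name="lstm.b_f")
        self.b_i = Tensor(np.zeros(hidden_size), requires_grad=True, name="lstm.b_i")
        self.b_o = Tensor(np.zeros(hidden_size), requires_grad=True, name="lstm.b_o")
        self.b_c = Tensor(np.zeros(hidden_size), requires_grad=True, name="lstm.b_c")

    def forward(self, x_t: Tensor, h_prev: Tensor, c_prev: Tensor):
        z = concat([h_prev, x_t], axis=1)
        f = (z @ self.w_f + self.b_f).sigmoid()
        i = (z @ self.w_i + self.b_i).sigmoid()
        o = (z @ self.w_o + self.b_o).sigmoid()
        c_tilde = (z @ self.w_c + self.b_c).tanh()
        c_t = f * c_prev + i * c_tilde
        h_t = o * c_t.tanh()
        return h_t, c_t


class BiLSTM(Module):
    """Stacked bidirectional LSTM.

    Each layer runs a forward and a backward pass over the sequence and
    concatenates their hidden states per step (doubling the feature dim);
    ``final_states`` of the last layer is the concatenation of the forward
    pass's last state and the backward pass's state at t=0.
    """

    def __init__(self, input_size: int, layer_sizes: list[int], *,
                 rng: np.random.Generator):
        super().__init__()
        self.layer_sizes = list(layer_sizes)
        self.cells_fwd: list[LSTMCell] = []
        self.cells_bwd: list[LSTMCell] = []
        size = input_size
        for h in layer_sizes:
            self.cells_fwd.append(LSTMCell(size, h, rng=rng))
            self.cells_bwd.append(LSTMCell(size, h, rng=rng))
            size = 2 * h
        self.output_size = size

    def _run_direction(self, cell: LSTMCell, steps: list[Tensor]) -> list[Tensor]:
        n = steps[0].data.shape[0]
        h = Tensor(np.zeros((n, cell.hidden_size)))
        c = Tensor(np.zeros((n, cell.hidden_size)))
        outs = []
        for x_t in steps:
            h, c = cell(x_t, h, c)
            outs.append(h)
        return outs

    def forward(self, x: Tensor, return_sequence: bool = False):
        """x: (N, T, D).  Returns the final feature vector (N, 2*H_last),
        or the full sequence (N, T, 2*H_last) if requested."""
        t_len = x.data.shape[1]
        if t_len < 1:
            raise ValueError("empty sequence")
        steps = [x[:, t, :] for t in range(t_len)]
        for cf, cb in zip(self.cells_fwd, self.cells_bwd):
            fwd = self._run_direction(cf, steps)
            bwd = list(reversed(self._run_direction(cb, list(reversed(steps)))))
            steps = [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
            last_fwd, first_bwd = fwd[-1], bwd[0]
        final = concat([last_fwd, first_bwd], axis=1)
        if return_sequence:
            # stack steps back into (N, T, D)
            return concat([s.reshape(s.shape[0], 1, s.shape[1]) for s in steps],
                          axis=1)
        return final
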