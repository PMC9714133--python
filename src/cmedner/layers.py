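"""Parallel feature extractors and their fusion.

The downstream feature pipeline mirrors the hybrid architecture for
character-level clinical NER:

* a bidirectional LSTM over the embedded sentence (forward and backward
  passes concatenated per position, width ``2 * hidden_dim``);
* a bank of 1-D convolutions with different odd kernel widths, ReLU, and a
  per-position channelwise max across kernel widths (position-preserving so
  the CNN path can be fused with the BiLSTM path);
* a project-then-add fusion of both paths to a common width ``z``;
* one multihead scaled-dot-product self-attention stage whose scores are
  scaled by the square root of the model width and masked additively.

All functions take and return :class:`~cmedner.autodiff.Tensor` values (or a
:class:`FeatureMatrix` wrapper carrying a stage tag); gradients flow through
every stage.

In the LSTM gate equations, ``sigmoid`` denotes the logistic function and
``*`` the elementwise (Hadamard) product:

    f_t = sigmoid(h_{t-1} w_f + x_t u_f + b_f)
    i_t = sigmoid(h_{t-1} w_i + x_t u_i + b_i)
    c~_t = tanh(h_{t-1} w_c + x_t u_c + b_c)
    c_t = f_t * c_{t-1} + i_t * c~_t
    o_t = sigmoid(h_{t-1} w_o + x_t u_o + b_o)
    h_t = o_t * tanh(c_t)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import (
    Tensor,
    as_tensor,
    concat,
    matmul,
    maximum,
    mul,
    pad,
    relu,
    reshape,
    sigmoid,
    softmax,
    swapaxes,
    tanh,
)

__all__ = [
    "FeatureMatrix",
    "LSTMParams",
    "CNNParams",
    "ConvKernel",
    "FusionParams",
    "MHAParams",
    "lstm_step",
    "bilstm_encode",
    "cnn_encode",
    "fuse",
    "multihead_attention",
    "dropout",
]

ATTENTION_MASK_VALUE = -1e9


@dataclass
class FeatureMatrix:
    """Per-position feature vectors with a pipeline stage tag."""

    values: Tensor
    stage: str  # "bilstm" | "cnn" | "fused" | "attended"

    @property
    def shape(self):
        return self.values.shape


def _vals(x) -> Tensor:
    return x.values if isinstance(x, FeatureMatrix) else as_tensor(x)


def _mask_array(mask, n_positions: int) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float64)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[-1] != n_positions:
        raise ValueError(f"mask covers {m.shape[-1]} positions, expected {n_positions}")
    return m


# ---------------------------------------------------------------------------
# BiLSTM path
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Gate parameters of one LSTM direction.

    ``w_*`` map the previous hidden state, ``u_*`` the current input, and
    ``b_*`` are biases, for the forget / input / candidate / output gates.
    """

    w_f: Tensor
    w_i: Tensor
    w_c: Tensor
    w_o: Tensor
    u_f: Tensor
    u_i: Tensor
    u_c: Tensor
    u_o: Tensor
    b_f: Tensor
    b_i: Tensor
    b_c: Tensor
    b_o: Tensor
    hidden_dim: int

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator) -> "LSTMParams":
        k = 1.0 / math.sqrt(hidden_dim)

        def w():
            return Tensor(rng.uniform(-k, k, (hidden_dim, hidden_dim)), requires_grad=True)

        def u():
            return Tensor(rng.uniform(-k, k, (input_dim, hidden_dim)), requires_grad=True)

        def b():
            return Tensor(np.zeros(hidden_dim), requires_grad=True)

        return cls(w(), w(), w(), w(), u(), u(), u(), u(), b(), b(), b(), b(), hidden_dim)

    @classmethod
    def zeros(cls, input_dim: int, hidden_dim: int) -> "LSTMParams":
        def w():
            return Tensor(np.zeros((hidden_dim, hidden_dim)))

        def u():
            return Tensor(np.zeros((input_dim, hidden_dim)))

        def b():
            return Tensor(np.zeros(hidden_dim))

        return cls(w(), w(), w(), w(), u(), u(), u(), u(), b(), b(), b(), b(), hidden_dim)

    def parameters(self) -> list[Tensor]:
        return [
            self.w_f, self.w_i, self.w_c, self.w_o,
            self.u_f, self.u_i, self.u_c, self.u_o,
            self.b_f, self.b_i, self.b_c, self.b_o,
        ]


def lstm_step(x_t, h_prev, c_prev, p: LSTMParams) -> tuple[Tensor, Tensor]:
    """One LSTM cell update; returns ``(h_t, c_t)``.

    Accepts single vectors or batches (leading batch dimension).
    """
    x_t, h_prev, c_prev = as_tensor(x_t), as_tensor(h_prev), as_tensor(c_prev)
    f = sigmoid(matmul(h_prev, p.w_f) + matmul(x_t, p.u_f) + p.b_f)
    i = sigmoid(matmul(h_prev, p.w_i) + matmul(x_t, p.u_i) + p.b_i)
    c_tilde = tanh(matmul(h_prev, p.w_c) + matmul(x_t, p.u_c) + p.b_c)
    c = f * c_prev + i * c_tilde
    o = sigmoid(matmul(h_prev, p.w_o) + matmul(x_t, p.u_o) + p.b_o)
    h = o * tanh(c)
    return h, c


def bilstm_encode(E, mask, p_fwd: LSTMParams, p_bwd: LSTMParams) -> FeatureMatrix:
    """Run forward and backward LSTMs over unmasked positions.

    Initial states are zero; state updates are gated by the mask so the
    recurrence skips masked (padding) positions, and outputs at masked
    positions are exactly zero.  Per-position output is ``[h_fwd; h_bwd]``.
    """
    V = _vals(E)
    B, n, _ = V.shape
    m = _mask_array(mask, n)
    H = p_fwd.hidden_dim

    def run(p: LSTMParams, order) -> list[Tensor]:
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor | None] = [None] * n
        for i in order:
            x = V[:, i, :]
            h_new, c_new = lstm_step(x, h, c, p)
            mi = m[:, i][:, None]
            h = h_new * mi + h * (1.0 - mi)
            c = c_new * mi + c * (1.0 - mi)
            outs[i] = reshape(h * mi, (B, 1, H))
        return outs  # type: ignore[return-value]

    fwd = run(p_fwd, range(n))
    bwd = run(p_bwd, range(n - 1, -1, -1))
    out = concat([concat(fwd, axis=1), concat(bwd, axis=1)], axis=-1)
    return FeatureMatrix(out, "bilstm")


# ---------------------------------------------------------------------------
# CNN path
# ---------------------------------------------------------------------------

@dataclass
class ConvKernel:
    width: int
    weight: Tensor  # (width * in_dim, out_channels)
    bias: Tensor  # (out_channels,)


_ACTIVATIONS = {"relu": relu, "tanh": tanh, "identity": lambda x: x}


@dataclass
class CNNParams:
    """A bank of same-padded 1-D convolutions sharing an output channel count."""

    kernels: list[ConvKernel]
    activation: str = "relu"

    def __post_init__(self):
        if not self.kernels:
            raise ValueError("need at least one convolution kernel")
        channels = {k.weight.shape[1] for k in self.kernels}
        if len(channels) != 1:
            raise ValueError("all kernels must share one output channel count")
        for k in self.kernels:
            if k.width < 1 or k.width % 2 == 0:
                raise ValueError(f"kernel widths must be odd and >= 1, got {k.width}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def out_channels(self) -> int:
        return self.kernels[0].weight.shape[1]

    @classmethod
    def init(
        cls,
        input_dim: int,
        widths: Sequence[int],
        channels: int,
        rng: np.random.Generator,
        activation: str = "relu",
    ) -> "CNNParams":
        kernels = []
        for w in widths:
            k = 1.0 / math.sqrt(w * input_dim)
            kernels.append(
                ConvKernel(
                    int(w),
                    Tensor(rng.uniform(-k, k, (w * input_dim, channels)), requires_grad=True),
                    Tensor(np.zeros(channels), requires_grad=True),
                )
            )
        return cls(kernels, activation)

    def parameters(self) -> list[Tensor]:
        out = []
        for k in self.kernels:
            out += [k.weight, k.bias]
        return out


def cnn_encode(E, mask, p: CNNParams) -> FeatureMatrix:
    """Convolve each kernel over the position axis and max-pool across widths.

    Same-length zero padding keeps the position axis intact so the CNN path
    aligns position-wise with the BiLSTM path.  Masked positions contribute
    zeros to every window and are zeroed in the output.
    """
    V = _vals(E)
    B, n, t = V.shape
    m = _mask_array(mask, n)
    act = _ACTIVATIONS[p.activation]
    X = V * m[:, :, None]
    combined: Tensor | None = None
    for kern in p.kernels:
        if kern.width > 2 * n:
            raise ValueError(f"kernel width {kern.width} too wide for {n} positions")
        half = kern.width // 2
        Xp = pad(X, ((0, 0), (half, half), (0, 0)))
        windows = concat([Xp[:, j : j + n, :] for j in range(kern.width)], axis=-1)
        y = act(matmul(windows, kern.weight) + kern.bias)
        combined = y if combined is None else maximum(combined, y)
    out = combined * m[:, :, None]
    return FeatureMatrix(out, "cnn")


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionParams:
    """Linear projections of both feature paths to a common width, then add."""

    proj_b: Tensor  # (bilstm_dim, z)
    proj_c: Tensor  # (cnn_dim, z)
    bias: Tensor  # (z,)

    @classmethod
    def init(cls, b_dim: int, c_dim: int, z: int, rng: np.random.Generator) -> "FusionParams":
        return cls(
            Tensor(rng.uniform(-1, 1, (b_dim, z)) / math.sqrt(b_dim), requires_grad=True),
            Tensor(rng.uniform(-1, 1, (c_dim, z)) / math.sqrt(c_dim), requires_grad=True),
            Tensor(np.zeros(z), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.proj_b, self.proj_c, self.bias]


def fuse(V_B, V_C, p: FusionParams) -> FeatureMatrix:
    """Project both paths to width ``z`` and add them position-wise."""
    vb, vc = _vals(V_B), _vals(V_C)
    if vb.shape[:-1] != vc.shape[:-1]:
        raise ValueError(
            f"position count mismatch: {vb.shape[:-1]} vs {vc.shape[:-1]}"
        )
    out = matmul(vb, p.proj_b) + matmul(vc, p.proj_c) + p.bias
    return FeatureMatrix(out, "fused")


# ---------------------------------------------------------------------------
# multihead self-attention
# ---------------------------------------------------------------------------

@dataclass
class MHAParams:
    """Per-head Q/K/V projections plus the output mixing matrix.

    ``d_k`` is the model width; each head projects to ``d_k // h`` and the
    attention scores are scaled by ``1 / sqrt(d_k)``.
    """

    h: int
    d_k: int
    w_q: list[Tensor]
    w_k: list[Tensor]
    w_v: list[Tensor]
    w_o: Tensor

    def __post_init__(self):
        if self.d_k % self.h != 0:
            raise ValueError(f"model width {self.d_k} not divisible by {self.h} heads")

    @classmethod
    def init(cls, d_model: int, heads: int, rng: np.random.Generator) -> "MHAParams":
        if d_model % heads != 0:
            raise ValueError(f"model width {d_model} not divisible by {heads} heads")
        dh = d_model // heads
        scale = 1.0 / math.sqrt(d_model)

        def proj():
            return Tensor(rng.uniform(-1, 1, (d_model, dh)) * scale, requires_grad=True)

        return cls(
            heads,
            d_model,
            [proj() for _ in range(heads)],
            [proj() for _ in range(heads)],
            [proj() for _ in range(heads)],
            Tensor(rng.uniform(-1, 1, (d_model, d_model)) * scale, requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [*self.w_q, *self.w_k, *self.w_v, self.w_o]


def multihead_attention(
    V, mask, p: MHAParams, return_weights: bool = False
):
    """Multihead scaled-dot-product self-attention with key masking.

    Queries, keys and values are all the input sequence.  Masked key
    positions receive a large negative additive score and hence zero
    attention weight; each attention row is a distribution over the
    unmasked keys.  Head outputs are concatenated and mixed by ``w_o``.
    """
    X = _vals(V)
    B, n, z = X.shape
    if z != p.d_k:
        raise ValueError(f"input width {z} != model width {p.d_k}")
    m = _mask_array(mask, n)
    key_bias = (1.0 - m)[:, None, :] * ATTENTION_MASK_VALUE  # (B, 1, n) constant
    scale = 1.0 / math.sqrt(p.d_k)
    heads = []
    weights = []
    for i in range(p.h):
        Q = matmul(X, p.w_q[i])
        K = matmul(X, p.w_k[i])
        Vv = matmul(X, p.w_v[i])
        scores = matmul(Q, swapaxes(K, -1, -2)) * scale + key_bias
        attn = softmax(scores, axis=-1)
        heads.append(matmul(attn, Vv))
        if return_weights:
            weights.append(attn.data)
    out = matmul(concat(heads, axis=-1), p.w_o) * m[:, :, None]
    fm = FeatureMatrix(out, "attended")
    if return_weights:
        return fm, np.stack(weights, axis=1)  # (B, h, n, n)
    return fm


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def dropout(x, keep_prob: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: keep each activation with probability ``keep_prob``."""
    if not 0.0 < keep_prob <= 1.0:
        raise ValueError("keep_prob must be in (0, 1]")
    x = _vals(x)
    if keep_prob >= 1.0:
        return x
    keep = (rng.random(x.shape) < keep_prob) / keep_prob
    return mul(x, keep)
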