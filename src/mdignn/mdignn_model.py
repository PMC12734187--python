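"""The directed-graph neural network.

Architecture: stacked magnetic spectral convolution layers operating on
complex activations,

    X(ℓ) = σ( X(ℓ−1) W_self(ℓ) + L̃(q) X(ℓ−1) W_neigh(ℓ) + B(ℓ) ),

with the complex ReLU σ(z) = z·1[Re(z) ≥ 0]; the final complex activations
are unwound to a real N×2F matrix [Re | Im], refined by sequential channel
and spatial attention, and scored by a single fully connected layer with a
sigmoid, giving one driver probability per gene.

The identity/neighbor weight pair is the K=1 Chebyshev filter of the
shifted magnetic Laplacian; higher Chebyshev orders add one weight matrix
per polynomial term (T_k(L̃) X W_k).

Two code paths share the ModelParams container: the plain-numpy functions
here (inference and the documented per-op surface) and the autodiff
training graph in :mod:`mdignn.train_eval`. Their agreement is enforced by
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .autodiff import Tensor, parameter
from .core_io import RunConfig

__all__ = [
    "ModelParams",
    "init_params",
    "complex_relu",
    "conv_layer",
    "unwind",
    "channel_attention",
    "spatial_attention",
    "forward",
]

SPATIAL_KERNEL_WIDTH = 7


@dataclass
class LayerParams:
    """One convolution layer: Chebyshev weight stack + bias, re/im split.

    ``w_re[k]``/``w_im[k]`` multiply the k-th Chebyshev term; k=0 is the
    self weight, k=1 the neighbor weight.
    """

    w_re: list[Tensor]
    w_im: list[Tensor]
    b_re: Tensor
    b_im: Tensor

    @property
    def Wself(self) -> np.ndarray:
        return self.w_re[0].value + 1j * self.w_im[0].value

    @property
    def Wneigh(self) -> np.ndarray:
        return self.w_re[1].value + 1j * self.w_im[1].value

    @property
    def B(self) -> np.ndarray:
        return self.b_re.value + 1j * self.b_im.value


@dataclass
class ModelParams:
    """All learnable parameters; attention blocks are None when ablated."""

    layers: list[LayerParams]
    att_w1: Tensor | None = None
    att_b1: Tensor | None = None
    att_w2: Tensor | None = None
    att_b2: Tensor | None = None
    conv_w: Tensor | None = None
    conv_b: Tensor | None = None
    head_w: Tensor = None
    head_b: Tensor = None
    complex_weights: bool = True
    _extra: dict = field(default_factory=dict)

    def trainable(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            out += layer.w_re
            out.append(layer.b_re)
            if self.complex_weights:
                out += layer.w_im
                out.append(layer.b_im)
        for t in (self.att_w1, self.att_b1, self.att_w2, self.att_b2,
                  self.conv_w, self.conv_b, self.head_w, self.head_b):
            if t is not None:
                out.append(t)
        return out

    def copy_values(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.trainable()]

    def load_values(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.trainable(), values, strict=True):
            p.value[...] = v


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: RunConfig, in_dim: int,
                rng: np.random.Generator) -> ModelParams:
    """Glorot-uniform init (independently on real and imaginary parts),
    zero biases; seeded through ``rng``."""
    complex_weights = not config.gcn_mode
    layers: list[LayerParams] = []
    f_in = in_dim
    for _ in range(config.num_layers):
        f_out = config.num_filters
        w_re, w_im = [], []
        for _k in range(config.cheb_order + 1):
            w_re.append(parameter(_glorot(rng, f_in, f_out)))
            if complex_weights:
                w_im.append(parameter(_glorot(rng, f_in, f_out)))
            else:
                w_im.append(Tensor(np.zeros((f_in, f_out))))
        layers.append(
            LayerParams(
                w_re=w_re,
                w_im=w_im,
                b_re=parameter(np.zeros((1, f_out))),
                b_im=(parameter(np.zeros((1, f_out))) if complex_weights
                      else Tensor(np.zeros((1, f_out)))),
            )
        )
        f_in = f_out
    width = 2 * config.num_filters  # unwound [Re | Im]
    params = ModelParams(layers=layers, complex_weights=complex_weights)
    if config.channel_attention:
        r = config.attention_reduction
        if width < r:
            raise ValueError(
                f"attention reduction {r} exceeds channel width {width}; use a smaller r"
            )
        hidden = max(width // r, 1)
        params.att_w1 = parameter(_glorot(rng, width, hidden))
        params.att_b1 = parameter(np.zeros((1, hidden)))
        params.att_w2 = parameter(_glorot(rng, hidden, width))
        params.att_b2 = parameter(np.zeros((1, width)))
    if config.spatial_attention:
        params.conv_w = parameter(
            _glorot(rng, SPATIAL_KERNEL_WIDTH, 2).reshape(SPATIAL_KERNEL_WIDTH, 2)
        )
        params.conv_b = parameter(np.zeros(1))
    params.head_w = parameter(_glorot(rng, width, 1))
    params.head_b = parameter(np.zeros((1, 1)))
    return params


# ---------------------------------------------------------------------------
# Plain-numpy ops (inference / documented surface)


def complex_relu(z: np.ndarray) -> np.ndarray:
    """z where Re(z) >= 0, else 0 (boundary Re = 0 is kept)."""
    z = np.asarray(z, dtype=np.complex128)
    return z * (z.real >= 0)


def conv_layer(x_prev: np.ndarray, L_shifted, params: ModelParams,
               layer: int) -> np.ndarray:
    """One magnetic convolution layer on complex activations."""
    lp = params.layers[layer]
    x = np.asarray(x_prev, dtype=np.complex128)
    z = np.zeros((x.shape[0], lp.w_re[0].value.shape[1]), dtype=np.complex128)
    t_prev, t_curr = None, x
    for k in range(len(lp.w_re)):
        w = lp.w_re[k].value + 1j * lp.w_im[k].value
        if x.shape[1] != w.shape[0]:
            raise ValueError(
                f"layer {layer}: input width {x.shape[1]} != weight rows {w.shape[0]}"
            )
        z += t_curr @ w
        if k + 1 < len(lp.w_re):
            t_next = L_shifted @ t_curr if t_prev is None \
                else 2.0 * (L_shifted @ t_curr) - t_prev
            t_prev, t_curr = t_curr, t_next
    z += lp.b_re.value + 1j * lp.b_im.value
    return complex_relu(z)


def unwind(x_complex: np.ndarray) -> np.ndarray:
    """N×F complex → N×2F real: [Re(X) | Im(X)]."""
    x = np.asarray(x_complex, dtype=np.complex128)
    return np.concatenate([x.real, x.imag], axis=1)


def channel_attention(x: np.ndarray, params: ModelParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel reweighting from globally average-pooled statistics.

    Returns (Mc, X ⊙ Mc) with Mc = sigmoid(MLP(column means)) in (0,1)^F.
    """
    pool = x.mean(axis=0, keepdims=True)
    h = np.maximum(pool @ params.att_w1.value + params.att_b1.value, 0.0)
    mc = _sigmoid(h @ params.att_w2.value + params.att_b2.value)
    return mc.ravel(), x * mc


def spatial_attention(x: np.ndarray, params: ModelParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-node reweighting: channel-wise avg and max pooling, a width-7
    1-D convolution along the canonical node order, then a sigmoid."""
    if x.shape[0] < 1:
        raise ValueError("spatial attention requires at least one node")
    pooled = np.stack([x.mean(axis=1), x.max(axis=1)], axis=1)
    pad = SPATIAL_KERNEL_WIDTH // 2
    n = x.shape[0]
    xpad = np.zeros((n + 2 * pad, 2))
    xpad[pad:pad + n] = pooled
    scores = np.full(n, params.conv_b.value.item())
    for k in range(SPATIAL_KERNEL_WIDTH):
        scores += xpad[k:k + n] @ params.conv_w.value[k]
    ms = _sigmoid(scores)
    return ms, x * ms[:, None]


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(v, -500, 500)))


def forward(features: np.ndarray, L_shifted, params: ModelParams,
            config: RunConfig, return_logits: bool = False) -> np.ndarray:
    """Eval-mode forward pass: per-gene driver probability.

    Dropout is inactive here (inference); the training path lives in
    :func:`mdignn.train_eval.forward_graph`.
    """
    x = np.asarray(features, dtype=np.complex128)
    for layer in range(len(params.layers)):
        x = conv_layer(x, L_shifted, params, layer)
    h = unwind(x)
    if config.channel_attention:
        _, h = channel_attention(h, params)
    if config.spatial_attention:
        _, h = spatial_attention(h, params)
    logits = (h @ params.head_w.value + params.head_b.value).ravel()
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite activation at the scoring head")
    if return_logits:
        return logits
    return _sigmoid(logits)
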