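"""Minimal reverse-mode automatic differentiation over real numpy arrays.

Just enough machinery for full-batch training of the model: broadcasting
arithmetic, dense/sparse matmul, sigmoid/relu/softplus, axis reductions,
max-pooling, concatenation, a width-7 1-D convolution, and an Adam
optimizer with L2 weight decay. Complex quantities never appear here —
model code carries them as explicit (real, imaginary) tensor pairs, so all
gradients are plain real calculus.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "constant", "parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph holding a real ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph execution ----------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of ``self`` (a scalar) into all parameters."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------

    def _binary(self, other, forward, back_self, back_other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_val = forward(self.value, other.value)
        out = Tensor(out_val, parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(back_self(grad, self.value, other.value), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(back_other(grad, self.value, other.value), other.shape))

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def backward(grad):
            if self.requires_grad:
                g = grad @ other.value.T
                self._accumulate(g.reshape(self.shape))
            if other.requires_grad:
                g = self.value.T @ grad
                other._accumulate(g.reshape(other.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        out = Tensor(s, parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * s * (1.0 - s))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        mask = self.value > 0
        out = Tensor(self.value * mask, parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * mask)

        out._backward = backward
        return out

    def softplus(self) -> "Tensor":
        # stable: softplus(x) = max(x, 0) + log1p(exp(-|x|))
        v = self.value
        out_val = np.maximum(v, 0.0) + np.log1p(np.exp(-np.abs(v)))
        out = Tensor(out_val, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(v, -500, 500)))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * sig)

        out._backward = backward
        return out

    def mask(self, mask_array: np.ndarray) -> "Tensor":
        """Multiply by a constant 0/1 (or scaled) mask — used for the
        complex ReLU gate and for dropout."""
        m = np.asarray(mask_array, dtype=np.float64)
        out = Tensor(self.value * m, parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * m, self.shape))

        out._backward = backward
        return out

    # -- reductions, shaping --------------------------------------------------

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.mean(axis=axis, keepdims=keepdims), parents=(self,))
        denom = self.value.size if axis is None else self.value.shape[axis]

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape) / denom)

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.value, axis=axis)
        out_val = np.max(self.value, axis=axis, keepdims=keepdims)
        out = Tensor(out_val, parents=(self,))

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            full = np.zeros_like(self.value)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._accumulate(full)

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.value.reshape(*shape), parents=(self,))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.shape))

        out._backward = backward
        return out

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Row subset (for masking the loss to labeled nodes)."""
        out = Tensor(self.value[index], parents=(self,))

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, index, grad)
                self._accumulate(full)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                 parents=tuple(tensors))
    splits = np.cumsum([t.value.shape[axis] for t in tensors])[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(g)

    out._backward = backward
    return out


def spmatmul(S: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse matrix @ tensor; gradient is Sᵀ @ grad."""
    S = S.tocsr()
    out = Tensor(S @ x.value, parents=(x,))
    ST = S.T.tocsr()

    def backward(grad):
        if x.requires_grad:
            x._accumulate(ST @ grad)

    out._backward = backward
    return out


def conv1d_width(x: Tensor, weight: Tensor, bias: Tensor, width: int = 7) -> Tensor:
    """1-D convolution over axis 0 of an N×C input with same-padding.

    ``weight`` is width×C, ``bias`` a scalar; output is an N-vector:
    out[i] = Σ_{k,c} xpad[i+k, c] · w[k, c] + b.
    """
    pad = width // 2
    n, c = x.value.shape
    xpad = np.zeros((n + 2 * pad, c))
    xpad[pad:pad + n] = x.value
    out_val = np.full(n, bias.value.item())
    for k in range(width):
        out_val += xpad[k:k + n] @ weight.value[k]
    out = Tensor(out_val, parents=(x, weight, bias))

    def backward(grad):
        if weight.requires_grad:
            gw = np.empty_like(weight.value)
            for k in range(width):
                gw[k] = grad @ xpad[k:k + n]
            weight._accumulate(gw)
        if bias.requires_grad:
            bias._accumulate(np.asarray(grad.sum()).reshape(bias.shape))
        if x.requires_grad:
            gx_pad = np.zeros_like(xpad)
            for k in range(width):
                gx_pad[k:k + n] += np.outer(grad, weight.value[k])
            x._accumulate(gx_pad[pad:pad + n])

    out._backward = backward
    return out


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam with (coupled) L2 weight decay, matching the common
    deep-learning-framework convention of adding wd·θ to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
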