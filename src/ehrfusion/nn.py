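"""Minimal reverse-mode automatic differentiation on numpy arrays.

All trainable components of the package (semantic text encoder, time-series
transformer, fusion MLP, training losses) are built on the :class:`Tensor`
defined here.  The design follows the classic define-by-run tape: every
operation records a closure that accumulates gradients into its inputs, and
``Tensor.backward`` walks the tape in reverse topological order.

Everything is float64 and single-threaded numpy, which keeps runs bitwise
reproducible across machines for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "gather_rows",
    "Adam",
    "Linear",
    "LayerNorm",
    "MaskedSequenceNorm",
    "MultiHeadSelfAttention",
    "FeedForward",
    "TransformerLayer",
    "sinusoidal_positions",
    "gelu_scalar",
]

_SQRT_2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward: Callable[[], None] | None = None
        self._prev = _prev
        self._grad_owned = False

    # -- infrastructure ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # copy-on-write: alias the first incoming gradient, allocate only if a
        # second contribution arrives (topological order makes this safe)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw():
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, axes: Sequence[int]):
        out = Tensor(np.transpose(self.data, axes), _prev=(self,))
        inv = np.argsort(axes)

        def _bw():
            if self.requires_grad:
                self._accum(np.transpose(out.grad, inv))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0.0))

        out._backward = _bw
        return out

    def gelu(self):
        """Exact Gaussian-error-function GELU: x * Phi(x)."""
        phi = 0.5 * (1.0 + erf(self.data / _SQRT_2))
        out = Tensor(self.data * phi, _prev=(self,))

        def _bw():
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * self.data ** 2)
                self._accum(out.grad * (phi + self.data * pdf))

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - t ** 2))

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        inside = (self.data > lo) & (self.data < hi)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * inside)

        out._backward = _bw
        return out

    def masked_softmax(self, mask: np.ndarray, axis: int = -1):
        """Softmax over ``axis`` restricted to positions where ``mask`` is true.

        Fully masked rows yield all-zero output rather than NaN.
        """
        x = np.where(mask, self.data, -np.inf)
        m = np.max(x, axis=axis, keepdims=True, initial=-np.inf)
        e = np.exp(np.where(mask, x - np.where(np.isfinite(m), m, 0.0), -np.inf))
        denom = e.sum(axis=axis, keepdims=True)
        y = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
        out = Tensor(y, _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = _bw
        return out


class Parameter(Tensor):
    """A leaf tensor that optimizers update in place."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = _bw
    return out


def gather_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup ``table[ids]`` with scatter-add gradient."""
    out = Tensor(table.data[ids], _prev=(table,))

    def _bw():
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, ids, out.grad)
            table._accum(g)

    out._backward = _bw
    return out


def gelu_scalar(x):
    """Closed-form GELU on plain arrays (used by oracles and docs)."""
    x = np.asarray(x, dtype=np.float64)
    return x * 0.5 * (1.0 + erf(x / _SQRT_2))


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sin/cos positional encodings at geometric wavelengths.

    Even channels carry sin(pos / 10000^(2i/dim)), odd channels the matching
    cos, the standard fixed scheme for transformer encoders.
    """
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(dim // 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.zeros((length, dim), dtype=np.float64)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles[:, : dim - dim // 2] if dim % 2 else angles)
    return pe


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, v in vars(self).items():
            if isinstance(v, Parameter):
                state[prefix + k] = v.data.copy()
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{prefix}{k}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in vars(self).items():
            if isinstance(v, Parameter):
                v.data = np.asarray(state[prefix + k], dtype=np.float64).copy()
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Parameter(_xavier(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        return y * self.gamma + self.beta


class MaskedSequenceNorm(Module):
    """Batch-norm-style feature normalization over a visit sequence.

    Statistics are computed per sequence over *valid* (masked-in) time
    positions only, so padded rows can never leak into the normalization of
    real visits and the output is invariant to the amount of trailing
    padding.  Padded rows are zeroed on output.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        # x: (B, w, dim); mask: (B, w) booleans
        if mask is None:
            mask = np.ones(x.shape[:2], dtype=bool)
        m = mask[:, :, None].astype(np.float64)
        cnt = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
        xm = x * m
        mu = xm.sum(axis=1, keepdims=True) * (1.0 / cnt)
        xc = (x - mu) * m
        var = (xc * xc).sum(axis=1, keepdims=True) * (1.0 / cnt)
        y = xc * (var + self.eps) ** -0.5
        return y * self.gamma + self.beta * m


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        B, w, d = x.shape
        H, dk = self.n_heads, self.d_k

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, w, H, dk).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        q = q * (1.0 / np.sqrt(dk))  # fold the score scaling into Q
        scores = q @ k.transpose((0, 1, 3, 2))
        # masked keys are excluded from the softmax; a query whose keys are
        # all masked gets an all-zero attention row, hence zero context
        attn = scores.masked_softmax(key_mask[:, None, None, :], axis=-1)
        ctx = attn @ v
        out = ctx.transpose((0, 2, 1, 3)).reshape(B, w, d)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ffn: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "gelu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.lin1 = Linear(d_model, d_ffn, rng)
        self.lin2 = Linear(d_ffn, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.lin1(x)
        h = h.relu() if self.activation == "relu" else h.gelu()
        return self.lin2(h)


class TransformerLayer(Module):
    """Post-norm encoder block: x <- norm(x + attn(x)); x <- norm(x + ffn(x))."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_ffn: int,
        activation: str,
        norm: str,
        rng: np.random.Generator,
    ):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ffn, activation, rng)
        norm_cls = {"layer": LayerNorm, "batch": MaskedSequenceNorm}[norm]
        self.norm1 = norm_cls(d_model)
        self.norm2 = norm_cls(d_model)

    def __call__(
        self,
        x: Tensor,
        key_mask: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        a = self.attn(x, key_mask)
        a = _dropout(a, dropout, rng)
        x = self.norm1(x + a, key_mask)
        f = self.ffn(x)
        f = _dropout(f, dropout, rng)
        return self.norm2(x + f, key_mask)


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * keep


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
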