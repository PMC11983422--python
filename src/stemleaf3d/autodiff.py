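"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in :mod:`stemleaf3d.network` needs gradients for a
handful of dense operations (pointwise linear layers, batched gathers,
reductions, sigmoid/ReLU nonlinearities).  This module provides exactly that:
a :class:`Tensor` wrapping an ``ndarray`` plus a tape of vector-Jacobian
closures, and the few layer/optimizer helpers the network uses.  Everything is
vectorized; no per-element Python loops occur in forward or backward passes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "Module",
    "Linear",
    "BatchNorm",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` so it has ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @classmethod
    def _make(cls, data, parents, vjps):
        out = cls(data)
        keep = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad]
        if keep:
            out.requires_grad = True
            out._parents = tuple(p for p, _ in keep)
            out._vjps = tuple(v for _, v in keep)
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, weak promotion
            return Tensor._make(self.data + other, (self,), (lambda g: g,))
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data - other, (self,), (lambda g: g,))
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(other - self.data, (self,), (lambda g: -g,))
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data * other, (self,), (lambda g: g * other,))
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g * other.data, self.data.shape),
                lambda g: _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g / other.data, self.data.shape),
                lambda g: _unbroadcast(
                    -g * self.data / (other.data**2), other.data.shape
                ),
            ),
        )

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(
                other / self.data,
                (self,),
                (lambda g: -g * other / (self.data**2),),
            )
        return self._coerce(other) / self

    def __matmul__(self, other):
        """Matrix product ``(..., n, m) @ (m, p)`` (weight is always 2-D)."""
        other = self._coerce(other)
        if other.data.ndim != 2:
            raise ValueError("matmul: right operand must be 2-D")
        out = self.data @ other.data

        def g_left(g):
            return g @ other.data.T

        def g_right(g):
            a = self.data.reshape(-1, self.data.shape[-1])
            gg = g.reshape(-1, g.shape[-1])
            return a.T @ gg

        return Tensor._make(out, (self, other), (g_left, g_right))

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(
            self.data**e,
            (self,),
            (lambda g: g * e * self.data ** (e - 1.0),),
        )

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), (lambda g: g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), (lambda g: g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), (lambda g: g * e,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), (lambda g: g / self.data,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor._make(r, (self,), (lambda g: g * 0.5 / r,))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), (lambda g: g * mask,)
        )

    # -- reductions & shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.data.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._make(out, (self,), (vjp,))

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)
        mx = self.data.max(axis=axis, keepdims=True)
        mask = self.data == mx
        # split gradient among ties to keep the vjp well defined
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def vjp(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return g * mask

        return Tensor._make(out, (self,), (vjp,))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), (lambda g: g.reshape(old),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes), (self,), (lambda g: g.transpose(*inv),)
        )

    # -- backward ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, vjp in zip(node._parents, node._vjps):
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor._make(out, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Batched point gather: x (B, N, C), idx (B, ...) -> (B, ..., C).

    Backward scatter-adds into the source positions.
    """
    idx = np.asarray(idx)
    B, N, C = x.data.shape
    b = np.arange(B).reshape((B,) + (1,) * (idx.ndim - 1))
    out = x.data[b, idx]
    flat = (np.broadcast_to(b, idx.shape) * N + idx).ravel()

    def vjp(g):
        from ._fast import scatter_add_rows

        gx = np.zeros((B * N, C), dtype=g.dtype)
        scatter_add_rows(gx, flat, g.reshape(-1, C))
        return gx.reshape(B, N, C)

    return Tensor._make(out, (x,), (vjp,))


# ---------------------------------------------------------------------------
# Layers


class Module:
    """Lightweight parameter container with train/eval state."""

    training: bool = True

    def parameters(self) -> list:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def state_arrays(self, prefix: str = "") -> dict:
        """Flat name -> ndarray map of parameters and buffers, for checkpoints."""
        out = {}
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data
            elif isinstance(v, np.ndarray):
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{name}.{i}."))
        return out

    def load_state_arrays(self, state: dict, prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[name], dtype=v.data.dtype)
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(state[name], dtype=v.dtype)
            elif isinstance(v, Module):
                v.load_state_arrays(state, name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{name}.{i}.")


class Linear(Module):
    """Pointwise linear layer acting on the trailing channel axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_features, out_features)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)
        self.in_features = in_features
        self.out_features = out_features

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization over all leading axes, channels last.

    In training mode statistics are computed over every axis except the last
    and folded into running estimates; in eval mode the running estimates are
    used.  A single sample row (one element per channel) degenerates to the
    learned affine transform alone.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        n_rows = int(np.prod([x.shape[a] for a in axes])) if axes else 1
        if self.training and n_rows > 1:
            return self._fused_train(x, axes, n_rows)
        if self.training:  # single row: affine only
            return x * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * Tensor(inv) * self.gamma + self.beta

    def _fused_train(self, x: Tensor, axes: tuple, n_rows: int) -> Tensor:
        """Single-op batch normalization with the closed-form backward pass."""
        xd = x.data
        mu = xd.mean(axis=axes)
        xc = xd - mu
        var = np.mean(xc * xc, axis=axes)
        m = self.momentum
        self.running_mean = (1 - m) * self.running_mean + m * mu.astype(np.float32)
        self.running_var = (1 - m) * self.running_var + m * var.astype(np.float32)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        gamma, beta = self.gamma, self.beta
        out = xhat * gamma.data + beta.data

        def g_x(g):
            dxhat = g * gamma.data
            return inv * (
                dxhat
                - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)
            )

        def g_gamma(g):
            return (g * xhat).sum(axis=axes)

        def g_beta(g):
            return g.sum(axis=axes)

        return Tensor._make(out, (x, gamma, beta), (g_x, g_gamma, g_beta))


class AdamW(Module):
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = p.data - self.lr * (update + self.weight_decay * p.data)
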