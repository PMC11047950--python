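"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the small set of differentiable operations the toolkit
needs — elementwise arithmetic, 2D convolution (via im2col + BLAS matmul),
the usual nonlinearities, reductions and reshapes — together with a tiny
``Module`` container system and an Adam optimizer.

The engine is tape-based: every operation returns a new :class:`Tensor`
holding references to its parents and a closure that maps the output gradient
to parent gradients. ``Tensor.backward()`` runs a topological sweep. Gradients
accumulate in ``Tensor.grad`` for tensors with ``requires_grad=True``.

Arrays keep whatever dtype they are given; training code uses float32 for
speed, gradient-check tests use float64 for accuracy.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Adam",
    "no_grad",
    "conv2d",
    "relu",
    "exp",
    "log",
    "sigmoid",
    "clip",
    "softmax",
    "group_norm",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference-only forward)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from length 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 grad_fn: Callable[[np.ndarray], Sequence] | None = None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        if grad_fn is not None and not _GRAD_ENABLED:
            parents, grad_fn = (), None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._grad_fn = grad_fn
        self.grad: np.ndarray | None = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor.

        If `grad` is omitted the tensor must be scalar-shaped; the seed
        gradient is 1.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.data)

        # topological order via iterative DFS
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._grad_fn is not None:
                parent_grads = node._grad_fn(g)
                for p, pg in zip(node._parents, parent_grads):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:  # leaf
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g
        # the root might itself be a leaf
        if self._grad_fn is None and self.requires_grad and self.grad is None:
            self.grad = grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data
        sa, sb = self.data.shape, other.data.shape

        def grad_fn(g):
            return _unbroadcast(g, sa), _unbroadcast(g, sb)

        return Tensor(out_data, parents=(self, other), grad_fn=grad_fn)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), grad_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def grad_fn(g):
            return _unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)

        return Tensor(a * b, parents=(self, other), grad_fn=grad_fn)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def grad_fn(g):
            return _unbroadcast(g / b, a.shape), _unbroadcast(-g * a / (b * b), b.shape)

        return Tensor(a / b, parents=(self, other), grad_fn=grad_fn)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("tensor exponents are not supported; use exp/log")
        e = float(exponent)
        a = self.data
        out = a ** e

        def grad_fn(g):
            return (g * e * a ** (e - 1.0),)

        return Tensor(out, parents=(self,), grad_fn=grad_fn)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor(self.data.reshape(shape), parents=(self,),
                      grad_fn=lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor(self.data.transpose(axes), parents=(self,),
                      grad_fn=lambda g: (g.transpose(inv),))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy() if np.ndim(g) == 0 or g.shape != shape
                        else g,)
            g2 = g
            if not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % len(shape) for a in axes)
                for a in sorted(axes):
                    g2 = np.expand_dims(g2, a)
            return (np.broadcast_to(g2, shape).copy(),)

        return Tensor(out, parents=(self,), grad_fn=grad_fn)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a % self.data.ndim] for a in ((axis,) if isinstance(axis, int) else axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


class Parameter(Tensor):
    """A leaf tensor that an optimizer updates."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    return Tensor(out, parents=(x,), grad_fn=lambda g: (g * (out > 0),))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return Tensor(out, parents=(x,), grad_fn=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    a = x.data
    return Tensor(np.log(a), parents=(x,), grad_fn=lambda g: (g / a,))


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(np.asarray(x.data, dtype=x.data.dtype))
    return Tensor(s, parents=(x,), grad_fn=lambda g: (g * s * (1.0 - s),))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp to [lo, hi]; gradient passes only through the interior."""
    mask = (x.data >= lo) & (x.data <= hi)
    return Tensor(np.clip(x.data, lo, hi), parents=(x,),
                  grad_fn=lambda g: (g * mask,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`.

    The max-shift uses detached data (a constant offset does not change the
    gradient of softmax).
    """
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = exp(x - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over [N, C, H, W] with per-channel affine.

    Statistics are computed per sample per group of channels, so the op is
    batch-size independent and identical in train and eval modes. The
    backward pass uses the standard fused normalization gradient.
    """
    n, c, h, w = x.data.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    xg = x.data.reshape(n, groups, -1)
    k = xg.shape[2]
    mean = xg.mean(axis=2, keepdims=True)
    m2 = np.einsum("ngk,ngk->ng", xg, xg)[..., None] / k
    var = np.maximum(m2 - mean * mean, 0.0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv).reshape(n, c, h, w)
    gshape = gamma.data.reshape(1, c, 1, 1)
    out = xhat * gshape + beta.data.reshape(1, c, 1, 1)

    def grad_fn(g):
        gx = ggamma = gbeta = None
        if gamma.requires_grad:
            ggamma = (g * xhat).sum(axis=(0, 2, 3)).reshape(gamma.data.shape)
        if beta.requires_grad:
            gbeta = g.sum(axis=(0, 2, 3)).reshape(beta.data.shape)
        if x.requires_grad:
            dy = (g * gshape).reshape(n, groups, -1)
            xh = xhat.reshape(n, groups, -1)
            d1 = dy.mean(axis=2, keepdims=True)
            d2 = (np.einsum("ngk,ngk->ng", dy, xh) / k)[..., None]
            gx = ((dy - d1 - xh * d2) * inv).reshape(n, c, h, w)
        return gx, ggamma, gbeta

    return Tensor(out, parents=(x, gamma, beta), grad_fn=grad_fn)


# ---------------------------------------------------------------------------
# 2D convolution
# ---------------------------------------------------------------------------

def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else (int(v[0]), int(v[1]))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """2D cross-correlation of a batch `x` [N,C,H,W] with kernels `w` [O,C,kh,kw].

    Implemented as im2col followed by a single BLAS matmul, which is where
    essentially all training time is spent; both forward and backward reduce
    to GEMM calls plus a col2im scatter.
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    o, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {c2}")
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (wdt + 2 * pw - kw) // sw + 1

    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * sh, s3 * sw))
    # [C*kh*kw, N*oh*ow] — the copy happens here, once
    colsmat = np.ascontiguousarray(cols.transpose(1, 2, 3, 0, 4, 5)).reshape(c * kh * kw, n * oh * ow)
    wmat = wd.reshape(o, c * kh * kw)
    out = (wmat @ colsmat).reshape(o, n, oh, ow).transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def grad_fn(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, n * oh * ow)
        gw = gb = gx = None
        if w.requires_grad:
            gw = (gmat @ colsmat.T).reshape(wd.shape)
        if b is not None and b.requires_grad:
            gb = g.sum(axis=(0, 2, 3)).reshape(b.data.shape)
        if x.requires_grad:
            # scatter in channel-first layout (contiguous slices), transpose once
            dcols = (wmat.T @ gmat).reshape(c, kh, kw, n, oh, ow)
            dxp = np.zeros((c, n) + xp.shape[2:], dtype=xp.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += dcols[:, i, j]
            if ph or pw:
                dxp = dxp[:, :, ph:ph + h, pw:pw + wdt]
            gx = np.ascontiguousarray(dxp.transpose(1, 0, 2, 3))
        return (gx, gw) if b is None else (gx, gw, gb)

    return Tensor(np.ascontiguousarray(out), parents=parents, grad_fn=grad_fn)


# ---------------------------------------------------------------------------
# modules and optimization
# ---------------------------------------------------------------------------

class Module:
    """Lightweight parameter container with recursive discovery.

    Any attribute that is a :class:`Parameter`, a :class:`Module`, or a
    list/tuple/dict of modules is picked up by :meth:`named_parameters`.
    """

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item
            elif isinstance(value, dict):
                for k, item in value.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{k}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{k}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)


class Adam:
    """Adam optimizer (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
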