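"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's neural components (line-graph message passing, transformer
encoder, prediction heads) are small enough to train on a CPU, so they are
built on this self-contained tape-based engine rather than an external
framework: a :class:`Tensor` records the operations producing it and
`backward()` accumulates gradients in reverse topological order. Arrays are
float32 throughout; broadcasting follows numpy semantics with gradients
summed back over broadcast axes.

Only the operations the model needs are implemented; each op defines its
own vector-Jacobian product inline.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor", "Parameter", "Module", "Linear", "Embedding", "LayerNorm",
    "concat", "stack", "gather_rows", "scatter_rows", "segment_sum",
    "softmax", "sigmoid", "relu", "gelu", "tanh",
    "AdamW", "warmup_linear_schedule", "set_grad_enabled", "no_grad",
]

_GRAD_ENABLED = True


class set_grad_enabled:
    def __init__(self, mode: bool):
        self.mode = mode

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = self.mode

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev


def no_grad():
    return set_grad_enabled(False)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # numpy must defer mixed expressions (ndarray ∘ Tensor) to our
    # reflected operators instead of broadcasting over the object
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ---------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() needs a single-element tensor")
        return float(self.data.reshape(()))

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff core ----------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS (graphs can be deep for long training sequences)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad, dtype=DTYPE), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))
        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(_matmul_lhs_grad(g, self.data, other.data))
            if other.requires_grad:
                other._accum(_matmul_rhs_grad(g, self.data, other.data))
        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out


def _matmul_lhs_grad(g, a, b):
    if b.ndim == 1:
        return np.expand_dims(g, -1) * b
    grad = g @ np.swapaxes(b, -1, -2)
    return _unbroadcast(grad, a.shape) if grad.shape != a.shape else grad


def _matmul_rhs_grad(g, a, b):
    if a.ndim == 1:
        return np.outer(a, g) if b.ndim == 2 else a[:, None] * g
    grad = np.swapaxes(a, -1, -2) @ g
    return _unbroadcast(grad, b.shape) if grad.shape != b.shape else grad


# -- functional ops --------------------------------------------------------


def tanh(x: Tensor) -> Tensor:
    out = Tensor(np.tanh(x.data), x.requires_grad, (x,))
    out._backward = lambda g: x._accum(g * (1.0 - out.data ** 2))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))
    out._backward = lambda g: x._accum(g * out.data * (1.0 - out.data))
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """tanh-approximate GELU (the BERT-lineage nonlinearity)."""
    u = _GELU_C * (x.data + 0.044715 * x.data ** 3)
    t = np.tanh(u)
    out = Tensor(0.5 * x.data * (1.0 + t), x.requires_grad, (x,))
    def bw(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * x.data ** 2)
        x._accum(g * (0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t ** 2) * du))
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax along `axis`; `additive_mask` (e.g. -inf at padding) is a
    constant added to the logits before normalization."""
    z = x.data if additive_mask is None else x.data + additive_mask
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))
    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))
    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows x[index] (first axis); backward scatters with np.add.at."""
    index = np.asarray(index)
    out = Tensor(x.data[index], x.requires_grad, (x,))
    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        x._accum(full)
    out._backward = bw
    return out


def scatter_rows(src: Tensor, index: tuple[np.ndarray, np.ndarray],
                 shape: tuple[int, ...]) -> Tensor:
    """Place row vectors src[k] at positions (index[0][k], index[1][k]) of a
    zero tensor with the given (B, T, H) shape."""
    bi, ti = (np.asarray(i) for i in index)
    data = np.zeros(shape, dtype=DTYPE)
    data[bi, ti] = src.data
    out = Tensor(data, src.requires_grad, (src,))
    out._backward = lambda g: src._accum(g[bi, ti])
    return out


def segment_sum(src: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of src into `num_segments` buckets; backward is a gather."""
    seg = np.asarray(segment_ids)
    data = np.zeros((num_segments,) + src.data.shape[1:], dtype=DTYPE)
    np.add.at(data, seg, src.data)
    out = Tensor(data, src.requires_grad, (src,))
    out._backward = lambda g: src._accum(g[seg])
    return out


# -- modules ---------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive traversal (torch-like, tiny)."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)
        visit(self)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y if self.b is None else y + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, width: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, width)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return gather_rows(self.table, idx)


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = Tensor(xhat, x.requires_grad or self.gamma.requires_grad,
                     (x, self.gamma, self.beta))
        gamma = self.gamma
        beta = self.beta
        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if beta.requires_grad:
                beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
            if x.requires_grad:
                gy = g * gamma.data
                n = x.data.shape[-1]
                term = gy - gy.mean(axis=-1, keepdims=True) \
                    - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
                x._accum(term * inv)
        out._backward = bw
        out.data = xhat * gamma.data + beta.data
        return out


# -- optimizer -------------------------------------------------------------


class AdamW(Module):
    """AdamW with decoupled weight decay (lr 1e-4, wd 1e-2 defaults)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def warmup_linear_schedule(step: int, total_steps: int, base_lr: float,
                           warmup_fraction: float = 0.05) -> float:
    """Linear warm-up over the first `warmup_fraction` of steps, then linear
    decay to zero at the final step."""
    warm = max(1, int(round(warmup_fraction * total_steps)))
    if step < warm:
        return base_lr * (step + 1) / warm
    rest = max(1, total_steps - warm)
    return base_lr * max(0.0, (total_steps - step - 1) / rest)
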