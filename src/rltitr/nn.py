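"""Minimal reverse-mode autodiff over numpy arrays, with the handful of layers
the package's sequence models need (linear, embedding, layer norm, multi-head
self-attention, dropout) and an Adam optimizer.

The engine is deliberately small: tensors wrap ``numpy.ndarray``s, every
operation records a backward closure, and ``Tensor.backward`` runs a
topological sweep.  Only the operations used by the models are implemented.
"""

from __future__ import annotations

import json
import math
import zipfile
from io import BytesIO
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MLP",
    "TransformerEncoder",
    "Adam",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return self._make(data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data * data))

        return self._make(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return self._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(part)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean categorical cross-entropy of integer ``targets`` under ``logits``.

    ``logits`` has shape (..., n_classes); ``targets`` the leading shape.
    ``mask`` (same leading shape) selects which positions contribute.
    """
    lp = log_softmax(logits, axis=-1)
    flat = lp.reshape(-1, logits.shape[-1])
    idx = (np.arange(flat.shape[0]), np.asarray(targets).reshape(-1))
    picked = flat[idx]
    if mask is None:
        return -picked.mean()
    m = np.asarray(mask, dtype=np.float64).reshape(-1)
    denom = max(m.sum(), 1.0)
    return -(picked * m).sum() * (1.0 / denom)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for value in vars(self).values():
            if isinstance(value, Parameter) and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        v._collect(params, seen)
                    elif isinstance(v, Parameter) and id(v) not in seen:
                        seen.add(id(v))
                        params.append(v)

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.update(v.named_parameters(f"{key}.{i}."))
                    elif isinstance(v, Parameter):
                        out[f"{key}.{i}"] = v
        return out

    def train(self):
        self.training = True
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        x.train()
        return self

    def eval(self):
        self.training = False
        for v in vars(self).values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        x.eval()
        return self

    # -- checkpointing --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float64).copy()


def save_archive(path, arrays: dict[str, np.ndarray], meta: dict):
    """Single-file checkpoint: a zip of .npy members plus a JSON metadata entry."""
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for k, v in arrays.items():
            buf = BytesIO()
            np.save(buf, v)
            zf.writestr(k + ".npy", buf.getvalue())


def load_archive(path) -> tuple[dict[str, np.ndarray], dict]:
    arrays: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        for name in zf.namelist():
            if name.endswith(".npy"):
                arrays[name[:-4]] = np.load(BytesIO(zf.read(name)), allow_pickle=False)
    return arrays, meta


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gain + self.shift


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class MLP(Module):
    """Stack of ``n_layers`` linear maps with ReLU between (none after the last)."""

    def __init__(self, n_in: int, hidden: int, n_out: int, n_layers: int, rng, dropout: float = 0.0):
        super().__init__()
        dims = [n_in] + [hidden] * (n_layers - 1) + [n_out]
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(n_layers)]
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = self.drop(x.relu())
        return x


class SelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng, dropout: float):
        super().__init__()
        if dim % n_heads:
            raise ValueError("hidden dim must be divisible by the head count")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, causal_bias: np.ndarray) -> Tensor:
        B, T, D = x.shape
        qkv = self.qkv(x).reshape(B, T, 3, self.n_heads, self.d_head)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        scores = scores + causal_bias  # (B,H,T,T) broadcast of (T,T)
        att = self.drop(softmax(scores, axis=-1))
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, rng, dropout: float):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.att = SelfAttention(dim, n_heads, rng, dropout)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, 2 * dim, rng)
        self.ff2 = Linear(2 * dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, causal_bias: np.ndarray) -> Tensor:
        x = x + self.drop(self.att(self.ln1(x), causal_bias))
        h = self.drop(self.ff2(self.drop(self.ff1(self.ln2(x)).relu())))
        return x + h


class TransformerEncoder(Module):
    """Causal (left-to-right) transformer: position t attends only to ≤ t."""

    def __init__(self, dim: int, n_layers: int, n_heads: int, rng, dropout: float = 0.0):
        super().__init__()
        self.blocks = [TransformerBlock(dim, n_heads, rng, dropout) for _ in range(n_layers)]
        self.ln_out = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        bias = np.triu(np.full((T, T), -1e9), k=1)
        for block in self.blocks:
            x = block(x, bias)
        return self.ln_out(x)


class Adam(Module):
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        super().__init__()
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, max_grad_norm: float | None = 5.0):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if max_grad_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > max_grad_norm:
                scale = max_grad_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.betas
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
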