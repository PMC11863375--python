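"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's neural components (edge/local/global encoders, score MLPs)
are small graph networks evaluated on modest numbers of atoms and edges,
so a compact tape-based tensor engine is sufficient: each :class:`Tensor`
records its parents and a backward closure, and :meth:`Tensor.backward`
walks the tape in reverse topological order accumulating gradients.

Only the operations the model needs are provided; all of them support
NumPy broadcasting, with gradients reduced back to the operand shapes.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "MLP",
    "BatchNorm",
    "concat",
    "segment_sum",
    "no_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data ** 2)

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), bw)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g2, self.data.shape))

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return self._make(self.data * factor, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), bw)

    def gelu(self):
        # exact Gaussian-CDF form: x * Phi(x)
        from scipy.special import ndtr

        phi = ndtr(self.data)
        pdf = np.exp(-0.5 * self.data ** 2) / np.sqrt(2.0 * np.pi)
        out_data = self.data * phi

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (phi + self.data * pdf))

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._make(out_data, (self,), bw)

    def gather(self, idx: np.ndarray):
        """Select rows (first axis) by integer index array."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return self._make(out_data, (self,), bw)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out = Tensor(out_data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of `x` into `num_segments` buckets (message aggregation)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[segment_ids])

    return x._make(out_data, (x,), bw)


# ---------------------------------------------------------------------------
# Layers


class Module:
    """Base class: parameter registry, train/eval mode, state round-trip."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    # buffers (non-learned state such as batch-norm running stats)
    def named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                yield name, v

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[f"buffer:{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {f"buffer:{n}": n for n, _ in self.named_buffers()}
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in buffers:
                self._set_buffer(buffers[name], value)
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj: object = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        getattr(obj, parts[-1])[...] = value


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_vocab: int, n_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_dim),
                                           size=(n_vocab, n_dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        idx = np.asarray(idx, dtype=np.intp)
        if idx.size and (idx.min() < 0 or idx.max() >= self.weight.shape[0]):
            raise ValueError("embedding index out of vocabulary range")
        return self.weight.gather(idx)


_ACTS = {
    "relu": Tensor.relu,
    "gelu": Tensor.gelu,
    "leaky_relu": Tensor.leaky_relu,
    "sigmoid": Tensor.sigmoid,
    "softplus": Tensor.softplus,
    "tanh": Tensor.tanh,
}


class MLP(Module):
    """Stack of Linear layers with a fixed activation between (not after) them."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "relu", final_activation: str | None = None,
                 final_bias: bool = True):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-2], sizes[1:-1])]
        self.layers.append(Linear(sizes[-2], sizes[-1], rng, bias=final_bias))
        self.activation = activation
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        act = _ACTS[self.activation]
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = act(x)
        if self.final_activation is not None:
            x = _ACTS[self.final_activation](x)
        return x


class BatchNorm(Module):
    """Feature-wise normalization over the first (atom/edge) axis.

    Training mode normalizes by the statistics of the current batch and
    updates running estimates. At inference the statistics are chosen by
    `eval_stats`: "batch" (default) normalizes by the current graph's own
    statistics — deterministic for a fixed input, and consistent with what
    the layers saw during training even when training batches are small —
    while "running" uses the tracked running estimates. Single-row inputs
    always fall back to the running estimates (a one-sample variance is
    degenerate).
    """

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, eval_stats: str = "batch"):
        super().__init__()
        if eval_stats not in ("batch", "running"):
            raise ValueError("eval_stats must be 'batch' or 'running'")
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.eval_stats = eval_stats

    def __call__(self, x: Tensor) -> Tensor:
        use_batch = x.shape[0] > 1 and (self.training
                                        or self.eval_stats == "batch")
        if use_batch:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            if self.training:
                self.running_mean *= 1.0 - self.momentum
                self.running_mean += self.momentum * mu.data.ravel()
                self.running_var *= 1.0 - self.momentum
                self.running_var += self.momentum * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta
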