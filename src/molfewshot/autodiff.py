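"""Compact reverse-mode automatic differentiation on NumPy arrays.

A tape-based engine in the micrograd tradition, sized for the needs of this
package: dense affine maps, ReLU networks, embedding lookups, and the
scatter/gather primitives of message passing on graphs (``gather_rows`` /
``segment_sum``). Gradients flow through a dynamically built DAG; calling
:meth:`Tensor.backward` on a scalar loss topologically sorts the tape and
accumulates ``grad`` on every tensor created with ``requires_grad=True``.

All arrays are float64 unless they hold integer codes; single-threaded NumPy
makes every computation bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "relu",
    "concatenate",
    "maximum",
    "log_softmax",
    "SGD",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=parents if req else (),
                      backward=backward if req else None)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g, out):
            return (g * p * self.data ** (p - 1),)

        return self._make(self.data ** p, (self,), bwd)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        def bwd(g, out):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self):
        def bwd(g, out):
            return (g.T,)

        return self._make(self.data.T, (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    # -- nonlinear elementwise ---------------------------------------------
    def exp(self):
        def bwd(g, out):
            return (g * out.data,)

        return self._make(np.exp(self.data), (self,), bwd)

    def log(self):
        def bwd(g, out):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        def bwd(g, out):
            return (g / (2.0 * out.data),)

        return self._make(np.sqrt(self.data), (self,), bwd)

    # -- indexing / graph primitives ---------------------------------------
    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Row lookup ``self[index]``; repeated indices accumulate gradient."""
        index = np.asarray(index, dtype=np.intp)

        def bwd(g, out):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            return (acc,)

        return self._make(self.data[index], (self,), bwd)

    def segment_sum(self, index: np.ndarray, n_segments: int) -> "Tensor":
        """Scatter-add rows of self into ``n_segments`` buckets by ``index``."""
        index = np.asarray(index, dtype=np.intp)
        out = np.zeros((n_segments,) + self.data.shape[1:])
        if self.data.size:
            np.add.at(out, index, self.data)

        def bwd(g, _out):
            return (g[index],)

        return self._make(out, (self,), bwd)

    # -- autodiff driver ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


# -- free functions ---------------------------------------------------------

def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)

    def bwd(g, out):
        return (g * mask,)

    return x._make(x.data * mask, (x,), bwd)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient routes to the first argument."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    take_a = (a.data >= b.data).astype(np.float64)

    def bwd(g, out):
        return (_unbroadcast(g * take_a, a.shape),
                _unbroadcast(g * (1.0 - take_a), b.shape))

    return a._make(np.maximum(a.data, b.data), (a, b), bwd)


def concatenate(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bwd(g, out):
        return tuple(np.split(g, splits, axis=axis))

    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate(datas, axis=axis), requires_grad=req,
                 parents=tuple(tensors) if req else (),
                 backward=bwd if req else None)
    return out


def log_softmax(logits: Tensor) -> Tensor:
    """Numerically stable row-wise log-softmax (last axis)."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out_data = z - lse

    def bwd(g, out):
        softmax = np.exp(out.data)
        return (g - softmax * g.sum(axis=-1, keepdims=True),)

    return logits._make(out_data, (logits,), bwd)


# -- optimizers -------------------------------------------------------------

class SGD:
    """Plain gradient descent over a name->Tensor parameter dict."""

    def __init__(self, params: dict, lr: float):
        self.params = params
        self.lr = float(lr)

    def step(self):
        for p in self.params.values():
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict | None = None):
        """Apply one update; `grads` overrides the tensors' own .grad."""
        self.t += 1
        for k, p in self.params.items():
            g = grads[k] if grads is not None else p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
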