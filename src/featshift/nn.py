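"""Minimal reverse-mode automatic differentiation and NN building blocks.

The trainable pieces of this package (classification head, low-rank adapters,
tiny transformer backbone) are small enough that a compact NumPy tape-based
autodiff is the whole story: a :class:`Tensor` wraps an ndarray, records its
parents, and :meth:`Tensor.backward` walks the tape in reverse topological
order.  Only the operations the package actually uses are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Linear", "LayerNorm", "Adam", "relu", "softmax",
           "dropout", "masked_cross_entropy"]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers --------------------------------------

    @staticmethod
    def _node(data, parents, backward):
        needs = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=needs, _parents=parents if needs else (),
                      _backward=backward if needs else None)

    def _accumulate(self, grad: np.ndarray) -> None:
        # reduce broadcast dimensions back to this tensor's shape
        while grad.ndim > self.data.ndim:
            grad = grad.sum(axis=0)
        for axis, size in enumerate(self.data.shape):
            if size == 1 and grad.shape[axis] != 1:
                grad = grad.sum(axis=axis, keepdims=True)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operations -------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor._node(out_data, (self, other), backward)

    def __mul__(self, scalar: float) -> "Tensor":
        scalar = float(scalar)
        out_data = self.data * scalar

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * scalar)

        return Tensor._node(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._node(out_data, (self, other), backward)

    def transpose(self) -> "Tensor":
        out_data = self.data.T

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return Tensor._node(out_data, (self,), backward)

    # -- backward pass ----------------------------------------------------

    def backward(self) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._node(out_data, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=-1, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._node(s, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out_data = x.data * keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor._node(out_data, (x,), backward)


def masked_cross_entropy(logits: Tensor, labels: np.ndarray, mask: np.ndarray,
                         class_weights: np.ndarray | None = None) -> Tensor:
    """Mean two-class cross-entropy over masked-in positions.

    ``logits`` is (L, 2); ``labels`` in {0, 1}; positions with ``mask == 0``
    contribute nothing to loss or gradient.  Optional ``class_weights`` (two
    reals) reweight positions by their true class; the loss is then the
    weighted mean over masked positions.
    """
    labels = np.asarray(labels, dtype=np.int64)
    mask = np.asarray(mask, dtype=float)
    if not mask.any():
        raise ValueError("all residues masked out; no loss to compute")
    if class_weights is not None:
        mask = mask * np.asarray(class_weights, dtype=float)[labels]
    denom = mask.sum()
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    picked = log_probs[np.arange(labels.size), labels]
    loss = -(picked * mask).sum() / denom

    def backward(g):
        if logits.requires_grad:
            probs = np.exp(log_probs)
            grad = probs.copy()
            grad[np.arange(labels.size), labels] -= 1.0
            grad *= (mask / denom)[:, None]
            logits._accumulate(g * grad)

    return Tensor._node(loss, (logits,), backward)


class LayerNorm:
    """Per-position layer normalisation over the feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out_data = xhat * self.gamma.data + self.beta.data
        d = x.data.shape[-1]

        def backward(g):
            if self.gamma.requires_grad:
                self.gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if self.beta.requires_grad:
                self.beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
            if x.requires_grad:
                gx = g * self.gamma.data
                x._accumulate(inv * (gx - gx.mean(axis=-1, keepdims=True)
                                     - xhat * (gx * xhat).mean(axis=-1, keepdims=True)))

        return Tensor._node(out_data, (x, self.gamma, self.beta), backward)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Linear:
    """Affine map ``y = x @ W + b`` with (d_in, d_out) weight storage."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        scale = scale if scale is not None else 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Tensor(np.zeros(d_out))
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def n_parameters(self) -> int:
        return self.W.data.size + self.b.data.size


class Adam:
    """Adam optimiser over an explicit parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
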