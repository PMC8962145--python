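"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery to train the sequence model in this package: tensors
carrying gradients, broadcast-aware elementwise arithmetic, batched matmul,
fused softmax / layer-norm / cross-entropy kernels, embedding lookup, and an
Adam optimizer.  Everything is float32 and CPU-only; determinism follows
from NumPy's.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An ndarray node in the backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._grad_fns = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, grad_fns) -> "Tensor":
        out = Tensor(data)
        tracked = [(p, f) for p, f in zip(parents, grad_fns) if p.requires_grad or p._parents]
        out._parents = tuple(p for p, _ in tracked)
        out._grad_fns = tuple(f for _, f in tracked)
        out.requires_grad = bool(tracked)
        return out

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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, grad_fn in zip(node._parents, node._grad_fns):
                contribution = np.asarray(grad_fn(node.grad), dtype=np.float32)
                if parent.grad is None:
                    if not (contribution.flags.owndata and contribution.flags.writeable):
                        contribution = contribution.copy()
                    parent.grad = contribution
                else:
                    parent.grad += contribution

    # -- elementwise --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (
                lambda g, s=self.data.shape: _unbroadcast(g, s),
                lambda g, s=other.data.shape: _unbroadcast(g, s),
            ),
        )

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (
                lambda g, o=other.data, s=self.data.shape: _unbroadcast(g * o, s),
                lambda g, a=self.data, s=other.data.shape: _unbroadcast(g * a, s),
            ),
        )

    def scale(self, c: float):
        return Tensor._make(self.data * c, (self,), (lambda g: g * c,))

    def sum(self):
        shape = self.data.shape
        return Tensor._make(
            np.float32(self.data.sum()), (self,), (lambda g: np.broadcast_to(g, shape),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), (lambda g: g * mask,))

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), (lambda g: g.reshape(old),)
        )

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes), (self,), (lambda g: g.transpose(*inverse),)
        )

    # -- contraction --------------------------------------------------------

    def matmul(self, other: "Tensor"):
        a, b = self.data, other.data
        return Tensor._make(
            a @ b,
            (self, other),
            (
                lambda g: _unbroadcast(g @ b.swapaxes(-1, -2), a.shape),
                lambda g: _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape),
            ),
        )

    def __matmul__(self, other):
        return self.matmul(other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# -- fused kernels ---------------------------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused affine map ``x @ w + b`` over the last axis of ``x``."""
    a = x.data

    def grad_x(g):
        return g @ w.data.T

    def grad_w(g):
        return a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])

    def grad_b(g):
        return g.reshape(-1, g.shape[-1]).sum(axis=0)

    return Tensor._make(a @ w.data + b.data, (x, w, b), (grad_x, grad_w, grad_b))


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""

    def grad_fn(g):
        d = np.zeros_like(table.data)
        np.add.at(d, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        return d

    return Tensor._make(table.data[ids], (table,), (grad_fn,))


def softmax_last(
    x: Tensor, additive_mask: np.ndarray | None = None, scale: float = 1.0
) -> Tensor:
    """Softmax of ``scale * x (+ mask)`` over the last axis."""
    z = x.data * scale if scale != 1.0 else x.data.copy()
    if additive_mask is not None:
        z += additive_mask
    z -= z.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    y = z

    def grad_fn(g):
        gy = g * y
        gy -= y * gy.sum(axis=-1, keepdims=True)
        if scale != 1.0:
            gy *= scale
        return gy

    return Tensor._make(y, (x,), (grad_fn,))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    n = x.data.shape[-1]

    def grad_x(g):
        gx = g * gamma.data
        return inv * (
            gx
            - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        )

    def grad_gamma(g):
        return _unbroadcast(g * xhat, gamma.data.shape)

    def grad_beta(g):
        return _unbroadcast(g, beta.data.shape)

    return Tensor._make(
        xhat * gamma.data + beta.data, (x, gamma, beta), (grad_x, grad_gamma, grad_beta)
    )


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.data.shape, dtype=np.float32) >= p
    keep = keep.astype(np.float32)
    keep /= 1.0 - p
    return Tensor._make(x.data * keep, (x,), (lambda g: g * keep,))


def cross_entropy_logits(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean masked token cross-entropy of ``logits`` (N, V) vs ``targets`` (N,).

    ``mask`` (N,) zeroes the padding positions; the mean is over unmasked
    tokens.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    n = np.arange(len(targets))
    nll = (logsumexp - z[n, targets]) * mask
    denom = max(mask.sum(), 1.0)
    loss = nll.sum() / denom

    def grad_fn(g):
        p = np.exp(z - logsumexp[:, None])
        p[n, targets] -= 1.0
        return g * p * (mask[:, None] / denom)

    return Tensor._make(np.float32(loss), (logits,), (grad_fn,))


# -- optimizer -------------------------------------------------------------


class Adam:
    """Adam with the transformer inverse-square-root warmup schedule.

    lr(step) = factor * width^-0.5 * min(step^-0.5, step * warmup^-1.5):
    linear increase up to ``warmup_steps`` (where it peaks), then decay
    proportional to step^-0.5.
    """

    def __init__(
        self,
        params: list[Tensor],
        model_width: int,
        warmup_steps: int,
        factor: float = 1.0,
        beta1: float = 0.9,
        beta2: float = 0.98,
        eps: float = 1e-9,
    ):
        self.params = params
        self.model_width = model_width
        self.warmup_steps = warmup_steps
        self.factor = factor
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step_num = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def learning_rate(self, step: int | None = None) -> float:
        step = self.step_num if step is None else step
        step = max(step, 1)
        return (
            self.factor
            * self.model_width ** -0.5
            * min(step ** -0.5, step * self.warmup_steps ** -1.5)
        )

    def step(self):
        self.step_num += 1
        lr = self.learning_rate()
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.step_num
        bias2 = 1.0 - b2 ** self.step_num
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
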