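"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model components in this package (transformer encoders, cross-attention
fusion, contrastive and cross-entropy losses) are small enough that a compact
tape-based engine over ``numpy.ndarray`` is sufficient: every operation builds
a node recording its parents and a closure that propagates the upstream
gradient.  All arithmetic is float64, which keeps analytic gradients close
enough to central finite differences for direct verification.

Only the operations the model needs are implemented: broadcasting arithmetic,
(batched) matmul, reshape/transpose/concatenate, slicing and integer-array
gather, reductions, elementwise nonlinearities, and a fused softmax along the
last axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "AdamW", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph.

    Parameters with ``requires_grad=True`` accumulate gradients in ``.grad``
    after :meth:`backward`.  Intermediate nodes are created by the operator
    methods below; constants can be plain arrays or scalars and are promoted
    on the fly.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _promote(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._promote(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._promote(other))

    def __rsub__(self, other):
        return self._promote(other) + (-self)

    def __mul__(self, other):
        other = self._promote(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._promote(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._promote(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, out):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._node(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._promote(other)

        def backward(g, out):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, out):
            return (g.reshape(old),)

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))

        def backward(g, out):
            return (g.transpose(inverse),)

        return self._node(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g, out):
            return (np.swapaxes(g, a, b),)

        return self._node(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, index):
        """Basic slicing or integer-array gather; duplicate indices accumulate."""

        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            return (full,)

        return self._node(self.data[index], (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, self.shape).copy(),)

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g, out):
            expanded = out.data if keepdims else np.expand_dims(out.data, axis)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            mask = self.data == expanded
            # ties share the gradient equally
            return (mask * g_exp / mask.sum(axis=axis, keepdims=True),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return self._node(out_data, (self,), lambda g, out: (g * out.data,))

    def log(self):
        return self._node(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._node(out_data, (self,), lambda g, out: (g * 0.5 / out.data,))

    def relu(self):
        mask = self.data > 0
        return self._node(self.data * mask, (self,), lambda g, out: (g * mask,))

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        return self._node(
            out_data, (self,), lambda g, out: (g * out.data * (1.0 - out.data),)
        )

    def softmax(self):
        """Row-wise softmax along the last axis, with max-subtraction."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        ex = np.exp(shifted)
        out_data = ex / ex.sum(axis=-1, keepdims=True)

        def backward(g, out):
            s = out.data
            return (s * (g - (g * s).sum(axis=-1, keepdims=True)),)

        return self._node(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep for many-layer models)
        order: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g, node)):
                if pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._promote(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied directly to the weights (not through the gradient), so the
    adaptive moments track only the data gradient.  Biases, embedding tables
    and normalization gains are typically registered with ``decay=False``.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 no_decay: set[str] | None = None):
        self.params = dict(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.no_decay = no_decay or set()
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * g
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * g * g
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            if self.weight_decay and name not in self.no_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def grad_check(loss_fn, params: dict[str, Tensor], eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    ``loss_fn`` must be a deterministic scalar function of ``params`` (called
    with no arguments; it closes over the tensors).  Used by the test suite to
    certify the engine and the full training objective.
    """
    for p in params.values():
        p.grad = None
    loss = loss_fn()
    loss.backward()
    analytic = {k: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data))
                for k, p in params.items()}

    worst = 0.0
    for name, p in params.items():
        flat = p.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(loss_fn().data)
            flat[i] = orig - eps
            lo = float(loss_fn().data)
            flat[i] = orig
            numeric = (hi - lo) / (2 * eps)
            ana = analytic[name].ravel()[i]
            scale = max(abs(numeric), abs(ana), 1.0)
            worst = max(worst, abs(numeric - ana) / scale)
    return worst
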