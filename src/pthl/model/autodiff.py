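"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Just enough tensor calculus to train the topological-sequence transformer:
broadcasting arithmetic, (batched) matmul, relu, fused softmax and
layer-norm standardization, reductions, reshapes and slicing. Gradients are
accumulated by topological-order backpropagation from a scalar loss.
Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None) -> None:
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- graph plumbing ---------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward
        return out

    # -- nonlinearities and fused ops --------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = backward
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        out._backward = backward
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - inner))

        out._backward = backward
        return out

    def standardize(self, axis: int = -1, eps: float = 1e-5) -> "Tensor":
        """(x - mean) / sqrt(var + eps) along ``axis`` (layer-norm core)."""
        mu = self.data.mean(axis=axis, keepdims=True)
        var = self.data.var(axis=axis, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = (self.data - mu) * inv
        out = Tensor(y, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                gm = g.mean(axis=axis, keepdims=True)
                gym = (g * y).mean(axis=axis, keepdims=True)
                self._accumulate(inv * (g - gm - y * gym))

        out._backward = backward
        return out

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(gg, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inverse))

        out._backward = backward
        return out

    def __getitem__(self, item) -> "Tensor":
        out = Tensor(self.data[item], _parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, item, g)
                self._accumulate(full)

        out._backward = backward
        return out

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    """Xavier-uniform parameter tensor."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        scale = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
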