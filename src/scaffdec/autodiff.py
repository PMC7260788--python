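"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the compute core for the recurrent generative models: a small set of
tensor operations (matmul, broadcast arithmetic, tanh/sigmoid, concatenation,
log-softmax, embedding lookup, attention contractions) with exact reverse-mode
gradients, plus an Adam optimizer. It is deliberately tiny — sequence models
at the scale this package trains (hidden sizes in the tens to low hundreds)
spend their time in NumPy BLAS calls, so no further machinery is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def visit(node):
            if id(node) in visited or not node.requires_grad:
                return
            visited.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ grad)

        return self._result(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * (1.0 - out_data ** 2))

        return self._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_data * (1.0 - out_data))

        return self._result(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(np.clip(self.data, -700, 700))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_data)

        return self._result(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        log_z = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - log_z

        def backward(grad):
            if self.requires_grad:
                softmax = np.exp(out_data)
                self._accumulate(grad - softmax * grad.sum(axis=axis, keepdims=True))

        return self._result(out_data, (self,), backward)

    # -- shaping -----------------------------------------------------------

    def narrow(self, axis: int, start: int, length: int):
        index = [slice(None)] * self.data.ndim
        index[axis] = slice(start, start + length)
        index = tuple(index)
        out_data = self.data[index]

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = grad
                self._accumulate(full)

        return self._result(out_data, (self,), backward)

    def reshape(self, *shape):
        old_shape = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(old_shape))

        return self._result(out_data, (self,), backward)

    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(grad):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.full_like(self.data, grad))
                else:
                    self._accumulate(np.broadcast_to(
                        np.expand_dims(grad, axis), self.data.shape).copy())

        return self._result(out_data, (self,), backward)

    # -- lookups / contractions -------------------------------------------

    def embed(self, indices):
        """Row lookup: self is (V, E), indices an int array (...,) -> (..., E)."""
        idx = np.asarray(indices, dtype=np.int64)
        out_data = self.data[idx]

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx.reshape(-1),
                          grad.reshape(-1, self.data.shape[1]))
                self._accumulate(full)

        return self._result(out_data, (self,), backward)

    def gather_rows(self, indices):
        """Pick one column per row: self (B, V), indices (B,) -> (B,)."""
        idx = np.asarray(indices, dtype=np.int64)
        rows = np.arange(self.data.shape[0])
        out_data = self.data[rows, idx]

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[rows, idx] = grad
                self._accumulate(full)

        return self._result(out_data, (self,), backward)

    def attn_scores(self, encoder_outs):
        """Dot products of a query against every encoder position.

        self: (B, H) decoder output; encoder_outs: (B, L, H) -> (B, L).
        """
        enc = self._coerce(encoder_outs)
        out_data = np.einsum("bh,blh->bl", self.data, enc.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(np.einsum("bl,blh->bh", grad, enc.data))
            if enc.requires_grad:
                enc._accumulate(np.einsum("bl,bh->blh", grad, self.data))

        return self._result(out_data, (self, enc), backward)

    def attn_context(self, encoder_outs):
        """Attention-weighted sum: self (B, L) weights, encoder (B, L, H) -> (B, H)."""
        enc = self._coerce(encoder_outs)
        out_data = np.einsum("bl,blh->bh", self.data, enc.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(np.einsum("bh,blh->bl", grad, enc.data))
            if enc.requires_grad:
                enc._accumulate(np.einsum("bl,bh->blh", self.data, grad))

        return self._result(out_data, (self, enc), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(grad):
        start = 0
        for t, size in zip(tensors, sizes):
            index = [slice(None)] * grad.ndim
            index[axis] = slice(start, start + size)
            if t.requires_grad:
                t._accumulate(grad[tuple(index)])
            start += size

    return Tensor._result(out_data, tensors, backward)


def stack(tensors, axis: int = 1) -> Tensor:
    """Stack (B, H) tensors into (B, L, H) (default) along a new axis."""
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(grad):
        parts = np.split(grad, len(tensors), axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(np.squeeze(part, axis=axis))

    return Tensor._result(out_data, tensors, backward)


class Adam:
    """Adam with the standard bias correction; operates on a parameter list."""

    def __init__(self, parameters, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.parameters = list(parameters)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.parameters]
        self._v = [np.zeros_like(p.data) for p in self.parameters]

    def zero_grad(self):
        for p in self.parameters:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.parameters):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g * g
            m_hat = self._m[i] / (1 - self.beta1 ** self.t)
            v_hat = self._v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
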