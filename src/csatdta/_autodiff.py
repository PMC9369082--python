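"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations the affinity network needs are provided: broadcasting
arithmetic, matrix multiplication, ReLU, softmax, axis reductions, 'same'
1-D convolution, embedding row gather and a gather-along-last-axis used by
relative-position logits.  Gradients accumulate in ``Tensor.grad`` after
``backward()`` on a scalar loss.  All data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_aliased")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_aliased = False

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # The first contribution aliases the caller's buffer; gradients of
        # completed nodes are never mutated afterwards, so this is safe and
        # avoids a zero-fill per graph node.  A second contribution forces
        # a fresh owned buffer.
        if self.grad is None:
            self.grad = grad
            self._grad_aliased = True
        elif self._grad_aliased:
            self.grad = self.grad + grad
            self._grad_aliased = False
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._node(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._node(self.data @ other.data, (self, other), bwd)

    # -- nonlinearities and reductions -------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - inner))

        return Tensor._node(s, (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, float(g)))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along one axis; ties send the gradient to the first hit."""
        out_data = self.data.max(axis=axis)
        argmax = self.data.argmax(axis=axis)

        def bwd(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            idx = list(np.indices(out_data.shape))
            idx.insert(axis if axis >= 0 else self.data.ndim + axis, argmax)
            np.add.at(grad, tuple(idx), g)
            self._accum(grad)

        return Tensor._node(out_data, (self,), bwd)

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), bwd)

    # -- structured ops ----------------------------------------------------

    def gather_rows(self, indices: np.ndarray):
        """Embedding lookup: self (V, E), indices (...,) -> (..., E)."""
        idx = np.asarray(indices)

        def bwd(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx.ravel(), g.reshape(-1, self.shape[1]))
                self._accum(grad)

        return Tensor._node(self.data[idx], (self,), bwd)

    def gather_last(self, indices: np.ndarray):
        """out[b, i, j] = self[b, i, indices[i, j]] for self (B, W, M)."""
        b, w, _ = self.shape
        bi = np.arange(b)[:, None, None]
        wi = np.arange(w)[None, :, None]
        idx = indices[None, :, :]

        def bwd(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, (bi, wi, idx), g)
                self._accum(grad)

        return Tensor._node(self.data[bi, wi, idx], (self,), bwd)

    def conv1d_same(self, kernel: "Tensor"):
        """'same'-padded 1-D convolution.

        self: (B, W, C_in); kernel: (k, C_in, C_out) -> (B, W, C_out).
        """
        k = kernel.shape[0]
        left = (k - 1) // 2
        right = k - 1 - left
        xp = np.pad(self.data, ((0, 0), (left, right), (0, 0)))
        b, w, _ = self.shape
        out_data = np.zeros((b, w, kernel.shape[2]))
        for t in range(k):
            out_data += xp[:, t : t + w] @ kernel.data[t]

        def bwd(g):
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for t in range(k):
                    gxp[:, t : t + w] += g @ kernel.data[t].T
                self._accum(gxp[:, left : left + w] if right else gxp[:, left:])
            if kernel.requires_grad:
                gk = np.zeros_like(kernel.data)
                for t in range(k):
                    gk[t] = np.einsum("bwi,bwo->io", xp[:, t : t + w], g)
                kernel._accum(gk)

        return Tensor._node(out_data, (self, kernel), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis."""
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )
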