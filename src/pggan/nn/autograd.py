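"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the 3D conditional GAN needs are provided: broadcasted
arithmetic, dense products, 3D strided (de)convolution, batch normalization,
the usual activations, concatenation/slicing and reductions.  Gradients are
accumulated by topological traversal of the recorded graph; everything is
deterministic given the inputs.
"""

from __future__ import annotations

import numpy as np

from . import conv as _conv

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple["Tensor", ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seed grad 1."""
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic --------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._result(a.data @ b.data, (a, b), backward)

    # -- shaping -----------------------------------------------------------

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._result(a.data.reshape(*shape), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accum(full)

        return Tensor._result(a.data[idx], (a,), backward)

    # -- activations & elementwise ----------------------------------------

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * np.where(mask, 1.0, slope))

        return Tensor._result(np.where(mask, a.data, slope * a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data**2))

        return Tensor._result(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * sign)

        return Tensor._result(np.abs(a.data), (a,), backward)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._result(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions --------------------------------------------------------

    def mean(self):
        a = self
        n = a.data.size

        def backward(g):
            if a.requires_grad:
                a._accum(np.full(a.data.shape, g / n, dtype=a.data.dtype))

        return Tensor._result(np.asarray(a.data.mean(), dtype=a.data.dtype), (a,), backward)

    def sum(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(np.full(a.data.shape, g, dtype=a.data.dtype))

        return Tensor._result(np.asarray(a.data.sum(), dtype=a.data.dtype), (a,), backward)

    # -- network primitives ------------------------------------------------

    def conv3d(self, w: "Tensor", b: "Tensor | None", stride: int) -> "Tensor":
        """Strided 3D convolution with 'same' padding (each axis -> ceil(n/s))."""
        x, weight = self, w
        y = _conv.conv3d_forward(x.data, weight.data, stride)
        if b is not None:
            y = y + b.data[None, :, None, None, None]
        parents = (x, weight) if b is None else (x, weight, b)

        def backward(g):
            if x.requires_grad:
                x._accum(_conv.conv3d_input_grad(g, weight.data, x.data.shape, stride))
            if weight.requires_grad:
                weight._accum(_conv.conv3d_weight_grad(x.data, g, weight.data.shape, stride))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))

        return Tensor._result(y, parents, backward)

    def conv_transpose3d(self, w: "Tensor", b: "Tensor | None", stride: int) -> "Tensor":
        """Transposed 3D convolution: each spatial axis -> n * stride.

        ``w`` has shape (in_channels, out_channels, k, k, k) and the layer is
        the exact adjoint of :meth:`conv3d` with the same stride.
        """
        x, weight = self, w
        n, cin = x.data.shape[:2]
        cout = weight.data.shape[1]
        out_spatial = tuple(s * stride for s in x.data.shape[2:])
        y = _conv.conv3d_input_grad(
            x.data, weight.data, (n, cout) + out_spatial, stride
        )
        if b is not None:
            y = y + b.data[None, :, None, None, None]
        parents = (x, weight) if b is None else (x, weight, b)

        def backward(g):
            if x.requires_grad:
                x._accum(_conv.conv3d_forward(g, weight.data, stride))
            if weight.requires_grad:
                weight._accum(_conv.conv3d_weight_grad(g, x.data, weight.data.shape, stride))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))

        return Tensor._result(y, parents, backward)

    def batch_norm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel batch normalization over (batch, spatial) axes.

        In training mode batch statistics normalize and the running buffers
        are updated in place; in eval mode the frozen running statistics are
        used.
        """
        x = self
        axes = (0,) + tuple(range(2, x.data.ndim))
        shape = (1, -1) + (1,) * (x.data.ndim - 2)
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mu, var = running_mean, running_var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(shape)) * inv_std.reshape(shape)
        y = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

        def backward(g):
            gs = gamma.data.reshape(shape)
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                gx = g * gs * inv_std.reshape(shape)
                if training:
                    dxhat = g * gs
                    t1 = dxhat.mean(axis=axes, keepdims=True)
                    t2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
                    gx = (dxhat - t1 - xhat * t2) * inv_std.reshape(shape)
                x._accum(gx)

        return Tensor._result(y, (x, gamma, beta), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each part."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(idx)])

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
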