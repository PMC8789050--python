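"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a capsule encoder feeding a variational Gaussian-process
head; all of it is expressed with the small set of differentiable primitives
defined here.  Tensors wrap ``float64`` numpy arrays and build a dynamic
computation graph; :meth:`Tensor.backward` runs reverse-mode accumulation
over a topological ordering of that graph.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.  Only the primitives the model needs are
provided — this is not a general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "cat", "conv1d", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over dims that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Accumulate gradients of `self` w.r.t. every graph leaf."""
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
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
            )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))
        out._backward = lambda: self._accum(
            out.grad * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw():
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            if a.ndim == 1:
                a2, g2 = a[None, :], np.expand_dims(g, -2)
                self._accum(_unbroadcast(g2 @ np.swapaxes(b, -1, -2), a2.shape)[0])
                other._accum(_unbroadcast(np.swapaxes(a2, -1, -2) @ g2, b.shape))
                return
            if b.ndim == 1:
                b2, g2 = b[:, None], np.expand_dims(g, -1)
                self._accum(_unbroadcast(g2 @ np.swapaxes(b2, -1, -2), a.shape))
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g2, b2.shape)[:, 0])
                return
            self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = _bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * 0.5 / out.data)
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), _prev=(self,))
        out._backward = lambda: self._accum(-out.grad * np.sin(self.data))
        return out

    def sin(self):
        out = Tensor(np.sin(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * np.cos(self.data))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        # numerically stable logistic
        s = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
            np.exp(np.clip(self.data, -500, 500))
            / (1.0 + np.exp(np.clip(self.data, -500, 500))),
        )
        out = Tensor(s, _prev=(self,))
        out._backward = lambda: self._accum(out.grad * out.data * (1.0 - out.data))
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), _prev=(self,))

        def _bw():
            sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
            self._accum(out.grad * sig)

        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))
        out._backward = lambda: self._accum(
            out.grad * np.where(self.data > 0, 1.0, slope)
        )
        return out

    # -- reductions and shape ops -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(self.data.swapaxes(a, b), _prev=(self,))
        out._backward = lambda: self._accum(out.grad.swapaxes(a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = _bw
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw():
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accum(g)

    out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 1-D convolution.

    x: (B, Cin, N); w: (Cout, Cin, K) with odd K; b: (Cout,).
    Returns (B, Cout, N).
    """
    B, Cin, N = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    if K % 2 == 0:
        raise ValueError("kernel width must be odd for 'same' padding")
    pad = K // 2
    xpad = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    res = np.zeros((B, Cout, N))
    for k in range(K):
        res += np.einsum("oc,bcn->bon", w.data[:, :, k], xpad[:, :, k : k + N])
    res += b.data[None, :, None]
    out = Tensor(res, _prev=(x, w, b))

    def _bw():
        g = out.grad
        gxpad = np.zeros_like(xpad)
        gw = np.zeros_like(w.data)
        for k in range(K):
            gxpad[:, :, k : k + N] += np.einsum("oc,bon->bcn", w.data[:, :, k], g)
            gw[:, :, k] = np.einsum("bon,bcn->oc", g, xpad[:, :, k : k + N])
        x._accum(gxpad[:, :, pad : pad + N])
        w._accum(gw)
        b._accum(g.sum(axis=(0, 2)))

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 2-D convolution.

    x: (B, Cin, H, W); w: (Cout, Cin, KH, KW) with odd KH, KW; b: (Cout,).
    Returns (B, Cout, H, W).
    """
    B, Cin, H, W_ = x.data.shape
    Cout, Cin_w, KH, KW = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    if KH % 2 == 0 or KW % 2 == 0:
        raise ValueError("kernel sizes must be odd for 'same' padding")
    ph, pw = KH // 2, KW // 2
    xpad = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    res = np.zeros((B, Cout, H, W_))
    for i in range(KH):
        for j in range(KW):
            res += np.einsum(
                "oc,bchw->bohw", w.data[:, :, i, j], xpad[:, :, i : i + H, j : j + W_]
            )
    res += b.data[None, :, None, None]
    out = Tensor(res, _prev=(x, w, b))

    def _bw():
        g = out.grad
        gxpad = np.zeros_like(xpad)
        gw = np.zeros_like(w.data)
        for i in range(KH):
            for j in range(KW):
                gxpad[:, :, i : i + H, j : j + W_] += np.einsum(
                    "oc,bohw->bchw", w.data[:, :, i, j], g
                )
                gw[:, :, i, j] = np.einsum(
                    "bohw,bchw->oc", g, xpad[:, :, i : i + H, j : j + W_]
                )
        x._accum(gxpad[:, :, ph : ph + H, pw : pw + W_])
        w._accum(gw)
        b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out
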