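"""Reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float64
``ndarray`` together with the nodes it was computed from and a
vector-Jacobian product (VJP) closure.  Every VJP is itself expressed in
terms of the primitives below, so calling :func:`grad` produces tensors
that are again differentiable.  That second-order capability is what the
Wasserstein gradient penalty needs: the penalty is a function of the
critic's *input* gradient, and training the critic requires
differentiating that gradient with respect to the critic's weights.

Only the primitives required by the connectivity-GAN stack are provided
(elementwise arithmetic, matmul, reductions, shape ops, the patch
gather/scatter pair behind convolutions, and a handful of activations).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "pow_", "exp", "log", "sqrt",
    "sigmoid", "softplus", "leaky_relu", "relu",
    "matmul", "sum_", "mean", "reshape", "transpose", "broadcast_to",
    "concat", "take_slice", "im2col", "col2im", "grad",
]


class Tensor:
    """A float64 array with optional provenance for backpropagation."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.vjp = vjp

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, float(p))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: tuple, vjp) -> Tensor:
    """Create an interior node; prune the graph when no parent needs grads."""
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjp=vjp)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcasted cotangent back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    axes = tuple(range(extra)) + tuple(
        i + extra for i, s in enumerate(shape) if s == 1 and g.shape[i + extra] != 1
    )
    out = sum_(g, axis=axes, keepdims=False) if axes else g
    return reshape(out, shape)


# elementwise ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(b))


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, pow_(b, -1.0))


def pow_(a: Tensor, p: float) -> Tensor:
    return _node(a.data ** p, (a,),
                 lambda g: (mul(g, mul(Tensor(np.float64(p)), pow_(a, p - 1.0))),))


def exp(a: Tensor) -> Tensor:
    out = _node(np.exp(a.data), (a,), None)
    out.vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    return pow_(a, 0.5)


def sigmoid(a: Tensor) -> Tensor:
    e = np.exp(-np.abs(a.data))
    s = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = _node(s, (a,), None)
    out.vjp = lambda g: (mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def softplus(a: Tensor) -> Tensor:
    # log(1 + e^x), computed stably; derivative is the logistic function
    return _node(np.logaddexp(0.0, a.data), (a,),
                 lambda g: (mul(g, sigmoid(a)),))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = Tensor(np.where(a.data > 0, 1.0, slope))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


# linear algebra and reductions --------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires tensors of rank >= 2")

    def vjp(g: Tensor):
        da = _unbroadcast(matmul(g, _swap_last(b)), a.shape)
        db = _unbroadcast(matmul(_swap_last(a), g), b.shape)
        return (da, db)

    return _node(np.matmul(a.data, b.data), (a, b), vjp)


def _swap_last(a: Tensor) -> Tensor:
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        axis_t = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axis_t = (axis % a.ndim,)
    else:
        axis_t = tuple(ax % a.ndim for ax in axis)

    def vjp(g: Tensor):
        if not keepdims:
            kshape = tuple(1 if i in axis_t else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return (broadcast_to(g, a.shape),)

    return _node(a.data.sum(axis=axis_t, keepdims=keepdims), (a,), vjp)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),))


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (_unbroadcast(g, a.shape),))


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g: Tensor):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = tuple(slice(None) if d != axis % g.ndim else slice(int(lo), int(hi))
                        for d in range(g.ndim))
            outs.append(take_slice(g, key))
        return tuple(outs)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def take_slice(a: Tensor, key: tuple) -> Tensor:
    return _node(a.data[key], (a,), lambda g: (_pad_slice(g, a.shape, key),))


def _pad_slice(g: Tensor, shape: tuple, key: tuple) -> Tensor:
    def fwd(data):
        out = np.zeros(shape)
        out[key] = data
        return out

    return _node(fwd(g.data), (g,), lambda c: (take_slice(c, key),))


# patch gather / scatter ----------------------------------------------
# im2col extracts all kernel-sized patches of a padded NCHW image as a
# (N, C*k*k, n_patches) matrix; col2im is its exact linear adjoint, so
# convolution and transposed convolution are matmuls around this pair.

def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def _im2col_data(x: np.ndarray, kernel: int, stride: int, padding: int) -> np.ndarray:
    n, c, h, w = x.shape
    ho = conv_out_size(h, kernel, stride, padding)
    wo = conv_out_size(w, kernel, stride, padding)
    if ho <= 0 or wo <= 0:
        raise ValueError(f"non-positive output size for input {h}x{w}, "
                         f"kernel={kernel}, stride={stride}, padding={padding}")
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N, C, Ho, Wo, k, k)
    win = win.transpose(0, 1, 4, 5, 2, 3)          # (N, C, k, k, Ho, Wo)
    return np.ascontiguousarray(win).reshape(n, c * kernel * kernel, ho * wo)


def _col2im_data(cols: np.ndarray, channels: int, hw: tuple, kernel: int,
                 stride: int, padding: int) -> np.ndarray:
    n = cols.shape[0]
    h, w = hw
    ho = conv_out_size(h, kernel, stride, padding)
    wo = conv_out_size(w, kernel, stride, padding)
    cols = cols.reshape(n, channels, kernel, kernel, ho, wo)
    out = np.zeros((n, channels, h + 2 * padding, w + 2 * padding))
    for i in range(kernel):
        for j in range(kernel):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if padding:
        out = out[:, :, padding:-padding or None, padding:-padding or None]
    return out


def im2col(a: Tensor, kernel: int, stride: int, padding: int) -> Tensor:
    if a.ndim != 4:
        raise ValueError("im2col expects an NCHW tensor")
    c, hw = a.shape[1], a.shape[2:]
    return _node(
        _im2col_data(a.data, kernel, stride, padding), (a,),
        lambda g: (col2im(g, c, hw, kernel, stride, padding),))


def col2im(a: Tensor, channels: int, hw: tuple, kernel: int, stride: int,
           padding: int) -> Tensor:
    return _node(
        _col2im_data(a.data, channels, hw, kernel, stride, padding), (a,),
        lambda g: (im2col(g, kernel, stride, padding),))


# backpropagation -----------------------------------------------------

def grad(output: Tensor, inputs: Iterable[Tensor],
         cotangent: Tensor | None = None) -> list[Tensor]:
    """Cotangents of ``output`` with respect to each tensor in ``inputs``.

    The returned tensors are themselves graph nodes, so they can be
    differentiated again (needed for the gradient penalty).  Inputs with
    no path to ``output`` receive a zero tensor of their shape.
    """
    inputs = list(inputs)
    if cotangent is None:
        cotangent = Tensor(np.ones(output.shape))

    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    cots: dict[int, Tensor] = {id(output): cotangent}
    for node in reversed(topo):
        g = cots.get(id(node))
        if g is None or node.vjp is None:
            continue
        for p, pg in zip(node.parents, node.vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            held = cots.get(id(p))
            cots[id(p)] = pg if held is None else add(held, pg)

    return [cots.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs]
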