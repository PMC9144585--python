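"""Reverse-mode tensor autodiff over NumPy.

A deliberately small engine covering exactly the operations the networks in
this package need: elementwise arithmetic, matmul, reshaping, zero padding,
``im2col``/``col2im`` (from which all convolutions are composed), 2x average
pooling / nearest-neighbour upsampling, LeakyReLU, tanh, exp/log/sqrt and
reductions.

Every vector-Jacobian product is itself expressed in these same primitives,
so gradients are ordinary graph nodes and gradients-of-gradients work.  That
property is what makes the WGAN-GP gradient penalty trainable: the penalty
is a function of ``d(critic)/d(input)``, and optimising it requires
differentiating through the backward pass.

All data is float32.  Tensors are created from parameters (leaves with
``requires_grad=True``) or from constants; ops propagate ``requires_grad``.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "grad", "no_grad"]

_f32 = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode): ops return constants."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_f32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _op(data, parents, vjp) -> "Tensor":
        t = Tensor.__new__(Tensor)
        t.data = data if data.dtype == _f32 else data.astype(_f32)
        t.requires_grad = _grad_enabled and any(p.requires_grad for p in parents)
        t.grad = None
        if t.requires_grad:
            t._parents = tuple(parents)
            t._vjp = vjp
        else:
            t._parents = ()
            t._vjp = None
        return t

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_scalar(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad_output: "Tensor | None" = None) -> None:
        """Accumulate gradients of this (scalar) tensor into leaf ``.grad``."""
        if grad_output is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad_output needs a scalar")
            grad_output = Tensor(np.ones_like(self.data))
        leaves = _backprop(self, grad_output, create_graph=False, wanted=None)
        for node, g in leaves:
            if node.grad is None:
                node.grad = g.data.copy()
            else:
                node.grad = node.grad + g.data
        # The graph is spent: break the vjp closures (some capture their own
        # output, a reference cycle the gc is slow to find under large
        # ndarray buffers) so memory is reclaimed by refcounting.
        for node in _topo_order(self):
            node._parents = ()
            node._vjp = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# backprop core
# ---------------------------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def _backprop(root: Tensor, grad_output: Tensor, create_graph: bool,
              wanted: set[int] | None):
    """Reverse sweep; frees each node's gradient as soon as it is consumed.

    ``wanted=None`` collects gradients of leaf tensors (parameters and
    explicit ``requires_grad`` inputs); otherwise gradients of the nodes
    whose ids are in ``wanted``.  Returns ``[(node, grad Tensor), ...]``.
    """
    order = _topo_order(root)
    gmap: dict[int, Tensor] = {id(root): grad_output}
    collected: list[tuple[Tensor, Tensor]] = []
    for node in reversed(order):
        g = gmap.pop(id(node), None)
        if g is None:
            continue
        if not create_graph:
            g = Tensor(g.data)
        if wanted is None:
            if node._vjp is None and node.requires_grad:
                collected.append((node, g))
        elif id(node) in wanted:
            collected.append((node, g))
        if node._vjp is None:
            continue
        if create_graph:
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                prev = gmap.get(id(p))
                gmap[id(p)] = pg if prev is None else add(prev, pg)
        else:
            # grads need no history of their own: evaluate vjps as constants
            with no_grad():
                parent_grads = node._vjp(g)
                for p, pg in zip(node._parents, parent_grads):
                    if pg is None or not p.requires_grad:
                        continue
                    prev = gmap.get(id(p))
                    gmap[id(p)] = pg if prev is None else add(prev, pg)
    return collected


def grad(output: Tensor, inputs: list[Tensor], create_graph: bool = False) -> list[Tensor]:
    """d(output)/d(input) for each input, without touching ``.grad`` fields.

    With ``create_graph=True`` the returned tensors stay connected to the
    graph, so expressions built from them can be differentiated again.
    """
    if output.data.size != 1:
        raise ValueError("grad() expects a scalar output")
    wanted = {id(t) for t in inputs}
    collected = _backprop(output, Tensor(np.ones_like(output.data)),
                          create_graph, wanted)
    by_id = {id(n): g for n, g in collected}
    return [by_id.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.data.shape == shape:
        return g
    ndiff = g.data.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, (a, b) in enumerate(zip(g.data.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._op(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._op(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(neg(g), b.data.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._op(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.data.shape), _unbroadcast(mul(g, a), b.data.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._op(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(div(g, b), a.data.shape),
            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor._op(-a.data, (a,), lambda g: (neg(g),))


def pow_scalar(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return Tensor._op(
        a.data ** _f32(p),
        (a,),
        lambda g: (mul(g, mul(Tensor(np.asarray(p, dtype=_f32)), pow_scalar(a, p - 1.0))),),
    )


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = Tensor._op(out_data, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor._op(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    out = Tensor._op(np.sqrt(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (div(mul(g, Tensor(np.asarray(0.5, dtype=_f32))), out),)
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor._op(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        one = Tensor(np.asarray(1.0, dtype=_f32))
        out._vjp = lambda g: (mul(g, sub(one, mul(out, out))),)
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(a.data >= 0, _f32(1.0), _f32(slope))
    return Tensor._op(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def clip_min(a: Tensor, lo: float) -> Tensor:
    """max(a, lo); gradient is zero where the clamp is active."""
    mask = (a.data > lo).astype(_f32)
    return Tensor._op(np.maximum(a.data, _f32(lo)), (a,), lambda g: (mul(g, Tensor(mask)),))


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    in_shape = a.data.shape

    def vjp(g):
        gg = g
        if axis is not None and not keepdims:
            kshape = list(in_shape)
            axes = (axis,) if isinstance(axis, int) else axis
            for ax in axes:
                kshape[ax] = 1
            gg = reshape(gg, tuple(kshape))
        elif axis is None and not keepdims:
            gg = reshape(gg, (1,) * len(in_shape))
        return (broadcast_to(gg, in_shape),)

    return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=_f32)))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return Tensor._op(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        lambda g: (_unbroadcast(g, a.data.shape),),
    )


def reshape(a: Tensor, shape: tuple) -> Tensor:
    in_shape = a.data.shape
    return Tensor._op(a.data.reshape(shape), (a,), lambda g: (reshape(g, in_shape),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    return Tensor._op(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor._op(
        a.data @ b.data,
        (a, b),
        lambda g: (matmul(g, transpose(b, (1, 0))), matmul(transpose(a, (1, 0)), g)),
    )


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        return tuple(
            narrow(g, axis, int(offsets[i]), sizes[i]) for i in range(len(tensors))
        )

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    before = start
    after = a.data.shape[axis] - start - length
    return Tensor._op(
        a.data[tuple(idx)].copy(),
        (a,),
        lambda g: (pad_zeros(g, axis, before, after),),
    )


def pad_zeros(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    pads = [(0, 0)] * a.data.ndim
    pads[axis] = (before, after)
    length = a.data.shape[axis]
    return Tensor._op(
        np.pad(a.data, pads),
        (a,),
        lambda g: (narrow(g, axis, before, length),),
    )


def pad_hw(a: Tensor, p: int) -> Tensor:
    """Zero-pad the last two (spatial) axes of an NCHW tensor by ``p``."""
    if p == 0:
        return a
    return pad_zeros(pad_zeros(a, a.data.ndim - 2, p, p), a.data.ndim - 1, p, p)


# ---------------------------------------------------------------------------
# convolution building blocks
# ---------------------------------------------------------------------------

def im2col(a: Tensor, k: int) -> Tensor:
    """(N,C,H,W) -> (N, OH*OW, C*k*k) for stride-1, valid convolution.

    Column layout is channel-major then kernel offset, i.e. index
    ``c*k*k + di*k + dj``.
    """
    n, c, h, w = a.data.shape
    oh, ow = h - k + 1, w - k + 1
    v = np.lib.stride_tricks.sliding_window_view(a.data, (k, k), axis=(2, 3))
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, oh * ow, c * k * k)
    return Tensor._op(cols, (a,), lambda g: (col2im(g, (n, c, h, w), k),))


def col2im(cols: Tensor, img_shape: tuple, k: int) -> Tensor:
    """Adjoint of :func:`im2col` — scatter-add columns back onto the image."""
    n, c, h, w = img_shape
    oh, ow = h - k + 1, w - k + 1
    colsr = cols.data.reshape(n, oh, ow, c, k, k)
    out = np.zeros((n, c, h, w), dtype=_f32)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + oh, j:j + ow] += colsr[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return Tensor._op(out, (cols,), lambda g: (im2col(g, k),))


def avg_pool2(a: Tensor) -> Tensor:
    n, c, h, w = a.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {h}x{w}")
    out = a.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    quarter = Tensor(np.asarray(0.25, dtype=_f32))
    return Tensor._op(out, (a,), lambda g: (mul(upsample2(g), quarter),))


def upsample2(a: Tensor) -> Tensor:
    out = np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3)
    four = Tensor(np.asarray(4.0, dtype=_f32))
    return Tensor._op(out, (a,), lambda g: (mul(avg_pool2(g), four),))


# ---------------------------------------------------------------------------
# composite ops (no custom vjp needed — built from primitives)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """Stride-1 2-D convolution; ``weight`` is (Cout, Cin, k, k)."""
    cout, cin, k, _ = weight.data.shape
    n = x.data.shape[0]
    xp = pad_hw(x, padding)
    h, w = xp.data.shape[2], xp.data.shape[3]
    oh, ow = h - k + 1, w - k + 1
    cols = im2col(xp, k)                                   # (N, OHW, Cin*k*k)
    cols2 = reshape(cols, (n * oh * ow, cin * k * k))
    w2 = transpose(reshape(weight, (cout, cin * k * k)), (1, 0))
    out = matmul(cols2, w2)                                # (N*OHW, Cout)
    out = transpose(reshape(out, (n, oh, ow, cout)), (0, 3, 1, 2))
    if bias is not None:
        out = add(out, reshape(bias, (1, cout, 1, 1)))
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """Per-channel 2-D convolution; ``weight`` is (C, k, k)."""
    c, k, _ = weight.data.shape
    n = x.data.shape[0]
    xp = pad_hw(x, padding)
    h, w = xp.data.shape[2], xp.data.shape[3]
    oh, ow = h - k + 1, w - k + 1
    cols = im2col(xp, k)                                   # (N, OHW, C*k*k)
    cols4 = reshape(cols, (n, oh * ow, c, k * k))
    wk = reshape(weight, (1, 1, c, k * k))
    out = tsum(mul(cols4, wk), axis=3)                     # (N, OHW, C)
    out = transpose(reshape(out, (n, oh, ow, c)), (0, 3, 1, 2))
    if bias is not None:
        out = add(out, reshape(bias, (1, c, 1, 1)))
    return out


def softmax(a: Tensor, axis: int) -> Tensor:
    shift = Tensor(a.data.max(axis=axis, keepdims=True))   # constant: exact for softmax
    e = exp(sub(a, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))


def log_softmax(a: Tensor, axis: int) -> Tensor:
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    z = sub(a, shift)
    return sub(z, log(tsum(exp(z), axis=axis, keepdims=True)))
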