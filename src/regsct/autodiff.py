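"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine providing exactly the operations the
translation model needs: elementwise arithmetic and activations, full
reductions, 2-D convolution and transposed convolution (im2col/col2im),
instance normalisation, reflection padding, channel concatenation, a
differentiable bilinear resampler with border clamping, and a squared
forward-difference penalty for displacement fields.

Tensors hold ``data`` (a numpy array, dtype preserved) and, after
``backward()``, ``grad`` of the same shape.  Gradients of every op are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.ndim != 0:
                raise ShapeError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological order (graphs can be deep: 9 residual blocks)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack.pop())
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0) if isinstance(other, Tensor) else -other)

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise -----------------------------------------------------------


def add(a, b):
    a = _as_tensor(a)
    if not isinstance(b, Tensor):
        data = a.data + b
        return _make(data, (a,), lambda g: (g,))
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(data, (a, b), backward)


def mul(a, b):
    a = _as_tensor(a)
    if not isinstance(b, Tensor):
        data = a.data * b
        return _make(data, (a,), lambda g: (g * b,))
    data = a.data * b.data

    def backward(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def absolute(a):
    a = _as_tensor(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), lambda g: (g * sign,))


def square(a):
    a = _as_tensor(a)
    return _make(a.data ** 2, (a,), lambda g: (g * (2.0 * a.data),))


def tanh(a):
    a = _as_tensor(a)
    t = np.tanh(a.data)
    return _make(t, (a,), lambda g: (g * (1.0 - t * t),))


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    return _make(a.data * mask, (a,), lambda g: (g * mask,))


def leaky_relu(a, negative_slope: float = 0.2):
    a = _as_tensor(a)
    mult = np.where(a.data > 0, 1.0, negative_slope).astype(a.dtype)
    return _make(a.data * mult, (a,), lambda g: (g * mult,))


# -- reductions ------------------------------------------------------------


def mean(a):
    a = _as_tensor(a)
    n = a.data.size
    return _make(np.asarray(a.data.mean(), dtype=a.dtype), (a,),
                 lambda g: (np.broadcast_to(g / n, a.data.shape).astype(a.dtype, copy=False),))


def total(a):
    a = _as_tensor(a)
    return _make(np.asarray(a.data.sum(), dtype=a.dtype), (a,),
                 lambda g: (np.broadcast_to(g, a.data.shape).astype(a.dtype, copy=False),))


# -- shape ops -------------------------------------------------------------


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (N, C, H, W) tensors along the channel axis."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape[0] != b.data.shape[0] or a.data.shape[2:] != b.data.shape[2:]:
        raise ShapeError(f"cannot concatenate shapes {a.data.shape} and {b.data.shape}")
    ca = a.data.shape[1]
    data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        return g[:, :ca], g[:, ca:]

    return _make(data, (a, b), backward)


def reflect_pad2d(a: Tensor, pad: int) -> Tensor:
    """Reflection-pad the two trailing axes of an (N, C, H, W) tensor."""
    a = _as_tensor(a)
    n, c, h, w = a.data.shape
    if pad >= h or pad >= w:
        raise ShapeError(f"reflection pad {pad} too large for spatial size {(h, w)}")
    ih = np.pad(np.arange(h), pad, mode="reflect")
    iw = np.pad(np.arange(w), pad, mode="reflect")
    data = a.data[:, :, ih[:, None], iw[None, :]]

    def backward(g):
        gx = np.zeros_like(a.data)
        np.add.at(
            gx,
            (np.arange(n)[:, None, None, None], np.arange(c)[None, :, None, None],
             ih[None, None, :, None], iw[None, None, None, :]),
            g,
        )
        return (gx,)

    return _make(data, (a,), backward)


# -- convolution -----------------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution; ``weight`` is (Cout, Cin, kh, kw), zero padding.

    Computed as a sum over kernel taps of (Cout, Cin) x (Cin, Ho*Wo)
    matmuls on shifted views — faster than im2col at batch size 1 and the
    channel counts used here, and the backward pass reuses the same views.
    """
    x = _as_tensor(x)
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ShapeError(f"conv2d expected {cin} input channels, got {x.data.shape[1]}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise ShapeError(f"input {x.data.shape[2:]} too small for {kh}x{kw} kernel")
    n = x.data.shape[0]
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    views = {}
    yf = np.zeros((n, cout, ho * wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xv = np.ascontiguousarray(
                xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]
            ).reshape(n, cin, ho * wo)
            views[i, j] = xv
            yf += np.matmul(weight.data[:, :, i, j], xv)
    data = yf.reshape(n, cout, ho, wo) + bias.data.reshape(1, -1, 1, 1)

    def backward(g):
        gf = np.ascontiguousarray(g).reshape(n, cout, ho * wo)
        gw = np.empty_like(weight.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xv = views[i, j]
                gw[:, :, i, j] = np.matmul(gf, xv.transpose(0, 2, 1)).sum(axis=0)
                gxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                    np.matmul(weight.data[:, :, i, j].T, gf).reshape(n, cin, ho, wo)
        gb = g.sum(axis=(0, 2, 3))
        gx = gxp[:, :, padding:xp.shape[2] - padding, padding:xp.shape[3] - padding] if padding else gxp
        return gx, gw, gb

    return _make(data, (x, weight, bias), backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 2,
                     padding: int = 1, output_padding: int = 1) -> Tensor:
    """Transposed 2-D convolution; ``weight`` is (Cin, Cout, kh, kw)."""
    x = _as_tensor(x)
    cin, cout, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ShapeError(f"conv_transpose2d expected {cin} input channels, got {x.data.shape[1]}")
    if output_padding > padding:
        raise ShapeError("output_padding must not exceed padding")
    n, _, h, w = x.data.shape
    hf = (h - 1) * stride + kh
    wf = (w - 1) * stride + kw
    ho = hf - 2 * padding + output_padding
    wo = wf - 2 * padding + output_padding
    xf = x.data.reshape(n, cin, h * w)
    full = np.zeros((n, cout, hf, wf), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            full[:, :, i:i + h * stride:stride, j:j + w * stride:stride] += \
                np.matmul(weight.data[:, :, i, j].T, xf).reshape(n, cout, h, w)
    data = full[:, :, padding:padding + ho, padding:padding + wo] + bias.data.reshape(1, -1, 1, 1)

    def backward(g):
        gfull = np.zeros((n, cout, hf, wf), dtype=g.dtype)
        gfull[:, :, padding:padding + ho, padding:padding + wo] = g
        gx = np.zeros((n, cin, h * w), dtype=g.dtype)
        gw = np.empty_like(weight.data)
        for i in range(kh):
            for j in range(kw):
                gv = np.ascontiguousarray(
                    gfull[:, :, i:i + h * stride:stride, j:j + w * stride:stride]
                ).reshape(n, cout, h * w)
                gx += np.matmul(weight.data[:, :, i, j], gv)
                gw[:, :, i, j] = np.matmul(xf, gv.transpose(0, 2, 1)).sum(axis=0)
        gb = g.sum(axis=(0, 2, 3))
        return gx.reshape(x.data.shape), gw, gb

    return _make(data, (x, weight, bias), backward)


# -- normalisation ---------------------------------------------------------


def instance_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes."""
    x = _as_tensor(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gdata = gamma.data.reshape(1, -1, 1, 1)
    data = xhat * gdata + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gdata
        m1 = gxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
        gx = inv * (gxhat - m1 - xhat * m2)
        return gx, ggamma, gbeta

    return _make(data, (x, gamma, beta), backward)


# -- resampling ------------------------------------------------------------


def grid_sample(img: Tensor, field: Tensor) -> Tensor:
    """Bilinear resampling: out(p) = img(p + field(p)), border-clamped.

    ``img`` is (N, C, H, W); ``field`` is (N, 2, H, W) holding per-pixel
    (row, col) displacements in pixel units.  Differentiable in both
    arguments; samples landing outside the grid are clamped to the edge,
    which zeroes the coordinate gradient there.
    """
    img, field = _as_tensor(img), _as_tensor(field)
    n, c, h, w = img.data.shape
    if field.data.shape != (n, 2, h, w):
        raise ShapeError(f"field shape {field.data.shape} does not match image {img.data.shape}")
    rows = np.arange(h, dtype=img.dtype)[None, :, None]
    cols = np.arange(w, dtype=img.dtype)[None, None, :]
    r = rows + field.data[:, 0]
    cc = cols + field.data[:, 1]
    in_r = (r > 0) & (r < h - 1)  # coordinate gradient mask (border clamp)
    in_c = (cc > 0) & (cc < w - 1)
    r = np.clip(r, 0, h - 1)
    cc = np.clip(cc, 0, w - 1)
    r0 = np.clip(np.floor(r), 0, h - 2).astype(np.int64)
    c0 = np.clip(np.floor(cc), 0, w - 2).astype(np.int64)
    tr = (r - r0).astype(img.dtype)
    tc = (cc - c0).astype(img.dtype)
    flat = img.data.reshape(n, c, h * w)
    i00 = (r0 * w + c0)[:, None]  # (n, 1, h, w) broadcast over channels
    i01 = i00 + 1
    i10 = i00 + w
    i11 = i10 + 1
    nn = np.arange(n)[:, None, None, None]
    v00 = np.take_along_axis(flat, i00.reshape(n, 1, -1), axis=2).reshape(n, c, h, w)
    v01 = np.take_along_axis(flat, i01.reshape(n, 1, -1), axis=2).reshape(n, c, h, w)
    v10 = np.take_along_axis(flat, i10.reshape(n, 1, -1), axis=2).reshape(n, c, h, w)
    v11 = np.take_along_axis(flat, i11.reshape(n, 1, -1), axis=2).reshape(n, c, h, w)
    trr = tr[:, None]
    tcc = tc[:, None]
    w00 = (1 - trr) * (1 - tcc)
    w01 = (1 - trr) * tcc
    w10 = trr * (1 - tcc)
    w11 = trr * tcc
    data = w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11

    def backward(g):
        gimg = None
        gfield = None
        if img.requires_grad or img._parents:
            gflat = np.zeros((n, c, h * w), dtype=g.dtype)
            cidx = np.arange(c)[None, :, None, None]
            for idx, wgt in ((i00, w00), (i01, w01), (i10, w10), (i11, w11)):
                np.add.at(gflat, (nn, cidx, np.broadcast_to(idx, (n, c, h, w))), g * wgt)
            gimg = gflat.reshape(img.data.shape)
        if field.requires_grad or field._parents:
            dr = (1 - tcc) * (v10 - v00) + tcc * (v11 - v01)
            dc = (1 - trr) * (v01 - v00) + trr * (v11 - v10)
            gr = (g * dr).sum(axis=1) * in_r
            gc = (g * dc).sum(axis=1) * in_c
            gfield = np.stack([gr, gc], axis=1)
        return gimg, gfield

    return _make(data, (img, field), backward)


# -- field regularisation --------------------------------------------------


def gradient_sq_penalty(field: Tensor) -> Tensor:
    """Sum over components and spatial directions of the mean squared
    forward difference of an (N, 2, H, W) displacement field.

    Normalised so a field whose component has unit slope scores exactly 1.
    """
    field = _as_tensor(field)
    f = field.data
    dr = f[:, :, 1:, :] - f[:, :, :-1, :]
    dc = f[:, :, :, 1:] - f[:, :, :, :-1]
    # mean over (batch, rows-1, cols) entries per component, summed over the
    # 2 components and 2 directions
    nr = dr[:, 0].size
    nc = dc[:, 0].size
    val = (dr ** 2).sum(axis=(0, 2, 3)) / nr + (dc ** 2).sum(axis=(0, 2, 3)) / nc
    data = np.asarray(val.sum(), dtype=f.dtype)

    def backward(g):
        gf = np.zeros_like(f)
        gdr = 2.0 * dr * (g / nr)
        gdc = 2.0 * dc * (g / nc)
        gf[:, :, 1:, :] += gdr
        gf[:, :, :-1, :] -= gdr
        gf[:, :, :, 1:] += gdc
        gf[:, :, :, :-1] -= gdc
        return (gf,)

    return _make(data, (field,), backward)
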