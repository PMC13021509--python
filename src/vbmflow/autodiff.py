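"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine powers every gradient-based component of the package: the 3D UNets,
the affine registration optimizer, the velocity-field distillation, and the
registration losses (which differentiate through scaling-and-squaring and
trilinear warping).  It is deliberately small: float32 tensors, a dynamic tape,
and only the operations the package needs.

Conventions
-----------
* Volumetric tensors are channel-first: ``(C, D, H, W)``.
* Sampling grids are ``(3, D, H, W)`` in normalized coordinates, where -1 and
  +1 lie at the *centers* of the first and last voxels of each axis.
"""
from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- elementwise arithmetic -----------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    return _node(a.data + b.data, (a, b), bw)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(g * b.data)
        if b.requires_grad:
            b._accum(g * a.data)

    return _node(a.data * b.data, (a, b), bw)


def power(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def bw(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), bw)


def _unary(a, fn, dfn):
    a = as_tensor(a)
    y = fn(a.data)

    def bw(g):
        a._accum(g * dfn(a.data, y))

    return _node(y, (a,), bw)


def exp(a):
    return _unary(a, np.exp, lambda x, y: y)


def log(a):
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def sqrt(a):
    return _unary(a, np.sqrt, lambda x, y: 0.5 / np.maximum(y, 1e-12))


def sin(a):
    return _unary(a, np.sin, lambda x, y: np.cos(x))


def cos(a):
    return _unary(a, np.cos, lambda x, y: -np.sin(x))


def sigmoid(a):
    return _unary(a, lambda x: 1.0 / (1.0 + np.exp(-x)), lambda x, y: y * (1.0 - y))


def tanh(a):
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def relu(a):
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(DTYPE))


def leaky_relu(a, slope: float = 0.01):
    return _unary(
        a,
        lambda x: np.where(x > 0, x, slope * x),
        lambda x, y: np.where(x > 0, 1.0, slope).astype(DTYPE),
    )


def absolute(a):
    return _unary(a, np.abs, lambda x, y: np.sign(x).astype(DTYPE))


# -- reductions and shape -------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))

    return _node(out_data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = as_tensor(a)

    def bw(g):
        a._accum(g.reshape(a.data.shape))

    return _node(a.data.reshape(shape), (a,), bw)


def getitem(a, idx):
    a = as_tensor(a)

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _node(a.data[idx], (a,), bw)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def flip(a, axis):
    a = as_tensor(a)

    def bw(g):
        a._accum(np.flip(g, axis=axis))

    return _node(np.flip(a.data, axis=axis).copy(), (a,), bw)


def matmul(a, b):
    """2D matrix product (used for small affine-parameter algebra)."""
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), bw)


def stack(tensors, axis=0):
    return concat([reshape(t, t.data.shape[:axis] + (1,) + t.data.shape[axis:])
                   for t in map(as_tensor, tensors)], axis=axis)


# -- convolution / pooling ------------------------------------------------

def conv3d(x, w, b=None):
    """Stride-1 'same' 3D convolution: x (Cin,D,H,W), w (Cout,Cin,k,k,k)."""
    x, w = as_tensor(x), as_tensor(w)
    k = w.data.shape[2]
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    out_data = np.tensordot(w.data, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[:, None, None, None]
        parents.append(b)

    def bw(g):
        if w.requires_grad:
            gw = np.tensordot(g, win, axes=([1, 2, 3], [1, 2, 3]))
            w._accum(gw)
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (p, p), (p, p), (p, p)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k, k), axis=(1, 2, 3))
            wf = w.data[:, :, ::-1, ::-1, ::-1]
            gx = np.tensordot(wf, gwin, axes=([0, 2, 3, 4], [0, 4, 5, 6]))
            x._accum(gx)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))

    return _node(out_data, tuple(parents), bw)


def avg_pool3d(x):
    """Factor-2 average pooling; spatial dims must be even."""
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    r = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    out_data = r.mean(axis=(2, 4, 6))

    def bw(g):
        gx = np.repeat(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2), 2, axis=3) / 8.0
        x._accum(gx)

    return _node(out_data, (x,), bw)


def upsample_nearest3d(x):
    """Factor-2 nearest-neighbor upsampling."""
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), 2, axis=3)

    def bw(g):
        c, d, h, w = x.data.shape
        gx = g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
        x._accum(gx)

    return _node(out_data, (x,), bw)


# -- trilinear grid sampling ----------------------------------------------

def grid_sample3d(img, grid, padding: str = "zeros"):
    """Sample ``img`` (C,D,H,W) at ``grid`` (3,D',H',W') normalized coords.

    padding='zeros' returns 0 outside the field of view; padding='border'
    clamps coordinates to the volume edge (used for deformation-field
    composition, where extrapolating the last value is the stable choice).
    """
    img, grid = as_tensor(img), as_tensor(grid)
    C = img.data.shape[0]
    dims = np.asarray(img.data.shape[1:], dtype=np.float64)
    out_shape = grid.data.shape[1:]
    g = grid.data.reshape(3, -1).astype(np.float64)
    # normalized [-1,1] -> voxel coordinates with +-1 at first/last centers
    f = (g + 1.0) * (dims[:, None] - 1.0) / 2.0
    if padding == "border":
        inside = [(f[ax] > 0.0) & (f[ax] < dims[ax] - 1.0) for ax in range(3)]
        f = np.clip(f, 0.0, (dims - 1.0)[:, None])
    elif padding != "zeros":
        raise ValueError(f"unknown padding mode {padding!r}")
    i0 = np.floor(f).astype(np.int64)
    frac = (f - i0).astype(DTYPE)
    n = f.shape[1]
    out = np.zeros((C, n), dtype=DTYPE)
    img_flat = img.data.reshape(C, -1)
    strides = np.array([dims[1] * dims[2], dims[2], 1.0]).astype(np.int64)

    corners = []  # cache for backward
    for a in range(2):
        for bb in range(2):
            for cc in range(2):
                off = np.array([a, bb, cc])
                idx = i0 + off[:, None]
                if padding == "zeros":
                    valid = np.all((idx >= 0) & (idx < dims[:, None]), axis=0)
                else:
                    valid = np.ones(n, dtype=bool)
                idxc = np.clip(idx, 0, (dims - 1)[:, None].astype(np.int64))
                lin = (idxc * strides[:, None]).sum(axis=0)
                wx = frac[0] if a else 1.0 - frac[0]
                wy = frac[1] if bb else 1.0 - frac[1]
                wz = frac[2] if cc else 1.0 - frac[2]
                wgt = (wx * wy * wz) * valid
                vals = img_flat[:, lin]
                out += wgt * vals
                corners.append((off, lin, valid, vals))
    out_data = out.reshape((C,) + out_shape)

    def bw(gout):
        gflat = gout.reshape(C, -1)
        if img.requires_grad:
            gimg = np.zeros((int(np.prod(dims)), C), dtype=DTYPE)
            for off, lin, valid, _ in corners:
                wx = frac[0] if off[0] else 1.0 - frac[0]
                wy = frac[1] if off[1] else 1.0 - frac[1]
                wz = frac[2] if off[2] else 1.0 - frac[2]
                wgt = (wx * wy * wz) * valid
                np.add.at(gimg, lin, (wgt * gflat).T)
            img._accum(gimg.T.reshape(img.data.shape))
        if grid.requires_grad:
            gf = np.zeros((3, n), dtype=DTYPE)
            for off, lin, valid, vals in corners:
                wx = frac[0] if off[0] else 1.0 - frac[0]
                wy = frac[1] if off[1] else 1.0 - frac[1]
                wz = frac[2] if off[2] else 1.0 - frac[2]
                sx = 1.0 if off[0] else -1.0
                sy = 1.0 if off[1] else -1.0
                sz = 1.0 if off[2] else -1.0
                dot = (vals * gflat).sum(axis=0) * valid
                gf[0] += sx * wy * wz * dot
                gf[1] += sy * wx * wz * dot
                gf[2] += sz * wx * wy * dot
            scale = ((dims - 1.0) / 2.0).astype(DTYPE)[:, None]
            if padding == "border":
                for ax in range(3):
                    gf[ax] *= inside[ax]
            grid._accum((gf * scale).reshape(grid.data.shape))

    return _node(out_data, (img, grid), bw)


# -- parameters and optimizer ---------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with optional per-step learning rate (for one-cycle schedules)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (lr * mh / (np.sqrt(vh) + self.eps)).astype(DTYPE)


def one_cycle_lr(step: int, total_steps: int, max_lr: float = 1e-3,
                 pct_start: float = 0.25, div_factor: float = 25.0,
                 final_div_factor: float = 1e4) -> float:
    """Cosine-annealed one-cycle learning rate: warm up to max_lr, anneal down."""
    if total_steps <= 1:
        return max_lr
    lo = max_lr / div_factor
    final = max_lr / final_div_factor
    warm = max(1, int(round(pct_start * total_steps)))
    if step < warm:
        t = step / warm
        return lo + (max_lr - lo) * (1 - np.cos(np.pi * t)) / 2
    t = (step - warm) / max(1, total_steps - warm)
    return final + (max_lr - final) * (1 + np.cos(np.pi * t)) / 2
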