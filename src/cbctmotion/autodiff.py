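"""Compact reverse-mode automatic differentiation on numpy arrays.

The package trains three coupled function approximators (a hash-encoded
implicit volume, a free-form-deformation B-spline basis and a convolutional
motion encoder) through a differentiable cone-beam projector and volume
warper.  All of these are expressed with the :class:`Tensor` type below,
which records an operation graph and back-propagates gradients with plain
numpy kernels.  Only the operations actually needed by the model are
implemented; every primitive has a finite-difference check in the test
suite.

Scatter-style gradients (trilinear sampling, hash-table lookups) use
``np.bincount`` on flattened indices, which is deterministic and orders of
magnitude faster than ``np.add.at``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self._grad_borrowed = False

    # -- graph mechanics ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        # first accumulation keeps a borrowed reference (never mutated in
        # place); later accumulations allocate a fresh sum once
        if self.grad is None:
            self.grad = grad if grad.dtype == DTYPE else grad.astype(DTYPE)
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + grad
            self._grad_borrowed = False
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out = Tensor(self.data + o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            o._accum(_unbroadcast(g, o.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        return self + (-o)

    def __rsub__(self, other):
        return Tensor(_as_array(other)) + (-self)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out = Tensor(self.data * o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            self._accum(_unbroadcast(g * o.data, self.data.shape))
            o._accum(_unbroadcast(g * self.data, o.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out = Tensor(self.data / o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            self._accum(_unbroadcast(g / o.data, self.data.shape))
            o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor(_as_array(other)) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out = Tensor(self.data @ o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            if self.requires_grad:
                if o.data.ndim == 1:
                    self._accum(np.outer(g, o.data) if self.data.ndim == 2
                                else g[..., None] * o.data)
                else:
                    self._accum(_unbroadcast(g @ o.data.swapaxes(-1, -2),
                                             self.data.shape))
            if o.requires_grad:
                if self.data.ndim == 1:
                    o._accum(np.outer(self.data, g))
                else:
                    o._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g,
                                          o.data.shape))
        out._backward = bw
        return out

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw
        return out

    # -- nonlinearities -----------------------------------------------------
    def sin(self):
        out = Tensor(np.sin(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * np.cos(self.data))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = Tensor(root, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / root)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bw
    return out


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup `table[idx]` with scatter-add gradient (hash-table access)."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], table.requires_grad, (table,))

    def bw(g):
        flat_idx = idx.ravel()
        gf = g.reshape(-1, table.data.shape[1])
        acc = np.zeros_like(table.data)
        for c in range(table.data.shape[1]):
            acc[:, c] = np.bincount(flat_idx, weights=gf[:, c],
                                    minlength=table.data.shape[0])
        table._accum(acc)
    out._backward = bw
    return out


def _corner_data(shape):
    # 8 corner offsets of a trilinear cell
    return np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)])


_CORNERS = _corner_data(None)


def grid_sample3(vol: Tensor, coords, coords_tensor: Tensor | None = None) -> Tensor:
    """Trilinear sampling of `vol` at fractional voxel coordinates.

    Parameters
    ----------
    vol : Tensor, shape (X, Y, Z) or (X, Y, Z, C)
        Values on the voxel grid.
    coords : ndarray, shape (N, 3)
        Sample positions in voxel units (0-based, node-centered).  Samples
        outside the grid contribute zero.
    coords_tensor : Tensor, optional
        When given, coords are taken from this Tensor's data and gradients
        are also propagated to the coordinates (needed for warping, where
        the displacement field is itself learnable).

    Returns Tensor of shape (N,) or (N, C).
    """
    from ._kernels import trilinear_coord_grad, trilinear_gather, \
        trilinear_scatter
    if coords_tensor is not None:
        coords = coords_tensor.data
    coords = np.ascontiguousarray(coords, dtype=DTYPE)
    squeeze = vol.data.ndim == 3
    vdata = vol.data[..., None] if squeeze else vol.data
    vdata = np.ascontiguousarray(vdata)
    X, Y, Z, C = vdata.shape

    vals = trilinear_gather(vdata, coords)
    out_data = vals[:, 0] if squeeze else vals
    parents = [vol] + ([coords_tensor] if coords_tensor is not None
                       and coords_tensor.requires_grad else [])
    out = Tensor(out_data, any(p.requires_grad for p in parents), tuple(parents))

    def bw(g):
        gm = np.ascontiguousarray(g[:, None] if squeeze else g)
        if vol.requires_grad:
            acc = trilinear_scatter(gm, coords, X, Y, Z)
            vol._accum(acc[..., 0] if squeeze else acc)
        if coords_tensor is not None and coords_tensor.requires_grad:
            coords_tensor._accum(trilinear_coord_grad(vdata, coords, gm))
    out._backward = bw
    return out


def bspline_apply(mats: tuple, coef: Tensor) -> Tensor:
    """Separable tensor-product B-spline evaluation.

    `mats` are three dense 1-D collocation matrices (nx, ncx), (ny, ncy),
    (nz, ncz); `coef` is the control-coefficient Tensor (ncx, ncy, ncz).
    Returns the field on the (nx, ny, nz) grid.  Linear in `coef`.
    """
    Bx, By, Bz = mats
    out_data = np.einsum("ai,bj,ck,ijk->abc", Bx, By, Bz, coef.data,
                         optimize=True)
    out = Tensor(out_data, coef.requires_grad, (coef,))

    def bw(g):
        coef._accum(np.einsum("ai,bj,ck,abc->ijk", Bx, By, Bz, g,
                              optimize=True))
    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2,
           pad: int = 1) -> Tensor:
    """3x3 2-D convolution via im2col.  x: (N, C, H, W), w: (Co, C, 3, 3)."""
    N, C, H, W = x.data.shape
    Co, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (N, C, Ho, Wo, kh, kw),
        (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]))
    cols = view.reshape(N, C, Ho * Wo, kh * kw).transpose(0, 2, 1, 3) \
               .reshape(N, Ho * Wo, C * kh * kw)
    wf = w.data.reshape(Co, C * kh * kw)
    out_data = (cols @ wf.T + b.data).transpose(0, 2, 1).reshape(N, Co, Ho, Wo)
    out = Tensor(out_data, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bw(g):
        gf = g.reshape(N, Co, Ho * Wo).transpose(0, 2, 1)       # (N, HoWo, Co)
        if b.requires_grad:
            b._accum(gf.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("npo,npk->ok", gf, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = gf @ wf                                      # (N, HoWo, CKK)
            gview = gcols.reshape(N, Ho * Wo, C, kh * kw) \
                         .transpose(0, 2, 1, 3).reshape(N, C, Ho, Wo, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + Ho * stride:stride,
                        j:j + Wo * stride:stride] += gview[:, :, :, :, i, j]
            x._accum(gxp[:, :, pad:pad + H, pad:pad + W])
    out._backward = bw
    return out


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Adaptive average pooling with torch-style bin edges."""
    N, C, H, W = x.data.shape
    oh, ow = out_hw
    hs = [(int(np.floor(i * H / oh)), max(int(np.ceil((i + 1) * H / oh)),
                                          int(np.floor(i * H / oh)) + 1))
          for i in range(oh)]
    ws = [(int(np.floor(j * W / ow)), max(int(np.ceil((j + 1) * W / ow)),
                                          int(np.floor(j * W / ow)) + 1))
          for j in range(ow)]
    out_data = np.empty((N, C, oh, ow), dtype=DTYPE)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    out = Tensor(out_data, x.requires_grad, (x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                gx[:, :, h0:h1, w0:w1] += (g[:, :, i, j] /
                                           ((h1 - h0) * (w1 - w0)))[:, :, None, None]
        x._accum(gx)
    out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    `running_mean`/`running_var` are plain arrays mutated in place during
    training and used verbatim at inference (deterministic eval mode).
    """
    N, C, H, W = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        m = N * H * W
        # momentum 1.0 pins the statistics to this batch exactly (used for
        # post-training recalibration), so no unbiased correction there
        unbiased = var if momentum == 1.0 else var * m / max(m - 1, 1)
        running_var *= (1 - momentum)
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    out = Tensor(out_data, x.requires_grad or gamma.requires_grad
                 or beta.requires_grad, (x, gamma, beta))

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                m = N * H * W
                sum_gi = gi.sum(axis=(0, 2, 3))
                sum_gix = (gi * xhat).sum(axis=(0, 2, 3))
                gx = (inv[None, :, None, None] / m) * (
                    m * gi - sum_gi[None, :, None, None]
                    - xhat * sum_gix[None, :, None, None])
            else:
                gx = gi * inv[None, :, None, None]
            x._accum(gx)
    out._backward = bw
    return out


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999) with per-group learning rates."""

    def __init__(self, groups: dict[str, list[Tensor]], lrs: dict[str, float],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.groups = groups
        self.lrs = dict(lrs)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state = {}
        self.t = 0
        for name, params in groups.items():
            for i, p in enumerate(params):
                self.state[(name, i)] = (np.zeros_like(p.data),
                                         np.zeros_like(p.data))

    def zero_grad(self):
        for params in self.groups.values():
            for p in params:
                p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, params in self.groups.items():
            lr = self.lrs.get(name, 0.0)
            if lr == 0.0:
                continue
            for i, p in enumerate(params):
                if p.grad is None:
                    continue
                m, v = self.state[(name, i)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
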