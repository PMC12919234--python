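"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the DCF models need: broadcasted arithmetic,
matrix products, common nonlinearities, reductions, reshaping/indexing,
concatenation, strided 2-D convolution (with its transposed counterpart for
the backward pass), nearest-neighbour upsampling, and a differentiable thin
QR factorization with a fixed sign convention.

Tensors carry float32 data by default; gradients accumulate in the dtype of
the forward data.  The graph is built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _as_array(x, dtype=np.float32):
    a = np.asarray(x)
    if a.dtype != dtype and np.issubdtype(a.dtype, np.floating):
        a = a.astype(dtype)
    elif not np.issubdtype(a.dtype, np.floating):
        a = a.astype(dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached backward function."""

    # Opt out of numpy ufunc dispatch so `ndarray op Tensor` falls back to
    # the reflected Tensor operators instead of elementwise object arrays.
    __array_ufunc__ = None

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data) if not isinstance(data, np.ndarray) else data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ meta
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
        # free the graph
        for t in topo:
            t._parents = ()
            t._backward = None

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad = self.grad + g

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(_as_array(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / (other.data ** 2))
            out._backward = back
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    if other.data.ndim == 1:
                        self._accum(np.outer(g, other.data) if self.data.ndim == 2
                                    else g[..., None] * other.data)
                    else:
                        self._accum(g @ other.data.swapaxes(-1, -2))
                if other.requires_grad:
                    if self.data.ndim == 1:
                        other._accum(np.outer(self.data, g))
                    else:
                        other._accum(self.data.swapaxes(-1, -2) @ g)
            out._backward = back
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / np.maximum(r, 1e-12))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (s + self.data * s * (1.0 - s)))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data).astype(self.data.dtype),
                     _parents=(self,))
        if out.requires_grad:
            s = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g: self._accum(g * s)
        return out

    def clip_norm(self, cap: float, axis=-1):
        """Rescale rows whose l2 norm along `axis` exceeds `cap` to norm `cap`.

        Differentiable: the scale factor min(1, cap/||f||) carries gradient
        through ||f|| on the capped rows.
        """
        norm = np.sqrt(np.sum(self.data ** 2, axis=axis, keepdims=True))
        capped = norm > cap
        scale = np.where(capped, cap / np.maximum(norm, 1e-12), 1.0)
        out = Tensor(self.data * scale, _parents=(self,))
        if out.requires_grad:
            def back(g):
                # d(out)/d(f) = scale*I + f * d(scale)/d(f);
                # on capped rows scale = cap/||f||, d(scale)/df = -cap f / ||f||^3
                gf = g * scale
                inner = np.sum(g * self.data, axis=axis, keepdims=True)
                corr = np.where(capped,
                                -cap * inner / np.maximum(norm, 1e-12) ** 3,
                                0.0)
                self._accum(gf + corr * self.data)
            out._backward = back
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        if out.requires_grad:
            def back(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes) if axes else self.data.T,
                     _parents=(self,))
        if out.requires_grad:
            if axes:
                inv = np.argsort(axes)
                out._backward = lambda g: self._accum(g.transpose(inv))
            else:
                out._backward = lambda g: self._accum(g.T)
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        if out.requires_grad:
            def back(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = back
        return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = back
    return out


# ----------------------------------------------------------------- conv ops

def _dilate(x: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=x.dtype)
    out[:, :, ::stride, ::stride] = x
    return out


def _corr2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Valid cross-correlation of x [N,C,H,W] with w [O,C,kh,kw]."""
    kh, kw = w.shape[2], w.shape[3]
    cols = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # cols: N,C,Ho,Wo,kh,kw
    out = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # N,Ho,Wo,O
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 2-D convolution (cross-correlation) with optional bias."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_d = _corr2d(xd, w.data, stride)
    if b is not None:
        out_d = out_d + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, _parents=parents)
    if out.requires_grad:
        kh, kw = w.data.shape[2], w.data.shape[3]

        def back(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                cols = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
                gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3]))  # O,C,kh,kw
                w._accum(gw)
            if x.requires_grad:
                gd = _dilate(g, stride)
                # pad so valid correlation with flipped kernel gives full grad
                ph, pw = kh - 1, kw - 1
                gd = np.pad(gd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                wf = w.data[:, :, ::-1, ::-1].swapaxes(0, 1)  # C,O,kh,kw
                gx = _corr2d(gd, wf, stride=1)
                # match padded-input size: trim, or zero-fill pixels no window reached
                H, W = xd.shape[2], xd.shape[3]
                gx = gx[:, :, :H, :W]
                dh, dw = H - gx.shape[2], W - gx.shape[3]
                if dh or dw:
                    gx = np.pad(gx, ((0, 0), (0, 0), (0, dh), (0, dw)))
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                x._accum(gx)
        out._backward = back
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of [N,C,H,W]."""
    d = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(d, _parents=(x,))
    if out.requires_grad:
        def back(g):
            n, c, h2, w2 = g.shape
            x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
        out._backward = back
    return out


# ------------------------------------------------------------------ thin QR

def qr_orthonormal(a: Tensor) -> Tensor:
    """Differentiable thin QR Q-factor with positive diagonal of R.

    The sign convention removes the per-column +/-1 ambiguity of plain QR so
    the factorization is a deterministic, smooth function of the input on the
    full-rank set.  Backward uses the standard thin-QR adjoint with the sign
    flips folded into (Q, R).
    """
    from scipy.linalg import solve_triangular

    ad = a.data.astype(np.float64)
    q, r = np.linalg.qr(ad, mode="reduced")
    diag = np.diagonal(r)
    if np.any(np.abs(diag) < 1e-10 * max(1.0, np.abs(r).max())):
        raise np.linalg.LinAlgError("rank-deficient matrix in qr_orthonormal")
    s = np.sign(diag)
    s[s == 0] = 1.0
    q = q * s[None, :]
    r = r * s[:, None]
    out = Tensor(q.astype(a.data.dtype), _parents=(a,))
    if out.requires_grad:
        def back(g):
            dq = np.asarray(g, dtype=np.float64)
            m = -dq.T @ q
            tri = np.tril(m) + np.tril(m, -1).T
            da = (dq + q @ tri)
            # right-multiply by R^{-T}: solve R X^T = da^T
            da = solve_triangular(r, da.T, lower=False).T
            a._accum(da.astype(a.data.dtype))
        out._backward = back
    return out
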