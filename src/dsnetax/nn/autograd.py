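"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the package's networks need: broadcasted
arithmetic, batched matmul, pointwise nonlinearities, reductions, shape
ops, 2-D convolution/pooling (im2col), embedding lookup and fused
softmax cross-entropy.  Gradients are accumulated by reverse topological
traversal of the recorded tape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference / statistics updates)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind == "f" else None)
        if self.data.dtype.kind not in "fiu":
            self.data = self.data.astype(np.float64)
        self.grad: Optional[np.ndarray] = None
        self._grad_owned = False
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff --------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar")
            grad = np.ones_like(self.data, dtype=np.float64)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution aliases the incoming array (no copy); a second
        # contribution allocates, so shared arrays are never mutated in place.
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                                   other.shape))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = backward
        return out

    # -- pointwise -------------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1 - t * t))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape -----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            fancy = any(
                isinstance(k, (np.ndarray, list)) for k in
                (key if isinstance(key, tuple) else (key,))
            )

            def backward(g):
                full = np.zeros_like(self.data, dtype=np.float64)
                if fancy:
                    np.add.at(full, key, g)  # duplicate indices must accumulate
                else:
                    full[key] += g
                self._accumulate(full)
            out._backward = backward
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
        out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tensors)
    if out.requires_grad:
        def backward(g):
            parts = np.moveaxis(g, axis, 0)
            for t, part in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(part)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- convolution / pooling -----------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(B,C,Hp,Wp) padded input -> (B,Ho,Wo,C,kh,kw) view."""
    B, C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]          # (B,C,Ho,Wo,kh,kw)
    return np.moveaxis(win, 1, 3), Ho, Wo  # (B,Ho,Wo,C,kh,kw)


def _col2im(dcols: np.ndarray, xshape, kh, kw, sh, sw, ph, pw) -> np.ndarray:
    """Scatter-add (B,Ho,Wo,C,kh,kw) gradients back to (B,C,H,W)."""
    B, C, H, W = xshape
    Ho, Wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=np.float64)
    d = np.moveaxis(dcols, 3, 1)  # (B,C,Ho,Wo,kh,kw)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += d[..., i, j]
    return dxp[:, :, ph:ph + H, pw:pw + W]


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: tuple[int, int] = (1, 1),
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """2-D cross-correlation: x (B,Cin,H,W), w (Cout,Cin,kh,kw) -> (B,Cout,Ho,Wo)."""
    sh, sw = stride
    ph, pw = padding
    Cout, Cin, kh, kw = w.shape
    if kh == 1 and kw == 1 and ph == 0 and pw == 0:
        return _conv2d_1x1(x, w, b, sh, sw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols, Ho, Wo = _im2col(xp, kh, kw, sh, sw)           # (B,Ho,Wo,Cin,kh,kw)
    cols2 = cols.reshape(*cols.shape[:3], -1)            # (B,Ho,Wo,Cin*kh*kw)
    wf = w.data.reshape(Cout, -1)                        # (Cout, Cin*kh*kw)
    out_data = np.einsum("bhwk,ck->bchw", cols2, wf, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data,
                 requires_grad=any(p.requires_grad for p in parents),
                 parents=parents)
    if out.requires_grad:
        cols2_saved = cols2  # xp is local and never mutated, views are safe

        def backward(g):
            if w.requires_grad:
                dwf = np.einsum("bchw,bhwk->ck", g, cols2_saved, optimize=True)
                w._accumulate(dwf.reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols2 = np.einsum("bchw,ck->bhwk", g, wf, optimize=True)
                dcols = dcols2.reshape(g.shape[0], Ho, Wo, Cin, kh, kw)
                x._accumulate(_col2im(dcols, x.shape, kh, kw, sh, sw, ph, pw))
        out._backward = backward
    return out


def _conv2d_1x1(x: Tensor, w: Tensor, b: Optional[Tensor], sh: int, sw: int) -> Tensor:
    """Pointwise convolution: a channel mixing matmul, no im2col."""
    xs = x.data[:, :, ::sh, ::sw]
    wf = w.data[:, :, 0, 0]  # (Cout, Cin)
    out_data = np.einsum("oc,bchw->bohw", wf, xs, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents),
                 parents=parents)
    if out.requires_grad:
        def backward(g):
            if w.requires_grad:
                dw = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
                w._accumulate(dw[:, :, None, None])
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxs = np.einsum("oc,bohw->bchw", wf, g, optimize=True)
                if sh == 1 and sw == 1:
                    x._accumulate(dxs)
                else:
                    dx = np.zeros_like(x.data, dtype=np.float64)
                    dx[:, :, ::sh, ::sw] = dxs
                    x._accumulate(dx)
        out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: tuple[int, int] = (3, 3),
               stride: tuple[int, int] = (2, 2),
               padding: tuple[int, int] = (1, 1)) -> Tensor:
    kh, kw = kernel
    sh, sw = stride
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                constant_values=-np.inf)
    win, Ho, Wo = _im2col(xp, kh, kw, sh, sw)            # (B,Ho,Wo,C,kh,kw)
    win = np.moveaxis(win, 3, 1)                         # (B,C,Ho,Wo,kh,kw)
    flat = win.reshape(*win.shape[:4], -1)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, requires_grad=x.requires_grad, parents=(x,))
    if out.requires_grad:
        def backward(g):
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
            dwin = dflat.reshape(win.shape)              # (B,C,Ho,Wo,kh,kw)
            dcols = np.moveaxis(dwin, 1, 3)              # (B,Ho,Wo,C,kh,kw)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, sh, sw, ph, pw))
        out._backward = backward
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
                mean: np.ndarray | None = None, var: np.ndarray | None = None):
    """Fused channel normalization over (batch, H, W).

    With ``mean``/``var`` given (inference), they are treated as constants;
    otherwise batch statistics are used and returned for running-stat
    updates.  Returns ``(out, mu, v)``.
    """
    axes = (0, 2, 3)
    if mean is None:
        mu = x.data.mean(axis=axes, keepdims=True)
        v = x.data.var(axis=axes, keepdims=True)
        batch_stats = True
    else:
        mu, v = mean, var
        batch_stats = False
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - mu) * inv_std
    out = Tensor(gamma.data * xhat + beta.data,
                 requires_grad=x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 parents=(x, gamma, beta))
    if out.requires_grad:
        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes, keepdims=True))
            if x.requires_grad:
                scale = gamma.data * inv_std
                if batch_stats:
                    gm = g.mean(axis=axes, keepdims=True)
                    gx = (g * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate(scale * (g - gm - xhat * gx))
                else:
                    x._accumulate(scale * g)
        out._backward = backward
    return out, mu, v


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup table[ids]; gradient scatter-adds into the table."""
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(table.data[ids], requires_grad=table.requires_grad, parents=(table,))
    if out.requires_grad:
        def backward(g):
            full = np.zeros_like(table.data)
            np.add.at(full, ids, g)
            table._accumulate(full)
        out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows; fused, numerically stable."""
    targets = np.asarray(targets, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = targets.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), targets], 1e-300, None))
    out = Tensor(nll.mean(), requires_grad=logits.requires_grad, parents=(logits,))
    if out.requires_grad:
        def backward(g):
            d = p.copy()
            d[np.arange(n), targets] -= 1.0
            logits._accumulate(g * d / n)
        out._backward = backward
    return out
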