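"""Compact reverse-mode automatic differentiation on numpy arrays.

The segmentation model in this package is small (a depthwise-separable
encoder plus a light U-Net decoder), so rather than depending on a full
deep-learning framework the package carries a minimal tape-based autodiff
engine: a :class:`Tensor` wrapping a float32 ndarray, elementwise and
reduction primitives with broadcasting-aware gradients, and fused layer
operations (conv2d, depthwise conv2d, batch norm, bilinear resize) whose
backward passes are written by hand for speed.  Everything runs on one CPU
thread and is deterministic for a fixed parameter state and RNG.

Shapes follow the NCHW convention throughout this module.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "SGD",
    "Adam",
    "concat",
    "softmax_channel",
    "im2col_conv2d",
    "depthwise_conv2d_raw",
]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- tape machinery -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=_DTYPE)
        if self.grad is None:
            # always copy: the same array object may be handed to two parents
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- transcendental / clipping -------------------------------------------
    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def relu6(self):
        out_data = np.clip(self.data, 0.0, 6.0)
        mask = (self.data > 0) & (self.data < 6.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax_channel(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along `axis` with a fused backward."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            x._accum(p * (g - dot))

    return Tensor._make(p, (x,), backward)


# ---------------------------------------------------------------------------
# Convolution primitives (shared by the autodiff layers and by the plain
# numpy functional operators exposed in histoseg.network)
# ---------------------------------------------------------------------------

def _conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col_view(xp: np.ndarray, kh: int, kw: int, stride: int):
    """Strided (N, C, kh, kw, Ho, Wo) window view of a padded NCHW array."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )


def _pad_nchw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add (N, C, kh, kw, Ho, Wo) patch gradients back to NCHW."""
    n, c, h, w = x_shape
    ho, wo = cols.shape[-2:]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


def im2col_conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Plain-numpy full convolution: x (N,C,H,W), w (K,C,kh,kw) -> (N,K,Ho,Wo)."""
    k, c, kh, kw = w.shape
    view = _im2col_view(_pad_nchw(x, pad), kh, kw, stride)
    n, _, _, _, ho, wo = view.shape
    cols = np.ascontiguousarray(view).reshape(n, c * kh * kw, ho * wo)
    out = np.matmul(w.reshape(k, c * kh * kw), cols)
    return out.reshape(n, k, ho, wo)


def depthwise_conv2d_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Plain-numpy per-channel convolution: x (N,C,H,W), w (C,kh,kw)."""
    c, kh, kw = w.shape
    view = _im2col_view(_pad_nchw(x, pad), kh, kw, stride)
    return np.einsum("ncijhw,cij->nchw", view, w, optimize=True)


def conv2d(x: Tensor, w: Parameter, b: Parameter | None, stride: int, pad: int) -> Tensor:
    """Autodiff full convolution (NCHW / KCkk weights)."""
    k, c, kh, kw = w.data.shape
    xp = _pad_nchw(x.data, pad)
    view = _im2col_view(xp, kh, kw, stride)
    n, _, _, _, ho, wo = view.shape
    cols = np.ascontiguousarray(view).reshape(n, c * kh * kw, ho * wo)
    out = np.matmul(w.data.reshape(k, -1), cols).reshape(n, k, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, k, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = g.reshape(n, k, ho * wo)
        if w.requires_grad:
            dw = np.einsum("nkl,ncl->kc", gf, cols, optimize=True)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w.data.reshape(k, -1).T, gf)
            dcols = dcols.reshape(n, c, kh, kw, ho, wo)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Parameter, stride: int, pad: int) -> Tensor:
    """Autodiff depthwise convolution; w has shape (C, kh, kw)."""
    c, kh, kw = w.data.shape
    view = _im2col_view(_pad_nchw(x.data, pad), kh, kw, stride)
    out = np.einsum("ncijhw,cij->nchw", view, w.data, optimize=True)

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("nchw,ncijhw->cij", g, view, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("nchw,cij->ncijhw", g, w.data, optimize=True)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor._make(out, (x, w), backward)


def _bilinear_axis_weights(n_out: int, n_in: int):
    """Half-pixel-centre source indices and fractional weights for one axis."""
    coords = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.floor(coords).astype(np.int64)
    frac = (coords - i0).astype(_DTYPE)
    i0 = np.clip(i0, 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    return i0, i1, frac


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Autodiff bilinear resize (half-pixel centres, replicate edges)."""
    n, c, h, w = x.data.shape
    r0, r1, fr = _bilinear_axis_weights(out_h, h)
    c0, c1, fc = _bilinear_axis_weights(out_w, w)
    fr_ = fr[:, None]
    fc_ = fc[None, :]
    top = x.data[:, :, r0, :] * (1 - fr_)[None, None] + x.data[:, :, r1, :] * fr_[None, None]
    out = top[:, :, :, c0] * (1 - fc_)[None, None] + top[:, :, :, c1] * fc_[None, None]

    def backward(g):
        if not x.requires_grad:
            return
        gtop = np.zeros((n, c, out_h, w), dtype=_DTYPE)
        np.add.at(gtop, (slice(None), slice(None), slice(None), c0), g * (1 - fc_)[None, None])
        np.add.at(gtop, (slice(None), slice(None), slice(None), c1), g * fc_[None, None])
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)), gtop * (1 - fr_)[None, None, :, :])
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)), gtop * fr_[None, None, :, :])
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter):
                    yield v

    def named_state(self, prefix=""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v.data
            elif isinstance(v, Module):
                yield from v.named_state(prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_state(prefix=f"{key}.{i}.")
            elif isinstance(v, np.ndarray):  # running statistics
                yield key, v

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.named_state()}

    def load_state_dict(self, state: dict) -> None:
        targets = dict(self._state_slots())
        missing = set(state) ^ set(targets)
        if missing:
            raise ValueError(f"state mismatch on keys: {sorted(missing)}")
        for key, arr in state.items():
            holder, attr = targets[key]
            current = getattr(holder, attr)
            if isinstance(current, Parameter):
                current.data = np.asarray(arr, dtype=_DTYPE).copy()
            else:
                setattr(holder, attr, np.asarray(arr, dtype=_DTYPE).copy())

    def _state_slots(self, prefix=""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter) or isinstance(v, np.ndarray):
                yield key, (self, name)
            elif isinstance(v, Module):
                yield from v._state_slots(prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._state_slots(prefix=f"{key}.{i}.")

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, channels, kernel=3, stride=1, pad=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, (channels, kernel, kernel)))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.stride, self.pad)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running stats."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.eps, self.momentum = eps, momentum

    def __call__(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        if self.training:
            axes = (0, 2, 3)
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_DTYPE)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
            out = self.gamma.data.reshape(1, c, 1, 1) * xhat + self.beta.data.reshape(1, c, 1, 1)
            gamma, x_ref = self.gamma, x
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

            def backward(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat).sum(axis=axes))
                if self.beta.requires_grad:
                    self.beta._accum(g.sum(axis=axes))
                if x_ref.requires_grad:
                    gsum = g.sum(axis=axes, keepdims=True)
                    gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
                    dx = (
                        gamma.data.reshape(1, c, 1, 1)
                        * inv_std.reshape(1, c, 1, 1)
                        * (g - gsum / m - xhat * gx_sum / m)
                    )
                    x_ref._accum(dx)

            return Tensor._make(out, (x, self.gamma, self.beta), backward)
        # evaluation mode: a fixed affine map
        scale = (self.gamma.data / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
        shift = (self.beta.data - self.running_mean * scale.ravel()).reshape(1, c, 1, 1)
        return x * Tensor(scale) + Tensor(shift)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(_DTYPE) / keep
        return x * Tensor(mask)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (self.lr * v).astype(_DTYPE)


class Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(_DTYPE)
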