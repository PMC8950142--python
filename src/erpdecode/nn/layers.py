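"""Minimal NumPy layer library for small EEG convolutional networks.

Tensors are laid out as ``(batch, feature_maps, height, width)`` in float32;
for EEG trials the height axis carries electrodes and the width axis carries
time samples.  Every layer implements ``forward(x, train)`` and
``backward(grad)`` and exposes its trainable parameters as :class:`Param`
objects, which carry optional max-norm constraints and L1/L2 penalties.

Only stride-1 convolutions are provided; the architectures served by this
engine downsample exclusively through pooling.  Temporal convolutions switch
to an FFT path for long kernels (EEG temporal filters can span hundreds of
samples) and to a windowed-matmul path for short ones.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import irfft, next_fast_len, rfft

_F32 = np.float32

# kernels at least this long go through the FFT path
_FFT_KERNEL_MIN = 32


class Param:
    """A trainable array plus its gradient and training-time attributes.

    ``maxnorm`` (with ``maxnorm_axes``) rescales the tensor after each
    optimizer step so the L2 norm over the given axes does not exceed the
    bound — the Keras-style max-norm kernel constraint.  ``l1``/``l2`` are
    penalty coefficients added to the loss by the trainer.
    """

    __slots__ = ("val", "grad", "maxnorm", "maxnorm_axes", "l1", "l2", "name")

    def __init__(self, val, name="", maxnorm=None, maxnorm_axes=None, l1=0.0, l2=0.0):
        self.val = np.asarray(val, dtype=_F32)
        self.grad = np.zeros_like(self.val)
        self.name = name
        self.maxnorm = maxnorm
        self.maxnorm_axes = maxnorm_axes
        self.l1 = float(l1)
        self.l2 = float(l2)

    def apply_constraint(self):
        if self.maxnorm is None:
            return
        norms = np.sqrt(np.sum(self.val ** 2, axis=self.maxnorm_axes, keepdims=True))
        scale = np.minimum(1.0, self.maxnorm / np.maximum(norms, 1e-12))
        self.val *= scale.astype(_F32)

    def penalty(self):
        p = 0.0
        if self.l1:
            p += self.l1 * float(np.sum(np.abs(self.val)))
        if self.l2:
            p += self.l2 * float(np.sum(self.val ** 2))
        return p

    def penalty_grad(self):
        g = 0.0
        if self.l1:
            g = g + self.l1 * np.sign(self.val)
        if self.l2:
            g = g + 2.0 * self.l2 * self.val
        return g


def glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


# ---------------------------------------------------------------------------
# temporal cross-correlation primitives (stride 1, along the last axis)
# ---------------------------------------------------------------------------

def _corr_valid_win(x, w):
    """Valid cross-correlation via sliding windows.

    x: (b, i, h, W); w: (o, i, k)  ->  (b, o, h, W-k+1)
    """
    k = w.shape[-1]
    v = sliding_window_view(x, k, axis=-1)          # (b,i,h,W',k)
    return np.einsum("bihwk,oik->bohw", v, w, optimize=True)


def _corr_valid_fft(x, w):
    """Same contract as :func:`_corr_valid_win` but through the FFT."""
    b, i, h, W = x.shape
    o, _, k = w.shape
    n = next_fast_len(W + k - 1)
    Xf = rfft(x, n=n, axis=-1)
    # correlation = convolution with the reversed kernel
    Wf = rfft(w[..., ::-1], n=n, axis=-1)
    Yf = np.einsum("bihf,oif->bohf", Xf, Wf, optimize=True)
    full = irfft(Yf, n=n, axis=-1)
    return np.ascontiguousarray(full[..., k - 1 : W], dtype=_F32)


def corr_valid(x, w):
    if w.shape[-1] >= _FFT_KERNEL_MIN:
        return _corr_valid_fft(x, w)
    return _corr_valid_win(x, w).astype(_F32, copy=False)


def _corr_grad_w(x, g, k):
    """Gradient of ``corr_valid`` w.r.t. the kernel.

    x: (b,i,h,W); g: (b,o,h,W') with W' = W-k+1  ->  (o,i,k)
    """
    Wp = g.shape[-1]
    if k >= _FFT_KERNEL_MIN:
        W = x.shape[-1]
        n = next_fast_len(W + Wp - 1)
        Xf = rfft(x, n=n, axis=-1)
        Gf = rfft(g[..., ::-1], n=n, axis=-1)
        Yf = np.einsum("bihf,bohf->oif", Xf, Gf, optimize=True)
        full = irfft(Yf, n=n, axis=-1)
        # corr(x, g)[kappa] for kappa = 0..k-1 lands at offset W'-1
        return np.ascontiguousarray(full[..., Wp - 1 : Wp - 1 + k], dtype=_F32)
    v = sliding_window_view(x, Wp, axis=-1)           # (b,i,h,k,W')
    return np.einsum("bihkw,bohw->oik", v, g, optimize=True).astype(_F32, copy=False)


def _corr_grad_x(g, w, W):
    """Gradient of ``corr_valid`` w.r.t. the input: full convolution of g with w.

    g: (b,o,h,W'); w: (o,i,k)  ->  (b,i,h,W)
    """
    o, i, k = w.shape
    if k >= _FFT_KERNEL_MIN:
        n = next_fast_len(W + k - 1)
        Gf = rfft(g, n=n, axis=-1)
        Wf = rfft(w, n=n, axis=-1)
        Yf = np.einsum("bohf,oif->bihf", Gf, Wf, optimize=True)
        full = irfft(Yf, n=n, axis=-1)
        return np.ascontiguousarray(full[..., :W], dtype=_F32)
    gp = np.pad(g, ((0, 0), (0, 0), (0, 0), (k - 1, k - 1)))
    v = sliding_window_view(gp, k, axis=-1)          # (b,o,h,W,k)
    return np.einsum("bohwk,oik->bihw", v, w[..., ::-1], optimize=True).astype(
        _F32, copy=False
    )


def _same_pad(k):
    """Left/right padding replicating Keras 'same' for stride 1."""
    return (k - 1) // 2, k // 2


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2-D convolution, kernel ``(kh, kw)``, pad 'same' or 'valid'.

    Implemented as a sum of temporal correlations over row offsets so the
    inner loop stays a BLAS/FFT contraction even for tall kernels such as the
    spatial ``(C, 1)`` filters.
    """

    def __init__(self, in_ch, out_ch, kernel, pad="valid", use_bias=True,
                 maxnorm=None, rng=None, name="conv", input_grad=True):
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        fan_out = out_ch * kh * kw
        self.w = Param(
            glorot_uniform(rng, (out_ch, in_ch, kh, kw), fan_in, fan_out),
            name=name + ".w", maxnorm=maxnorm, maxnorm_axes=(1, 2, 3),
        )
        self.b = Param(np.zeros(out_ch), name=name + ".b") if use_bias else None
        self.pad = pad
        self.kh, self.kw = kh, kw
        # network entry layers skip the input gradient (nothing below them)
        self.input_grad = input_grad

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        if self.pad == "same":
            ph = _same_pad(self.kh)
            pw = _same_pad(self.kw)
            x = np.pad(x, ((0, 0), (0, 0), ph, pw))
        self._x = x
        b, i, H, W = x.shape
        Ho, Wo = H - self.kh + 1, W - self.kw + 1
        y = None
        for dh in range(self.kh):
            part = corr_valid(x[:, :, dh : dh + Ho, :], self.w.val[:, :, dh, :])
            y = part if y is None else y + part
        if self.b is not None:
            y += self.b.val[None, :, None, None]
        return y

    def backward(self, grad):
        x = self._x
        b, i, H, W = x.shape
        Ho = H - self.kh + 1
        dx = np.zeros_like(x) if self.input_grad else None
        for dh in range(self.kh):
            xs = x[:, :, dh : dh + Ho, :]
            self.w.grad[:, :, dh, :] = _corr_grad_w(xs, grad, self.kw)
            if self.input_grad:
                dx[:, :, dh : dh + Ho, :] += _corr_grad_x(
                    grad, self.w.val[:, :, dh, :], W)
        if self.b is not None:
            self.b.grad[...] = grad.sum(axis=(0, 2, 3))
        if dx is None:
            return None
        if self.pad == "same":
            ph = _same_pad(self.kh)
            pw = _same_pad(self.kw)
            dx = dx[:, :, ph[0] : dx.shape[2] - ph[1] or None,
                    pw[0] : dx.shape[3] - pw[1] or None]
        return dx


class DepthwiseSpatialConv(Layer):
    """Depthwise convolution over the electrode axis with a full-height kernel.

    Kernel ``(in_ch, depth, H)``; each input map yields ``depth`` spatial
    filters, collapsing the electrode axis to 1 (EEGNet's DepthwiseConv2D
    ``(C, 1)`` with depth multiplier D).
    """

    def __init__(self, in_ch, depth, H, maxnorm=None, rng=None, name="dwspat"):
        self.w = Param(
            glorot_uniform(rng, (in_ch, depth, H), H, depth * H),
            name=name + ".w", maxnorm=maxnorm, maxnorm_axes=(2,),
        )
        self.in_ch, self.depth = in_ch, depth

    def params(self):
        return [self.w]

    def forward(self, x, train=False):
        self._x = x
        y = np.einsum("bict,idc->bidt", x, self.w.val, optimize=True)
        b, i, d, t = y.shape
        return np.ascontiguousarray(y.reshape(b, i * d, 1, t), dtype=_F32)

    def backward(self, grad):
        b = grad.shape[0]
        t = grad.shape[-1]
        g = grad.reshape(b, self.in_ch, self.depth, t)
        self.w.grad[...] = np.einsum("bict,bidt->idc", self._x, g, optimize=True)
        dx = np.einsum("bidt,idc->bict", g, self.w.val, optimize=True)
        return np.ascontiguousarray(dx, dtype=_F32)


class DepthwiseTemporalConv(Layer):
    """Per-map temporal convolution (the depthwise half of SeparableConv2D)."""

    def __init__(self, ch, k, rng=None, name="dwtemp"):
        self.w = Param(glorot_uniform(rng, (ch, k), k, k), name=name + ".w")
        self.k = k

    def params(self):
        return [self.w]

    def forward(self, x, train=False):
        pw = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), pw))
        self._xp = xp
        v = sliding_window_view(xp, self.k, axis=-1)   # (b,c,h,W,k)
        return np.einsum("bchwk,ck->bchw", v, self.w.val, optimize=True).astype(
            _F32, copy=False
        )

    def backward(self, grad):
        xp = self._xp
        v = sliding_window_view(xp, self.k, axis=-1)
        self.w.grad[...] = np.einsum("bchwk,bchw->ck", v, grad, optimize=True)
        gp = np.pad(grad, ((0, 0), (0, 0), (0, 0), (self.k - 1, self.k - 1)))
        gv = sliding_window_view(gp, self.k, axis=-1)
        dxp = np.einsum("bchwk,ck->bchw", gv, self.w.val[:, ::-1], optimize=True)
        pl, pr = _same_pad(self.k)
        W = xp.shape[-1]
        return np.ascontiguousarray(dxp[..., pl : W - pr or None], dtype=_F32)


class PointwiseConv(Layer):
    """1x1 convolution mixing feature maps."""

    def __init__(self, in_ch, out_ch, use_bias=False, rng=None, name="pw"):
        self.w = Param(glorot_uniform(rng, (in_ch, out_ch), in_ch, out_ch),
                       name=name + ".w")
        self.b = Param(np.zeros(out_ch), name=name + ".b") if use_bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        self._x = x
        y = np.einsum("bihw,io->bohw", x, self.w.val, optimize=True)
        if self.b is not None:
            y += self.b.val[None, :, None, None]
        return np.ascontiguousarray(y, dtype=_F32)

    def backward(self, grad):
        self.w.grad[...] = np.einsum("bihw,bohw->io", self._x, grad, optimize=True)
        if self.b is not None:
            self.b.grad[...] = grad.sum(axis=(0, 2, 3))
        dx = np.einsum("bohw,io->bihw", grad, self.w.val, optimize=True)
        return np.ascontiguousarray(dx, dtype=_F32)


class BatchNorm(Layer):
    """Per-feature-map batch normalization (statistics over batch x H x W)."""

    def __init__(self, ch, eps=1e-3, momentum=0.1, name="bn"):
        self.gamma = Param(np.ones(ch), name=name + ".gamma")
        self.beta = Param(np.zeros(ch), name=name + ".beta")
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(ch, dtype=_F32)
        self.run_var = np.ones(ch, dtype=_F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mean).astype(_F32)
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var).astype(_F32)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return (xhat * self.gamma.val[None, :, None, None]
                + self.beta.val[None, :, None, None]).astype(_F32, copy=False)

    def backward(self, grad):
        xhat, inv, train = self._cache
        self.gamma.grad[...] = np.sum(grad * xhat, axis=(0, 2, 3))
        self.beta.grad[...] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.val[None, :, None, None]
        if not train:
            return (g * inv[None, :, None, None]).astype(_F32, copy=False)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dxhat_mean = g.mean(axis=(0, 2, 3))[None, :, None, None]
        dxhat_dot = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        dx = inv[None, :, None, None] * (g - dxhat_mean - xhat * dxhat_dot)
        return dx.astype(_F32, copy=False)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x, train=False):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._y = y
        self._pos = x > 0
        return y.astype(_F32, copy=False)

    def backward(self, grad):
        return (grad * np.where(self._pos, 1.0, self._y + self.alpha)).astype(
            _F32, copy=False
        )


class LeakyReLU(Layer):
    def __init__(self, alpha=0.3):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._pos = x > 0
        return np.where(self._pos, x, self.alpha * x).astype(_F32, copy=False)

    def backward(self, grad):
        return (grad * np.where(self._pos, 1.0, self.alpha)).astype(_F32, copy=False)


class AvgPool(Layer):
    """Average pooling (1, p), valid padding: a trailing remainder is dropped."""

    def __init__(self, p):
        self.p = p

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        wo = w // self.p
        if wo == 0:
            raise ValueError(
                f"AvgPool(1,{self.p}) on width {w}: output would be empty "
                f"(shape {x.shape})"
            )
        self._in_w = w
        xr = x[..., : wo * self.p].reshape(b, c, h, wo, self.p)
        return xr.mean(axis=-1).astype(_F32, copy=False)

    def backward(self, grad):
        b, c, h, wo = grad.shape
        dx = np.zeros((b, c, h, self._in_w), dtype=_F32)
        dx[..., : wo * self.p] = np.repeat(grad / self.p, self.p, axis=-1)
        return dx


class MaxPool(Layer):
    """Max pooling (1, p) with stride p, valid padding."""

    def __init__(self, p):
        self.p = p

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        wo = w // self.p
        if wo == 0:
            raise ValueError(
                f"MaxPool(1,{self.p}) on width {w}: output would be empty "
                f"(shape {x.shape})"
            )
        self._in_w = w
        xr = x[..., : wo * self.p].reshape(b, c, h, wo, self.p)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1).astype(_F32, copy=False)

    def backward(self, grad):
        b, c, h, wo = grad.shape
        dxr = np.zeros((b, c, h, wo, self.p), dtype=_F32)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros((b, c, h, self._in_w), dtype=_F32)
        dx[..., : wo * self.p] = dxr.reshape(b, c, h, wo * self.p)
        return dx


class Dropout(Layer):
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape

    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, grad):
        return grad.reshape(self._in)


class Dense(Layer):
    def __init__(self, n_in, n_out, use_bias=True, maxnorm=None, l1=0.0, l2=0.0,
                 rng=None, name="dense"):
        self.w = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out),
                       name=name + ".w", maxnorm=maxnorm, maxnorm_axes=(0,),
                       l1=l1, l2=l2)
        self.b = Param(np.zeros(n_out), name=name + ".b") if use_bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.w.val
        if self.b is not None:
            y += self.b.val
        return y.astype(_F32, copy=False)

    def backward(self, grad):
        self.w.grad[...] = self._x.T @ grad
        if self.b is not None:
            self.b.grad[...] = grad.sum(axis=0)
        return (grad @ self.w.val.T).astype(_F32, copy=False)
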