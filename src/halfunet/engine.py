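"""Numpy compute kernels and layer objects with hand-written backward passes.

Everything runs in float32 on (batch, channels, height, width) arrays.
Convolutions use "same" padding at stride 1 and are lowered to K*K
channel-mixing GEMMs accumulated at shifted spatial offsets (a spatial
shift commutes with the pointwise channel mix), which avoids im2col
gathers; large temporaries come from a reusable scratch pool.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


class ShapeError(ValueError):
    """Raised when tensor shapes are inconsistent with a layer's contract."""


class UnsupportedConfigError(ValueError):
    """Raised for layer configurations outside the supported design space."""


# ---------------------------------------------------------------------------
# scratch-buffer pool: large *temporaries* (never returned values) are
# reused across calls so repeated training steps do not re-fault fresh
# mmap'd pages on every large allocation.

_SCRATCH: dict = {}


def scratch(tag: str, shape, dtype=F32, zero=False) -> np.ndarray:
    key = (tag, tuple(shape), np.dtype(dtype))
    a = _SCRATCH.get(key)
    if a is None:
        a = np.empty(shape, dtype)
        _SCRATCH[key] = a
    if zero:
        a.fill(0)
    return a


def _padded(tag, x, p):
    """Zero-padded copy of x in a scratch buffer."""
    if p == 0:
        return x
    n, c, h, w = x.shape
    xp = scratch(tag, (n, c, h + 2 * p, w + 2 * p), x.dtype, zero=True)
    xp[:, :, p : p + h, p : p + w] = x
    return xp


# ---------------------------------------------------------------------------
# convolution (stride 1, "same" padding, odd kernel)






def conv2d_fwd(x, w, b):
    """Same-padded stride-1 convolution, evaluated as a sum of K*K
    channel-mixing GEMMs accumulated at shifted offsets (spatial shifts
    commute with the pointwise channel mix, so no im2col gather is needed
    on the forward path)."""
    co, ci, k, _ = w.shape
    n, c, h, wd = x.shape
    if c != ci:
        raise ShapeError(f"conv expects {ci} input channels, got {c}")
    p = k // 2
    xm = x.reshape(n, c, h * wd)
    if k == 1:
        y = np.matmul(w.reshape(co, ci), xm).reshape(n, co, h, wd).copy()
    else:
        ypad = scratch("conv_ypad", (n, co, h + 2 * p, wd + 2 * p), x.dtype,
                       zero=True)
        zflat = scratch("conv_z", (n, co, h * wd), x.dtype)
        for ki in range(k):
            for kj in range(k):
                np.matmul(w[:, :, ki, kj], xm, out=zflat)
                ypad[:, :, 2 * p - ki : 2 * p - ki + h,
                     2 * p - kj : 2 * p - kj + wd] += zflat.reshape(n, co, h, wd)
        y = np.ascontiguousarray(ypad[:, :, p : p + h, p : p + wd])
    if b is not None:
        y += b.reshape(1, co, 1, 1)
    return y


def conv2d_bwd(dy, x, w, with_bias=True):
    co, ci, k, _ = w.shape
    n, c, h, wd = x.shape
    p = k // 2
    dym = dy.reshape(n, co, h * wd)
    if k == 1:
        dx = np.ascontiguousarray(
            np.matmul(w.reshape(co, ci).T, dym).reshape(x.shape)
        )
    else:
        dxpad = scratch("conv_dxpad", (n, ci, h + 2 * p, wd + 2 * p), dy.dtype,
                        zero=True)
        wt = np.ascontiguousarray(w.transpose(2, 3, 1, 0))  # (k,k,ci,co)
        uflat = scratch("conv_u", (n, ci, h * wd), dy.dtype)
        for ki in range(k):
            for kj in range(k):
                np.matmul(wt[ki, kj], dym, out=uflat)
                dxpad[:, :, ki : ki + h, kj : kj + wd] += uflat.reshape(n, ci, h, wd)
        dx = np.ascontiguousarray(dxpad[:, :, p : p + h, p : p + wd])
    if k == 1:
        dw = np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3])).reshape(w.shape)
    else:
        # weight gradient via row-flattened shifts: after zero-padding, the
        # (ki,kj) shift is a constant offset in the flattened row-major
        # index, so every summand is a strided-view GEMM — only one
        # channels-last copy of dy is needed.
        wp = wd + 2 * p
        l0 = h * wp
        ltot = (h + 2 * p) * wp
        xflat = scratch("conv_xflat", (n, ci, ltot + 2 * p), x.dtype, zero=True)
        xflat[:, :, :ltot].reshape(n, ci, h + 2 * p, wp)[
            :, :, p : p + h, p : p + wd
        ] = x
        dypt = scratch("conv_dypT", (n, h, wp, co), dy.dtype, zero=True)
        dypt[:, :, :wd, :] = dy.transpose(0, 2, 3, 1)
        dypt = dypt.reshape(n, l0, co)
        dw = np.empty_like(w)
        for ki in range(k):
            for kj in range(k):
                off = ki * wp + kj
                prod = np.matmul(xflat[:, :, off : off + l0], dypt)
                dw[:, :, ki, kj] = prod.sum(axis=0).T
    db = dy.sum(axis=(0, 2, 3)) if with_bias else None
    return dx, dw, db


# ---------------------------------------------------------------------------
# depthwise convolution (the Ghost module's cheap operation)


def depthwise_fwd(x, w, b):
    n, c, h, wd = x.shape
    cw, k, _ = w.shape
    if cw != c:
        raise ShapeError(f"depthwise conv expects {cw} channels, got {c}")
    p = k // 2
    xp = _padded("dw_pad", x, p)
    y = np.broadcast_to(b.reshape(1, c, 1, 1), x.shape).astype(x.dtype).copy()
    for ki in range(k):
        for kj in range(k):
            y += w[:, ki, kj].reshape(1, c, 1, 1) * xp[:, :, ki : ki + h, kj : kj + wd]
    return y


def depthwise_bwd(dy, x, w):
    n, c, h, wd = x.shape
    k = w.shape[1]
    p = k // 2
    xp = _padded("dw_pad", x, p)
    dxp = scratch("dw_dxpad", xp.shape, dy.dtype, zero=True)
    dw = np.empty_like(w)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + h, kj : kj + wd] += w[:, ki, kj].reshape(1, c, 1, 1) * dy
            dw[:, ki, kj] = (dy * xp[:, :, ki : ki + h, kj : kj + wd]).sum(axis=(0, 2, 3))
    db = dy.sum(axis=(0, 2, 3))
    return np.ascontiguousarray(dxp[:, :, p : p + h, p : p + wd]), dw, db


# ---------------------------------------------------------------------------
# transposed convolution with kernel == stride (non-overlapping upsampling)


def deconv_fwd(x, w, b):
    n, ci, h, wd = x.shape
    ciw, co, k, _ = w.shape
    if ciw != ci:
        raise ShapeError(f"deconv expects {ciw} input channels, got {ci}")
    t = np.tensordot(x, w, axes=([1], [0]))  # (n,h,w,co,k,k)
    y = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
        n, co, h * k, wd * k
    )
    return y + b.reshape(1, co, 1, 1)


def deconv_bwd(dy, x, w):
    n, ci, h, wd = x.shape
    _, co, k, _ = w.shape
    dyt = np.ascontiguousarray(
        dy.reshape(n, co, h, k, wd, k).transpose(0, 2, 4, 1, 3, 5)
    )  # (n,h,w,co,k,k)
    dx = np.tensordot(dyt, w, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
    dw = np.tensordot(x, dyt, axes=([0, 2, 3], [0, 1, 2]))
    db = dy.sum(axis=(0, 2, 3))
    return np.ascontiguousarray(dx), dw, db


# ---------------------------------------------------------------------------
# 2x2 max pooling, stride 2


def maxpool2_fwd(x):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ShapeError(f"maxpool input {h}x{w} not divisible by 2")
    xw = np.ascontiguousarray(
        x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(n, c, h // 2, w // 2, 4)
    idx = xw.argmax(axis=-1)
    y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return y, idx.astype(np.uint8)


def maxpool2_bwd(dy, idx, x_shape):
    n, c, h, w = x_shape
    dxw = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxw, idx[..., None].astype(np.intp), dy[..., None], axis=-1)
    return np.ascontiguousarray(
        dxw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# bilinear resize by an integer factor (half-pixel centers, edge clamped)

_INTERP_CACHE: dict = {}


def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    m = _INTERP_CACHE.get(key)
    if m is None:
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        i0 = np.floor(src).astype(int)
        frac = (src - i0).astype(F32)
        lo = np.clip(i0, 0, n_in - 1)
        hi = np.clip(i0 + 1, 0, n_in - 1)
        m = np.zeros((n_out, n_in), dtype=F32)
        np.add.at(m, (np.arange(n_out), lo), 1.0 - frac)
        np.add.at(m, (np.arange(n_out), hi), frac)
        _INTERP_CACHE[key] = m
    return m


def bilinear_fwd(x, factor: int):
    n, c, h, w = x.shape
    if factor == 1:
        return x
    mh = interp_matrix(h * factor, h)
    mw = interp_matrix(w * factor, w)
    t = np.tensordot(x.reshape(n * c, h, w), mh, axes=([1], [1]))  # (nc,w,fh)
    y = np.tensordot(t, mw, axes=([1], [1]))  # (nc,fh,fw)
    return np.ascontiguousarray(y).reshape(n, c, h * factor, w * factor)


def bilinear_bwd(dy, factor: int, x_shape):
    n, c, h, w = x_shape
    if factor == 1:
        return dy
    mh = interp_matrix(h * factor, h)
    mw = interp_matrix(w * factor, w)
    t = np.tensordot(dy.reshape(n * c, h * factor, w * factor), mh,
                     axes=([1], [0]))  # (nc,fw,h)
    g = np.tensordot(t, mw, axes=([1], [0]))  # (nc,h,w)
    return np.ascontiguousarray(g).reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# batch normalization


def bn_fwd(x, gamma, beta, running_mean, running_var, training):
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - BN_MOMENTUM
        running_mean += BN_MOMENTUM * mean
        running_var *= 1.0 - BN_MOMENTUM
        running_var += BN_MOMENTUM * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + BN_EPS).astype(F32)
    xhat = (x - mean.reshape(1, -1, 1, 1)) / std.reshape(1, -1, 1, 1)
    y = gamma.reshape(1, -1, 1, 1) * xhat + beta.reshape(1, -1, 1, 1)
    return y.astype(F32, copy=False), xhat.astype(F32, copy=False), std


def bn_bwd(dy, xhat, std, gamma):
    n, c, h, w = dy.shape
    m = n * h * w
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    coef = (gamma / std).reshape(1, c, 1, 1)
    dx = coef * (dy - dbeta.reshape(1, c, 1, 1) / m - xhat * dgamma.reshape(1, c, 1, 1) / m)
    return dx.astype(F32, copy=False), dgamma, dbeta


# ---------------------------------------------------------------------------
# layer objects


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Layer:
    """Base layer: holds parameters, gradients, and per-batch caches."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    def forward(self, inputs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class ConvLayer(Layer):
    """K x K same-padded convolution, optional batchnorm + ReLU."""

    def __init__(self, k, cin, cout, rng, bias=True, batchnorm=False, relu=False):
        super().__init__()
        self.k, self.cin, self.cout = k, cin, cout
        self.bias, self.batchnorm, self.relu = bias, batchnorm, relu
        self.params["w"] = _he(rng, (cout, cin, k, k), fan_in=k * k * cin)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=F32)
        if batchnorm:
            self.params["gamma"] = np.ones(cout, dtype=F32)
            self.params["beta"] = np.zeros(cout, dtype=F32)
            self.buffers["running_mean"] = np.zeros(cout, dtype=F32)
            self.buffers["running_var"] = np.ones(cout, dtype=F32)

    def forward(self, inputs, training):
        (x,) = inputs
        self._cache = {"x": x}
        y = conv2d_fwd(x, self.params["w"], self.params.get("b"))
        if self.batchnorm:
            y, xhat, std = bn_fwd(
                y,
                self.params["gamma"],
                self.params["beta"],
                self.buffers["running_mean"],
                self.buffers["running_var"],
                training,
            )
            self._cache["xhat"], self._cache["std"] = xhat, std
        if self.relu:
            y = np.maximum(y, 0.0)
            self._cache["out"] = y
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * (self._cache["out"] > 0)
        if self.batchnorm:
            dy, dg, dbeta = bn_bwd(
                dy, self._cache["xhat"], self._cache["std"], self.params["gamma"]
            )
            self.grads["gamma"] = dg
            self.grads["beta"] = dbeta
        dx, dw, db = conv2d_bwd(dy, self._cache["x"], self.params["w"], self.bias)
        self.grads["w"] = dw
        if self.bias:
            self.grads["b"] = db
        return [dx]


class GhostLayer(Layer):
    """Ghost module: a primary K x K conv yields the intrinsic half of the
    output channels; a cheap d x d depthwise conv of those maps yields the
    other ("ghost") half; both halves are concatenated.

    Only the calibrated ratio s=2 is supported; batchnorm + ReLU follow each
    of the two stages when enabled.
    """

    def __init__(self, k, cin, cout, rng, s=2, d=3, batchnorm=True, relu=True):
        super().__init__()
        if s != 2:
            raise UnsupportedConfigError(f"Ghost ratio s={s} unsupported (only s=2)")
        if cout % 2:
            raise UnsupportedConfigError(f"Ghost cout={cout} must be even for s=2")
        self.k, self.cin, self.cout, self.d = k, cin, cout, d
        self.batchnorm, self.relu = batchnorm, relu
        half = cout // 2
        self.half = half
        self.params["w1"] = _he(rng, (half, cin, k, k), fan_in=k * k * cin)
        self.params["b1"] = np.zeros(half, dtype=F32)
        self.params["w2"] = _he(rng, (half, d, d), fan_in=d * d)
        self.params["b2"] = np.zeros(half, dtype=F32)
        if batchnorm:
            for tag in ("1", "2"):
                self.params[f"gamma{tag}"] = np.ones(half, dtype=F32)
                self.params[f"beta{tag}"] = np.zeros(half, dtype=F32)
                self.buffers[f"running_mean{tag}"] = np.zeros(half, dtype=F32)
                self.buffers[f"running_var{tag}"] = np.ones(half, dtype=F32)

    def _post(self, z, tag, training):
        if self.batchnorm:
            z, xhat, std = bn_fwd(
                z,
                self.params[f"gamma{tag}"],
                self.params[f"beta{tag}"],
                self.buffers[f"running_mean{tag}"],
                self.buffers[f"running_var{tag}"],
                training,
            )
            self._cache[f"xhat{tag}"], self._cache[f"std{tag}"] = xhat, std
        if self.relu:
            z = np.maximum(z, 0.0)
        self._cache[f"out{tag}"] = z
        return z

    def _post_bwd(self, dz, tag):
        if self.relu:
            dz = dz * (self._cache[f"out{tag}"] > 0)
        if self.batchnorm:
            dz, dg, dbeta = bn_bwd(
                dz,
                self._cache[f"xhat{tag}"],
                self._cache[f"std{tag}"],
                self.params[f"gamma{tag}"],
            )
            self.grads[f"gamma{tag}"] = dg
            self.grads[f"beta{tag}"] = dbeta
        return dz

    def forward(self, inputs, training):
        (x,) = inputs
        self._cache = {"x": x}
        z1 = conv2d_fwd(x, self.params["w1"], self.params["b1"])
        r1 = self._post(z1, "1", training)
        z2 = depthwise_fwd(r1, self.params["w2"], self.params["b2"])
        r2 = self._post(z2, "2", training)
        return np.concatenate([r1, r2], axis=1)

    def backward(self, dy):
        dr1_direct = dy[:, : self.half]
        dr2 = dy[:, self.half :]
        dz2 = self._post_bwd(dr2, "2")
        dr1_cheap, dw2, db2 = depthwise_bwd(dz2, self._cache["out1"], self.params["w2"])
        self.grads["w2"], self.grads["b2"] = dw2, db2
        dz1 = self._post_bwd(dr1_direct + dr1_cheap, "1")
        dx, dw1, db1 = conv2d_bwd(dz1, self._cache["x"], self.params["w1"])
        self.grads["w1"], self.grads["b1"] = dw1, db1
        return [dx]


class DeconvLayer(Layer):
    """Transposed convolution with stride == kernel size (learned upsampling)."""

    def __init__(self, k, cin, cout, rng):
        super().__init__()
        self.k, self.cin, self.cout = k, cin, cout
        self.params["w"] = _he(rng, (cin, cout, k, k), fan_in=cin)
        self.params["b"] = np.zeros(cout, dtype=F32)

    def forward(self, inputs, training):
        (x,) = inputs
        self._cache = {"x": x}
        return deconv_fwd(x, self.params["w"], self.params["b"])

    def backward(self, dy):
        dx, dw, db = deconv_bwd(dy, self._cache["x"], self.params["w"])
        self.grads["w"], self.grads["b"] = dw, db
        return [dx]


class MaxPoolLayer(Layer):
    def forward(self, inputs, training):
        (x,) = inputs
        y, idx = maxpool2_fwd(x)
        self._cache = {"idx": idx, "x_shape": x.shape}
        return y

    def backward(self, dy):
        return [maxpool2_bwd(dy, self._cache["idx"], self._cache["x_shape"])]


class BilinearLayer(Layer):
    def __init__(self, factor):
        super().__init__()
        self.factor = int(factor)

    def forward(self, inputs, training):
        (x,) = inputs
        self._cache = {"x_shape": x.shape}
        return bilinear_fwd(x, self.factor)

    def backward(self, dy):
        return [bilinear_bwd(dy, self.factor, self._cache["x_shape"])]


class AddLayer(Layer):
    def forward(self, inputs, training):
        shapes = {a.shape for a in inputs}
        if len(shapes) != 1:
            raise ShapeError(f"additive fusion requires equal shapes, got {shapes}")
        self._cache = {"n": len(inputs)}
        out = inputs[0].copy()
        for a in inputs[1:]:
            out += a
        return out

    def backward(self, dy):
        return [dy] * self._cache["n"]


class ConcatLayer(Layer):
    def forward(self, inputs, training):
        self._cache = {"splits": [a.shape[1] for a in inputs]}
        return np.concatenate(inputs, axis=1)

    def backward(self, dy):
        out, at = [], 0
        for c in self._cache["splits"]:
            out.append(dy[:, at : at + c])
            at += c
        return out


class SigmoidLayer(Layer):
    def forward(self, inputs, training):
        (x,) = inputs
        out = 1.0 / (1.0 + np.exp(-x))
        self._cache = {"out": out}
        return out

    def backward(self, dy):
        out = self._cache["out"]
        return [dy * out * (1.0 - out)]
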