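"""Minimal 3D convolutional layer library (numpy, float32, explicit backprop).

Tensors are channel-first ``(C, D, H, W)`` single volumes; the training
pipeline uses batch size 1 throughout, so no batch axis is carried.
Stride-1 convolutions run as chunked im2col + GEMM (BLAS); the 2x2x2
stride-2 down/up convolutions are non-overlapping and reduce to single
reshaped GEMMs.  Every layer caches what its backward pass needs and
accumulates parameter gradients into ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

_CHUNK_BYTES = 192 * 1024**2  # patch-buffer budget for im2col


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col_chunks(xp: np.ndarray, k: int, h: int, w: int, reuse_buffer: bool = True):
    """Yield (d0, d1, patch matrix) over output-depth chunks.

    ``xp`` is the padded input ``(C, D + k - 1, H + k - 1, W + k - 1)``.  The
    patch matrix has one row per (kernel offset, input channel) and one
    column per output voxel of the chunk; it is filled with k**3 large
    strided block copies, which is far cheaper than a per-voxel gather.
    Row order is (ka, kb, kc, channel) — weights must be laid out to match.
    """
    c = xp.shape[0]
    d_out = xp.shape[1] - (k - 1)
    bytes_per_slice = h * w * c * k**3 * 4
    chunk = max(1, int(_CHUNK_BYTES // max(bytes_per_slice, 1)))
    patch = None
    for d0 in range(0, d_out, chunk):
        d1 = min(d0 + chunk, d_out)
        dd = d1 - d0
        if reuse_buffer:
            if patch is None or patch.shape[1] != dd * h * w:
                patch = np.empty((c * k**3, dd * h * w), dtype=np.float32)
        else:
            patch = np.empty((c * k**3, dd * h * w), dtype=np.float32)
        view = patch.reshape(k, k, k, c, dd, h, w)
        for a in range(k):
            for b in range(k):
                for g in range(k):
                    np.copyto(view[a, b, g], xp[:, d0 + a : d1 + a, b : b + h, g : g + w])
        yield d0, d1, patch


def _weight_matrix(weight: np.ndarray) -> np.ndarray:
    """(Cout, Cin, k, k, k) -> (Cout, k*k*k*Cin) matching the patch row order."""
    cout = weight.shape[0]
    return np.ascontiguousarray(weight.transpose(0, 2, 3, 4, 1).reshape(cout, -1))


def conv3d_same(
    x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None
) -> np.ndarray:
    """Stride-1 'same' 3D convolution; weight ``(Cout, Cin, k, k, k)``."""
    cout, cin, k, _, _ = weight.shape
    _, d, h, w = x.shape
    if k == 1:  # pure channel mixing: single GEMM, no patches
        out = (weight.reshape(cout, cin) @ x.reshape(cin, -1)).reshape(cout, d, h, w)
    else:
        pad = k // 2
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
        wm = _weight_matrix(weight)
        out = np.empty((cout, d, h, w), dtype=np.float32)
        for d0, d1, patch in _im2col_chunks(xp, k, h, w):
            y = wm @ patch  # (cout, chunk voxels)
            out[:, d0:d1] = y.reshape(cout, d1 - d0, h, w)
    if bias is not None:
        out += bias[:, None, None, None]
    return out


class Conv3d(Layer):
    """5x5x5-style stride-1 convolution with 'same' zero padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, name: str = "conv"):
        if k % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {k}")
        std = np.sqrt(2.0 / (cin * k**3))
        self.w = Param(f"{name}.weight", rng.normal(0.0, std, size=(cout, cin, k, k, k)))
        self.b = Param(f"{name}.bias", np.zeros(cout))
        self.k = k
        self._x: np.ndarray | None = None
        self._patches: list | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.k
        cout, cin = self.w.value.shape[:2]
        self._x = x if training else None
        if k == 1 or not training:
            return conv3d_same(x, self.w.value, self.b.value)
        # training path caches the im2col patches for the weight-gradient GEMM
        _, d, h, w = x.shape
        pad = k // 2
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
        wm = _weight_matrix(self.w.value)
        out = np.empty((cout, d, h, w), dtype=np.float32)
        self._patches = []
        for d0, d1, patch in _im2col_chunks(xp, k, h, w, reuse_buffer=False):
            out[:, d0:d1] = (wm @ patch).reshape(cout, d1 - d0, h, w)
            self._patches.append((d0, d1, patch))
        out += self.b.value[:, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        cout, cin, k = self.w.value.shape[:3]
        self.b.grad += dy.sum(axis=(1, 2, 3))
        if k == 1:
            dy_mat = dy.reshape(cout, -1)
            x_mat = x.reshape(cin, -1)
            self.w.grad += (dy_mat @ x_mat.T).reshape(self.w.value.shape)
            dx = (self.w.value.reshape(cout, cin).T @ dy_mat).reshape(x.shape)
            return dx.astype(np.float32)
        dwm = np.zeros((cout, k**3 * cin), dtype=np.float32)
        for d0, d1, patch in self._patches:
            dwm += dy[:, d0:d1].reshape(cout, -1) @ patch.T
        self._patches = None
        self.w.grad += dwm.reshape(cout, k, k, k, cin).transpose(0, 4, 1, 2, 3)
        # grad wrt input: correlate dy with the spatially flipped, transposed kernel
        w_rot = self.w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return conv3d_same(dy, np.ascontiguousarray(w_rot))


class DownConv2x(Layer):
    """2x2x2 convolution with stride 2 (non-overlapping), halves each axis."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "down"):
        std = np.sqrt(2.0 / (cin * 8))
        self.w = Param(f"{name}.weight", rng.normal(0.0, std, size=(cout, cin, 2, 2, 2)))
        self.b = Param(f"{name}.bias", np.zeros(cout))
        self._xr: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"down-convolution needs even dims, got {(d, h, w)}")
        xr = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(1, 3, 5, 0, 2, 4, 6)
            .reshape(-1, c * 8)
        )
        self._xr = xr if training else None
        self._shape = x.shape
        cout = self.w.value.shape[0]
        y = xr @ self.w.value.reshape(cout, -1).T + self.b.value
        return np.ascontiguousarray(
            y.reshape(d // 2, h // 2, w // 2, cout).transpose(3, 0, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        cout = self.w.value.shape[0]
        dy_mat = dy.transpose(1, 2, 3, 0).reshape(-1, cout)
        self.w.grad += (dy_mat.T @ self._xr).reshape(self.w.value.shape)
        self.b.grad += dy_mat.sum(axis=0)
        dxr = dy_mat @ self.w.value.reshape(cout, -1)
        return np.ascontiguousarray(
            dxr.reshape(d // 2, h // 2, w // 2, c, 2, 2, 2)
            .transpose(3, 0, 4, 1, 5, 2, 6)
            .reshape(c, d, h, w)
        )


class UpConv2x(Layer):
    """2x2x2 transpose convolution with stride 2, doubles each axis."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "up"):
        std = np.sqrt(2.0 / cin)
        self.w = Param(f"{name}.weight", rng.normal(0.0, std, size=(cin, cout, 2, 2, 2)))
        self.b = Param(f"{name}.bias", np.zeros(cout))
        self._xm: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, d, h, w = x.shape
        xm = x.transpose(1, 2, 3, 0).reshape(-1, c)
        self._xm = xm if training else None
        self._shape = x.shape
        cin, cout = self.w.value.shape[:2]
        y = xm @ self.w.value.reshape(cin, -1)  # (V, cout*8)
        out = np.ascontiguousarray(
            y.reshape(d, h, w, cout, 2, 2, 2)
            .transpose(3, 0, 4, 1, 5, 2, 6)
            .reshape(cout, 2 * d, 2 * h, 2 * w)
        )
        out += self.b.value[:, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        cin, cout = self.w.value.shape[:2]
        dy_r = (
            dy.reshape(cout, d, 2, h, 2, w, 2)
            .transpose(1, 3, 5, 0, 2, 4, 6)
            .reshape(-1, cout * 8)
        )
        self.w.grad += (self._xm.T @ dy_r).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(1, 2, 3))
        dxm = dy_r @ self.w.value.reshape(cin, -1).T
        return np.ascontiguousarray(dxm.reshape(d, h, w, c).transpose(3, 0, 1, 2))


class BatchNorm3d(Layer):
    """Per-channel activation normalization with learnable scale and shift.

    The pipeline trains with unit batches, where batch normalization reduces
    to per-sample (instance) statistics; the same per-sample statistics are
    used at inference, keeping prediction deterministic and batch-free.
    """

    def __init__(self, c: int, name: str = "bn", eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            self._xhat, self._inv_std = xhat, inv_std
        return (self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n = dy[0].size
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None, None]
        mean_dxhat = dxhat.mean(axis=(1, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return ((dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * inv_std).astype(np.float32)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative slope per channel."""

    def __init__(self, c: int, name: str = "prelu", init: float = 0.25):
        self.a = Param(f"{name}.alpha", np.full(c, init))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.a]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        a = self.a.value[:, None, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = np.minimum(x, 0.0)
        self.a.grad += (dy * neg).sum(axis=(1, 2, 3))
        a = self.a.value[:, None, None, None]
        return np.where(x > 0, dy, a * dy).astype(np.float32)


class SpatialDropout(Layer):
    """Channel-wise dropout: whole feature maps are zeroed during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape[0]) >= self.rate
        scale = 1.0 / (1.0 - self.rate)
        mask = (keep * scale).astype(np.float32)[:, None, None, None]
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequence(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """y = F(x) + P(x): additive skip around a conv group.

    ``projection`` is a 1x1x1 convolution used when the group changes channel
    count, otherwise the skip is the identity.
    """

    def __init__(self, body: Sequence, projection: Conv3d | None = None):
        self.body = body
        self.projection = projection

    def params(self) -> list[Param]:
        p = self.body.params()
        if self.projection is not None:
            p += self.projection.params()
        return p

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        skip = x if self.projection is None else self.projection.forward(x, training)
        return self.body.forward(x, training) + skip

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.body.backward(dy)
        if self.projection is None:
            return dx + dy
        return dx + self.projection.backward(dy)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of a (C, D, H, W) array."""
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient wrt logits given the softmax output p and dL/dp."""
    return (p * (dp - (dp * p).sum(axis=0, keepdims=True))).astype(np.float32)
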