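"""Minimal numpy neural-network engine (channels-first, float32).

Provides exactly the building blocks the compact micro-expression
classifiers need: 2-D convolution with dilation (atrous) support,
overlapping max pooling, non-overlapping average pooling, batch
normalization, bilinear resize, dense layers, ReLU/softmax, a combined
softmax-cross-entropy loss, and the Adam optimizer.  Every layer
implements an explicit ``forward``/``backward`` pair; gradients are
checked numerically in the test suite.

All tensors are ``(N, C, H, W)`` float32 unless noted.  He-uniform
initialization is drawn from an explicit ``numpy.random.Generator`` so a
model build is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class GeometryError(ValueError):
    """Raised when a layer's kernel/stride/padding cannot produce a
    spatially valid output on the given input."""


def conv_output_size(size: int, kernel: int, stride: int, padding: int,
                     dilation: int = 1) -> int:
    """Spatial output side of a conv/pool window: floor arithmetic."""
    span = (kernel - 1) * dilation + 1
    out = (size + 2 * padding - span) // stride + 1
    if out < 1:
        raise GeometryError(
            f"window span {span} (kernel {kernel}, dilation {dilation}) "
            f"exceeds padded input {size + 2 * padding}")
    return out


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# im2col machinery
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int,
            dilation: int = 1, pad_value: float = 0.0):
    """Return (cols, oh, ow): cols has shape (N, C, kh, kw, oh, ow)."""
    n, c, h, w = x.shape
    oh = conv_output_size(h, kh, stride, padding, dilation)
    ow = conv_output_size(w, kw, stride, padding, dilation)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                   constant_values=pad_value)
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow),
        (s[0], s[1], s[2] * dilation, s[3] * dilation,
         s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(view), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int,
            padding: int, dilation: int = 1) -> np.ndarray:
    """Scatter-add the (N, C, kh, kw, oh, ow) gradient back to x."""
    n, c, h, w = x_shape
    oh, ow = dcols.shape[-2:]
    dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=dcols.dtype)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            dxp[:, :, hi:hi + stride * oh:stride,
                wj:wj + stride * ow:stride] += dcols[:, :, i, j]
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameter dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with optional dilation.

    ``dilation=r`` realizes an atrous convolution: kernel taps are spaced
    ``r`` pixels apart, leaving a gap of ``r - 1`` between consecutive
    filter values, which enlarges the field of view at a constant
    parameter count.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.params["W"] = he_uniform(rng, (out_channels, in_channels,
                                            kernel, kernel), fan_in)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride,
                               self.padding, self.dilation)
        n = x.shape[0]
        cols2 = cols.reshape(n, -1, oh * ow)
        wmat = self.params["W"].reshape(self.out_channels, -1)
        out = np.matmul(wmat, cols2) + self.params["b"][:, None]
        if train:
            self._cache = (x.shape, cols2, oh, ow)
        return out.reshape(n, self.out_channels, oh, ow)

    def backward(self, grad):
        x_shape, cols2, oh, ow = self._cache
        n = grad.shape[0]
        g2 = grad.reshape(n, self.out_channels, oh * ow)
        wmat = self.params["W"].reshape(self.out_channels, -1)
        dw = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] = dw.reshape(self.params["W"].shape)
        self.grads["b"] = g2.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T, g2)
        dcols = dcols.reshape(n, self.in_channels, self.kernel, self.kernel,
                              oh, ow)
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride,
                       self.padding, self.dilation)


class MaxPool2d(Layer):
    """Max pooling, possibly overlapping (stride < kernel) and padded."""

    def __init__(self, kernel: int, stride: int, padding: int = 0) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride,
                               self.padding, pad_value=-np.inf)
        n, c = x.shape[:2]
        cols = cols.reshape(n, c, self.kernel * self.kernel, oh, ow)
        idx = cols.argmax(axis=2)
        out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (x.shape, idx, oh, ow)
        return out

    def backward(self, grad):
        x_shape, idx, oh, ow = self._cache
        n, c = x_shape[:2]
        dcols = np.zeros((n, c, self.kernel * self.kernel, oh, ow),
                         dtype=grad.dtype)
        np.put_along_axis(dcols, idx[:, :, None], grad[:, :, None], axis=2)
        dcols = dcols.reshape(n, c, self.kernel, self.kernel, oh, ow)
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride,
                       self.padding)


class AvgPool2d(Layer):
    """Non-overlapping average pooling (kernel == stride), floor mode.

    This is the down-sampling operator inside SPP branches; trailing rows
    and columns that do not fill a full window are dropped.
    """

    def __init__(self, kernel: int) -> None:
        super().__init__()
        self.kernel = kernel
        self._cache = None

    def forward(self, x, train=False):
        k = self.kernel
        n, c, h, w = x.shape
        oh, ow = h // k, w // k
        if oh < 1 or ow < 1:
            raise GeometryError(
                f"average-pool kernel {k} exceeds input {h}x{w}")
        xc = x[:, :, :oh * k, :ow * k].reshape(n, c, oh, k, ow, k)
        out = xc.mean(axis=(3, 5))
        if train:
            self._cache = (x.shape, oh, ow)
        return out.astype(DTYPE)

    def backward(self, grad):
        x_shape, oh, ow = self._cache
        k = self.kernel
        n, c, h, w = x_shape
        dx = np.zeros(x_shape, dtype=grad.dtype)
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, :oh * k, :ow * k] = g
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv)
        return (self.params["gamma"][:, None, None] * xhat
                + self.params["beta"][:, None, None]).astype(DTYPE)

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads["gamma"] = (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = grad.sum(axis=(0, 2, 3))
        g = grad * self.params["gamma"][:, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[:, None, None] / m) * (m * g - gsum - xhat * gxsum)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


def _interp_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Bilinear interpolation weights (out_size x in_size), half-pixel
    centers (no corner alignment)."""
    w = np.zeros((out_size, in_size), dtype=DTYPE)
    if in_size == 1:
        w[:, 0] = 1.0
        return w
    scale = in_size / out_size
    for o in range(out_size):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), in_size - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, in_size - 1)
        frac = src - lo
        w[o, lo] += 1.0 - frac
        w[o, hi] += frac
    return w


class BilinearResize(Layer):
    """Parameter-free bilinear resize expressed as two linear maps, so the
    backward pass is the exact transpose."""

    def __init__(self, out_h: int, out_w: int) -> None:
        super().__init__()
        self.out_h = out_h
        self.out_w = out_w
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._cache = None

    def _matrices(self, h: int, w: int):
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(self.out_h, h),
                               _interp_matrix(self.out_w, w))
        return self._mats[key]

    def forward(self, x, train=False):
        h, w = x.shape[2], x.shape[3]
        wr, wc = self._matrices(h, w)
        if train:
            self._cache = (h, w)
        return np.matmul(np.matmul(wr, x), wc.T)

    def backward(self, grad):
        h, w = self._cache
        wr, wc = self._matrices(h, w)
        return np.matmul(np.matmul(wr.T, grad), wc)


class Flatten(Layer):
    """(N, C, H, W) -> (N, C*H*W) in channel-major raster order."""

    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = he_uniform(rng, (in_features, out_features),
                                      in_features)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        x = self._cache
        self.grads["W"] = x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Softmax(Layer):
    """Row-wise softmax; used only at inference (training uses the fused
    cross-entropy loss for numerical stability)."""

    def forward(self, x, train=False):
        return softmax(x)

    def backward(self, grad):  # pragma: no cover - training bypasses this
        raise NotImplementedError("train through SoftmaxCrossEntropy")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

class Sequential(Layer):
    """Ordered, named layer chain.  ``layers`` is a list of (name, layer);
    names are unique and drive summaries and checkpoints."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        super().__init__()
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self.layers = layers

    def forward(self, x, train=False):
        for _, layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_params(self) -> int:
        return int(sum(layer.n_params() for _, layer in self.layers))

    def named_layers(self):
        yield from self.layers

    # -- parameter traversal (stable order: layer order, then key order) --

    def parameters(self):
        """Yield (path, layer, key) triples for every parameter array."""
        for name, layer in self.layers:
            if isinstance(layer, Sequential):
                for sub, l2, k in layer.parameters():
                    yield f"{name}/{sub}", l2, k
            elif hasattr(layer, "parameters_nested"):
                yield from layer.parameters_nested(prefix=name)
            else:
                for k in sorted(layer.params):
                    yield f"{name}/{k}", layer, k

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p: l.params[k] for p, l, k in self.parameters()}
        for name, layer in self._all_layers(""):
            if isinstance(layer, BatchNorm2d):
                state[f"{name}/running_mean"] = layer.running_mean
                state[f"{name}/running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p, l, k in self.parameters():
            l.params[k] = np.asarray(state[p], dtype=DTYPE)
        for name, layer in self._all_layers(""):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(state[f"{name}/running_mean"],
                                                dtype=DTYPE)
                layer.running_var = np.asarray(state[f"{name}/running_var"],
                                               dtype=DTYPE)

    def _all_layers(self, prefix: str):
        for name, layer in self.layers:
            path = f"{prefix}{name}"
            if isinstance(layer, Sequential):
                yield from layer._all_layers(path + "/")
            elif hasattr(layer, "all_layers_nested"):
                yield from layer.all_layers_nested(path + "/")
            else:
                yield path, layer


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; state keyed by parameter path."""

    def __init__(self, model: Sequential, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for path, layer, key in self.model.parameters():
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self.m.setdefault(path, np.zeros_like(layer.params[key]))
            v = self.v.setdefault(path, np.zeros_like(layer.params[key]))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            update = (self.lr * (m / bias1)
                      / (np.sqrt(v / bias2) + self.eps))
            layer.params[key] -= update.astype(layer.params[key].dtype)
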