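"""Fully convolutional reconstruction network and its training loop.

The network maps a normalized N x N frequency-domain amplitude matrix
directly to a velocity map: an input layer, four hidden convolution layers
(same-padded cross-correlation, each followed by a leaky ReLU), one max
pooling layer, a deterministic bilinear resize to the output (x, y) extent,
and a convolutional output head whose kernel count equals the number of
z-slices of the output grid (one kernel for a 2D map). Training minimizes
the mean squared error between predicted and true velocity maps (on a
min-max-normalized velocity scale) with Adam, mini-batches of 8, up to 5000
epochs and early stopping after 500 epochs without validation improvement —
the published training protocol.

Everything here is plain numpy: the convolution layers reduce to im2col +
matrix products with hand-written backpropagation, and ``conv2d_ref`` /
``max_pool`` / ``mse_loss`` expose the exact layer semantics as simple
reference functions that serve as oracles for the batched fast path.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "SplitIndices",
    "Model",
    "conv2d_ref",
    "leaky_relu",
    "max_pool",
    "build_network",
    "mse_loss",
    "split_dataset",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference ops (oracle semantics)
# ---------------------------------------------------------------------------

def leaky_relu(x, slope: float = 0.01):
    """x for x >= 0, slope * x otherwise."""
    if not (0 <= slope < 1):
        raise ValueError("slope must lie in [0, 1)")
    x = np.asarray(x)
    return np.where(x >= 0, x, slope * x)


def conv2d_ref(
    image: np.ndarray,
    kernel: np.ndarray,
    bias: float = 0.0,
    activation_slope: Optional[float] = 0.01,
) -> np.ndarray:
    """Single-channel same-padded cross-correlation followed by a leaky ReLU.

    out[m, n] = R( sum_{u,v} w[u, v] * S[m + u - L//2, n + v - L//2] + B )

    with zeros outside the image. This is the layer semantics of the network;
    the batched multi-channel path is tested against it.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError("kernel must be square")
    L = kernel.shape[0]
    if L % 2 == 0:
        raise ValueError("kernel size must be odd")
    if image.ndim != 2 or min(image.shape) < 1 or L > 2 * min(image.shape):
        raise ValueError("image must be 2D and not much smaller than the kernel")
    p = L // 2
    padded = np.pad(image, p)
    out = np.empty_like(image)
    H, W = image.shape
    for m in range(H):
        for n in range(W):
            out[m, n] = np.sum(kernel * padded[m : m + L, n : n + L]) + bias
    if activation_slope is not None:
        out = leaky_relu(out, activation_slope)
    return out


def max_pool(image: np.ndarray, window: int, stride: Optional[int] = None) -> np.ndarray:
    """Per-window maximum; stride defaults to the window (non-overlapping).

    Only full windows are evaluated; partial windows at the far edges are
    truncated away, so the output extent is floor((n - window)/stride) + 1.
    """
    image = np.asarray(image)
    stride = window if stride is None else stride
    if window < 1 or stride < 1 or window > min(image.shape[-2:]):
        raise ValueError("window must fit inside the image")
    win = sliding_window_view(image, (window, window), axis=(-2, -1))
    win = win[..., ::stride, ::stride, :, :]
    return win.max(axis=(-2, -1))


def mse_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean over all entries of the squared difference."""
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    d = pred.astype(np.float64) - label.astype(np.float64)
    return float(np.mean(d * d))


# ---------------------------------------------------------------------------
# specs and configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``hidden`` lists (kernel_count, kernel_size) per hidden convolution layer;
    the max-pool sits after hidden layer ``pool_after`` (1-based). The output
    head is a convolution with ``output_grid[2]`` kernels — one per z-slice of
    the reconstructed volume (z=1 for a 2D map). A deterministic bilinear
    resize bridges the pooled N x N extent to the output (x, y) extent; it
    sits after hidden layer ``resize_after`` (default: after the last one).
    Placing it earlier lets the remaining hidden layers run at output
    resolution, which helps when the output grid is finer than the pooled
    sensor grid.
    """

    input_size: int
    input_channels: int = 1
    hidden: Tuple[Tuple[int, int], ...] = ((32, 9), (64, 7), (64, 5), (32, 3))
    pool_window: int = 2
    pool_stride: int = 2
    pool_after: int = 2
    leaky_slope: float = 0.01
    output_grid: Tuple[int, int, int] = (48, 48, 1)  # (x, y, z)
    output_kernel_size: int = 3
    resize_after: Optional[int] = None  # hidden layer index; None -> after the last

    def __post_init__(self) -> None:
        if self.input_size < 4:
            raise ValueError("input_size too small")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")
        if len(self.hidden) != 4:
            warnings.warn(
                f"{len(self.hidden)} hidden convolution layers configured "
                "(the reference architecture uses 4)",
                stacklevel=2,
            )
        for cnt, k in self.hidden:
            if cnt < 1 or k < 1 or k % 2 == 0:
                raise ValueError("hidden layers need positive counts and odd kernel sizes")
        if self.output_kernel_size % 2 == 0:
            raise ValueError("output kernel size must be odd")
        if not (1 <= self.pool_after <= len(self.hidden)):
            raise ValueError("pool_after must index a hidden layer")
        if self.resize_after is not None and not (
            self.pool_after <= self.resize_after <= len(self.hidden)
        ):
            raise ValueError("resize_after must lie between pool_after and the last layer")
        if len(self.output_grid) != 3 or min(self.output_grid) < 1:
            raise ValueError("output_grid must be (x, y, z) with positive extents")

    @property
    def output_channels(self) -> int:
        """Output-head kernel count == number of z-slices."""
        return int(self.output_grid[2])


@dataclass(frozen=True)
class TrainConfig:
    """The training protocol (defaults are the published settings)."""

    batch_size: int = 8
    max_epochs: int = 5000
    early_stop_patience: int = 500
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    weight_init: str = "uniform01"  # "uniform01" (positive, published protocol) | "scaled"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.early_stop_patience < self.max_epochs):
            raise ValueError("patience must be < max_epochs")
        if self.weight_init not in ("uniform01", "scaled"):
            raise ValueError("weight_init must be 'uniform01' or 'scaled'")


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index sets covering all samples."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    ratios: Tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train, self.validation, self.test])
        if np.unique(allidx).size != allidx.size:
            raise ValueError("split index sets overlap")


def split_dataset(
    n_samples: int,
    ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitIndices:
    """Shuffle and split by the documented rounding rule.

    train = floor(r_train * n); of the remainder r, validation = ceil of its
    validation share, test gets the rest. For (0.6, 0.2, 0.2): n=700 gives
    420/140/140 and n=401 gives 240/81/80.
    """
    if n_samples < 5:
        raise ValueError("need at least 5 samples to split")
    rt, rv, rte = ratios
    if min(ratios) < 0 or not math.isclose(rt + rv + rte, 1.0, rel_tol=1e-9):
        raise ValueError("ratios must be non-negative and sum to 1")
    perm = np.random.default_rng(seed).permutation(n_samples)
    n_train = int(math.floor(rt * n_samples))
    rem = n_samples - n_train
    n_val = int(math.ceil(rem * rv / (rv + rte)))
    return SplitIndices(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
        ratios=ratios,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fast layers (im2col) with backprop
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patches under same zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    B, C, H, W = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)


class _ConvLayer:
    """Same-padded multi-channel cross-correlation + optional leaky ReLU."""

    def __init__(self, W: np.ndarray, b: np.ndarray, slope: Optional[float]):
        self.W = W  # (Cout, Cin, k, k)
        self.b = b  # (Cout,)
        self.slope = slope
        self._cols = None
        self._mask = None
        self._in_shape = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        B, C, H, Wd = x.shape
        Cout, Cin, k, _ = self.W.shape
        if C != Cin:
            raise ValueError(f"channel mismatch: input {C}, kernel expects {Cin}")
        cols = _im2col(x, k)
        y = cols @ self.W.reshape(Cout, -1).T + self.b
        y = y.reshape(B, H, Wd, Cout).transpose(0, 3, 1, 2)
        neg = None
        if self.slope is not None:
            neg = y < 0
            y = np.where(neg, self.slope * y, y)
        if keep:
            self._cols, self._in_shape = cols, x.shape
            self._mask = neg
        return y

    def backward(self, dy: np.ndarray):
        B, C, H, Wd = self._in_shape
        Cout, Cin, k, _ = self.W.shape
        if self._mask is not None:
            dy = np.where(self._mask, self.slope * dy, dy)
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, Cout)
        dW = (dyf.T @ self._cols).reshape(self.W.shape)
        db = dyf.sum(axis=0)
        # dx: same-padded correlation of dy with channel-transposed, flipped W
        Wt = np.ascontiguousarray(self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        cols_dy = _im2col(dy, k)
        dx = (cols_dy @ Wt.reshape(Cin, -1).T).reshape(B, H, Wd, Cin).transpose(0, 3, 1, 2)
        self._cols = self._mask = None
        return dx, [dW, db]


class _PoolLayer:
    """Non-overlapping max pool (window == stride) with argmax routing."""

    def __init__(self, window: int, stride: int):
        if stride != window:
            raise ValueError("in-network pooling supports stride == window")
        self.window = window
        self._arg = None
        self._in_shape = None

    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        w = self.window
        B, C, H, Wd = x.shape
        Ho, Wo = H // w, Wd // w
        xt = x[:, :, : Ho * w, : Wo * w].reshape(B, C, Ho, w, Wo, w)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, w * w)
        arg = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, arg[..., None], axis=-1)[..., 0]
        if keep:
            self._arg, self._in_shape = arg, x.shape
        return y

    def backward(self, dy: np.ndarray):
        w = self.window
        B, C, H, Wd = self._in_shape
        Ho, Wo = H // w, Wd // w
        dxt = np.zeros((B, C, Ho, Wo, w * w), dtype=dy.dtype)
        np.put_along_axis(dxt, self._arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros((B, C, H, Wd), dtype=dy.dtype)
        dx[:, :, : Ho * w, : Wo * w] = (
            dxt.reshape(B, C, Ho, Wo, w, w).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * w, Wo * w)
        )
        self._arg = None
        return dx, []


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic 1D bilinear interpolation matrix (cell-center aligned)."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    M[np.arange(n_out), lo] += 1.0 - frac
    M[np.arange(n_out), hi] += frac
    return M


class _ResizeLayer:
    """Deterministic bilinear resize between pooled and output extents."""

    def __init__(self, in_hw: Tuple[int, int], out_hw: Tuple[int, int], dtype):
        self.Ry = _bilinear_matrix(out_hw[0], in_hw[0], dtype)
        self.Rx = _bilinear_matrix(out_hw[1], in_hw[1], dtype)

    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        return np.einsum("oh,bchw,pw->bcop", self.Ry, x, self.Rx, optimize=True)

    def backward(self, dy: np.ndarray):
        # adjoint of the interpolation: Ry^T dY Rx
        dx = np.einsum("oh,bcop,pw->bchw", self.Ry, dy, self.Rx, optimize=True)
        return dx, []


class Model:
    """The fully convolutional reconstruction network.

    Holds architecture, weights, training history, the best-epoch index and
    the velocity bounds used to normalize labels (None until trained).
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, weight_init: str = "uniform01",
                 dtype: str = "float32"):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.history: dict = {"train_mse": [], "val_mse": []}
        self.best_epoch: Optional[int] = None
        self.velocity_bounds: Optional[Tuple[float, float]] = None

        rng = np.random.default_rng(seed)
        nx, ny, nz = spec.output_grid
        resize_at = spec.resize_after if spec.resize_after is not None else len(spec.hidden)
        self.layers: list = []
        c_in = spec.input_channels
        hw = spec.input_size
        for li, (cnt, k) in enumerate(spec.hidden, start=1):
            self.layers.append(self._make_conv(rng, cnt, c_in, k, spec.leaky_slope, weight_init))
            c_in = cnt
            if li == spec.pool_after:
                self.layers.append(_PoolLayer(spec.pool_window, spec.pool_stride))
                hw = hw // spec.pool_window
            if li == resize_at:
                self.layers.append(_ResizeLayer((hw, hw), (nx, ny), self.dtype))
        self.layers.append(
            self._make_conv(rng, nz, c_in, spec.output_kernel_size, None, weight_init)
        )

    def _make_conv(self, rng, c_out, c_in, k, slope, init):
        if init == "uniform01":
            W = rng.uniform(0.0, 1.0, size=(c_out, c_in, k, k))
        elif init == "scaled":
            bound = math.sqrt(6.0 / (c_in * k * k))
            W = rng.uniform(-bound, bound, size=(c_out, c_in, k, k))
        else:
            raise ValueError(f"unknown weight_init {init!r}")
        return _ConvLayer(W.astype(self.dtype), np.zeros(c_out, dtype=self.dtype), slope)

    # -- forward / backward over normalized scales --------------------------

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        """x: (B, 1, N, N) normalized features -> (B, z, nx, ny) normalized maps."""
        y = x
        for layer in self.layers:
            y = layer.forward(y, keep=keep)
        return y

    def backward(self, dy: np.ndarray) -> list:
        grads: list = []
        for layer in reversed(self.layers):
            dy, g = layer.backward(dy)
            grads[:0] = g
        return grads

    @property
    def parameters(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def get_weights(self) -> list:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters
        if len(params) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p[...] = w


def build_network(spec: NetworkSpec, seed: int = 0, weight_init: str = "uniform01",
                dtype: str = "float32") -> Model:
    """Instantiate the untrained network; deterministic under ``seed``.

    The default weight initialization draws every kernel weight uniformly from
    (0, 1) — the published protocol; ``weight_init='scaled'`` switches to a
    conventional symmetric fan-in-scaled initialization.
    """
    return Model(spec, seed=seed, weight_init=weight_init, dtype=dtype)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_feature_array(features, spec: NetworkSpec, dtype) -> np.ndarray:
    arrs = []
    for f in features:
        v = f.values if hasattr(f, "values") else np.asarray(f)
        v = np.asarray(v, dtype=dtype)
        if v.ndim == 2:
            v = v[None, :, :]
        arrs.append(v)
    X = np.stack(arrs)
    if X.shape[-1] != spec.input_size or X.shape[1] != spec.input_channels:
        raise ValueError(
            f"feature shape {X.shape[1:]} != network input "
            f"({spec.input_channels}, {spec.input_size}, {spec.input_size})"
        )
    return X


def _as_label_array(labels, spec: NetworkSpec, dtype) -> np.ndarray:
    nx, ny, nz = spec.output_grid
    arrs = []
    for lab in labels:
        a = np.asarray(lab, dtype=dtype)
        if a.ndim == 2:
            a = a[None, :, :]
        elif a.ndim == 3:
            a = np.moveaxis(a, 2, 0)  # (nx, ny, nz) -> (nz, nx, ny)
        if a.shape != (nz, nx, ny):
            raise ValueError(f"label shape {a.shape} != output grid (z,x,y)=({nz},{nx},{ny})")
        arrs.append(a)
    return np.stack(arrs)


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    model: Model,
    features: Sequence,
    labels: Sequence[np.ndarray],
    split: SplitIndices,
    cfg: TrainConfig,
    progress: Optional[Callable[[int, float, float], None]] = None,
) -> Model:
    """Fit the network by Adam on mini-batches; early-stop on validation MSE.

    Labels are min-max normalized to [0, 1] with bounds taken over the
    *training* labels (stored on the model for de-normalization at predict
    time). The returned model carries the weights of the epoch with the
    lowest validation MSE and the full per-epoch history.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must be aligned")
    dtype = np.dtype(cfg.dtype)
    X = _as_feature_array(features, model.spec, dtype)
    Y = _as_label_array(labels, model.spec, dtype)

    tr, va = split.train, split.validation
    vmin = float(Y[tr].min())
    vmax = float(Y[tr].max())
    if vmax <= vmin:
        raise ValueError("degenerate labels: constant velocity over the training set")
    model.velocity_bounds = (vmin, vmax)
    Yn = (Y - vmin) / (vmax - vmin)

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)

    best_val = math.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0
    hist_tr: List[float] = []
    hist_va: List[float] = []

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(tr)
        run_loss = 0.0
        n_seen = 0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Yn[idx]
            pred = model.forward(xb, keep=True)
            diff = pred - yb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not math.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (non-finite loss)")
            run_loss += loss * idx.size
            n_seen += idx.size
            dy = (2.0 / diff.size) * diff
            grads = model.backward(dy.astype(dtype))
            opt.step(model.parameters, grads)
        train_mse = run_loss / max(n_seen, 1)

        val_pred = model.forward(X[va])
        val_mse = float(np.mean((val_pred.astype(np.float64) - Yn[va]) ** 2))
        if not math.isfinite(val_mse):
            raise RuntimeError(f"training diverged at epoch {epoch} (non-finite validation loss)")
        hist_tr.append(train_mse)
        hist_va.append(val_mse)
        if progress is not None:
            progress(epoch, train_mse, val_mse)

        if val_mse < best_val:
            best_val = val_mse
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    model.set_weights(best_weights)
    model.history = {"train_mse": hist_tr, "val_mse": hist_va}
    model.best_epoch = best_epoch
    return model


def predict(model: Model, feature) -> np.ndarray:
    """Reconstruct a velocity map (m/s) from one normalized feature matrix.

    Returns (nx, ny) for a 2D network (z=1) and (nx, ny, nz) otherwise;
    outputs are de-normalized with the stored velocity bounds and clipped to
    them.
    """
    if model.velocity_bounds is None:
        raise ValueError("model has not been trained (no velocity bounds)")
    v = feature.values if hasattr(feature, "values") else np.asarray(feature)
    v = np.asarray(v, dtype=model.dtype)
    if v.ndim == 2:
        v = v[None, :, :]
    expected = (model.spec.input_channels, model.spec.input_size, model.spec.input_size)
    if v.shape != expected:
        raise ValueError(f"feature shape {v.shape} != expected {expected}")
    out = model.forward(v[None])[0]  # (z, nx, ny)
    vmin, vmax = model.velocity_bounds
    out = np.clip(out.astype(np.float64), 0.0, 1.0) * (vmax - vmin) + vmin
    if model.spec.output_grid[2] == 1:
        return out[0]
    return np.moveaxis(out, 0, 2)  # (nx, ny, nz)
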