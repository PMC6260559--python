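"""Depth-D fully convolutional residual predictor, implemented in numpy.

The architecture is the VGG-style denoising stack used for residual
artifact learning: layer 1 is conv+ReLU, layers 2..D-1 are
conv+BatchNorm+ReLU, and layer D is a plain convolution producing a single
output channel.  All convolutions are 3x3 (configurable, odd) with zero
padding, so every feature map keeps the input size and the network applies
unchanged to 50x50 training patches and full 512x512 slices.

Both the forward pass and analytic backpropagation are implemented here;
gradients are validated against central finite differences in the test
suite.  Weights are Xavier-uniform initialized,
``W ~ U(-b, b), b = sqrt(6 / (fan_in + fan_out))`` with conv fans
``k^2 * channels``, and all biases start at zero.

Internally activations are laid out (N, C, H, W) and the convolutions run
as direct vectorized stencils (numba-compiled when available, im2col
otherwise); parameters keep the conventional (k, k, C_in, C_out) layout.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "NetworkSpec",
    "TrainState",
    "relu",
    "init_weights",
    "forward",
    "backward",
    "param_count",
    "save_checkpoint",
    "load_checkpoint",
    "hu_to_unit",
    "unit_to_hu",
    "DEFAULT_WINDOW",
]

#: HU display window mapped onto [0, 1] at the network boundary.
DEFAULT_WINDOW = (-1000.0, 3000.0)

BN_EPS = 1e-5
BN_MOMENTUM = 0.1  # running <- (1 - mom) * running + mom * batch


def relu(x, slope: float = 0.0):
    """Rectifier max(0, x); ``slope`` > 0 gives the leaky variant."""
    x = np.asarray(x)
    if slope == 0.0:
        return np.maximum(x, 0.0)
    return np.where(x > 0, x, x * np.asarray(slope, dtype=x.dtype))


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    The default depth 17 gives a receptive field of 2*(D-1)*(k//2)+1 = 33
    pixels, inside the 50-pixel training patch; scaled-down studies use a
    shallower, narrower net.
    """

    depth: int = 17
    n_filters: int = 64
    kernel: int = 3
    bn_enabled: bool = True
    leaky_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 3:
            raise ValueError("depth must be at least 3")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.n_filters < 1:
            raise ValueError("n_filters must be positive")

    @property
    def receptive_field(self) -> int:
        return 2 * (self.depth - 1) * (self.kernel // 2) + 1

    def layer_channels(self) -> list[tuple[int, int]]:
        """(C_in, C_out) per layer, 1 -> F -> ... -> F -> 1."""
        chans = [(1, self.n_filters)]
        chans += [(self.n_filters, self.n_filters)] * (self.depth - 2)
        chans += [(self.n_filters, 1)]
        return chans

    def bn_layers(self) -> list[int]:
        """1-based indices of layers carrying batch normalization (2..D-1)."""
        return list(range(2, self.depth)) if self.bn_enabled else []


@dataclass
class TrainState:
    """Network parameters plus everything needed to resume training."""

    spec: NetworkSpec
    params: dict[str, np.ndarray]  # W{d} (k,k,Cin,Cout), b{d}, gamma{d}, beta{d}
    bn_running: dict[str, np.ndarray]  # mean{d}, var{d}
    adam_m: dict[str, np.ndarray] = field(default_factory=dict)
    adam_v: dict[str, np.ndarray] = field(default_factory=dict)
    adam_t: int = 0
    epoch: int = 0
    rng_seed: int = 0
    mode: str = "residual"  # learning target convention: residual | ordinary

    def check_finite(self) -> bool:
        return all(np.all(np.isfinite(v)) for v in self.params.values())


def param_count(spec: NetworkSpec) -> int:
    """Closed-form trainable parameter count (conv weights, biases, BN affine)."""
    k2 = spec.kernel**2
    n = 0
    for d, (cin, cout) in enumerate(spec.layer_channels(), start=1):
        n += k2 * cin * cout + cout
        if d in spec.bn_layers():
            n += 2 * cout
    return n


def init_weights(spec: NetworkSpec, seed: int, dtype=np.float64) -> TrainState:
    """Xavier-uniform weights, zero biases, identity batch-norm statistics."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    running: dict[str, np.ndarray] = {}
    k = spec.kernel
    for d, (cin, cout) in enumerate(spec.layer_channels(), start=1):
        fan_in = k * k * cin
        fan_out = k * k * cout
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        params[f"W{d}"] = ((rng.random((k, k, cin, cout)) - 0.5) * 2.0 * bound).astype(dtype)
        params[f"b{d}"] = np.zeros(cout, dtype=dtype)
        if d in spec.bn_layers():
            params[f"gamma{d}"] = np.ones(cout, dtype=dtype)
            params[f"beta{d}"] = np.zeros(cout, dtype=dtype)
            running[f"mean{d}"] = np.zeros(cout, dtype=dtype)
            running[f"var{d}"] = np.ones(cout, dtype=dtype)
    return TrainState(spec=spec, params=params, bn_running=running, rng_seed=seed)


# ---------------------------------------------------------------------------
# Convolution primitives (NCHW stencils)
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _nb_conv_fwd(xp, W, out):  # pragma: no cover - compiled
        n, cin, hp, wp = xp.shape
        cout, _, k, _ = W.shape
        h = hp - (k - 1)
        w = wp - (k - 1)
        for im in range(n):
            for f in range(cout):
                for c in range(cin):
                    for i in range(k):
                        if k == 3:  # unrolled 3-tap stencil fast path
                            w0 = W[f, c, i, 0]
                            w1 = W[f, c, i, 1]
                            w2 = W[f, c, i, 2]
                            for y in range(h):
                                xr = xp[im, c, y + i]
                                orow = out[im, f, y]
                                for x in range(w):
                                    orow[x] += w0 * xr[x] + w1 * xr[x + 1] + w2 * xr[x + 2]
                        else:
                            for j in range(k):
                                wv = W[f, c, i, j]
                                for y in range(h):
                                    xr = xp[im, c, y + i]
                                    orow = out[im, f, y]
                                    for x in range(w):
                                        orow[x] += wv * xr[x + j]

    @njit(cache=True, fastmath=True)
    def _nb_conv_bwd_dx(dout, W, dxp):  # pragma: no cover - compiled
        n, cout, h, w = dout.shape
        _, cin, k, _ = W.shape
        for im in range(n):
            for f in range(cout):
                for c in range(cin):
                    for i in range(k):
                        for j in range(k):
                            # fixed (i, j): shifted stores never overlap
                            wv = W[f, c, i, j]
                            for y in range(h):
                                g = dout[im, f, y]
                                dr = dxp[im, c, y + i]
                                for x in range(w):
                                    dr[x + j] += wv * g[x]

    @njit(cache=True, fastmath=True)
    def _nb_conv_bwd_dw(dout, xp, dW):  # pragma: no cover - compiled
        n, cout, h, w = dout.shape
        _, cin, k, _ = dW.shape
        for im in range(n):
            for f in range(cout):
                for c in range(cin):
                    for i in range(k):
                        if k == 3:  # three independent reduction chains
                            a0 = 0.0
                            a1 = 0.0
                            a2 = 0.0
                            for y in range(h):
                                g = dout[im, f, y]
                                xr = xp[im, c, y + i]
                                for x in range(w):
                                    gv = g[x]
                                    a0 += gv * xr[x]
                                    a1 += gv * xr[x + 1]
                                    a2 += gv * xr[x + 2]
                            dW[f, c, i, 0] += a0
                            dW[f, c, i, 1] += a1
                            dW[f, c, i, 2] += a2
                        else:
                            for j in range(k):
                                acc = 0.0
                                for y in range(h):
                                    g = dout[im, f, y]
                                    xr = xp[im, c, y + i]
                                    for x in range(w):
                                        acc += g[x] * xr[x + j]
                                dW[f, c, i, j] += acc


def _kernel_layout(W: np.ndarray) -> np.ndarray:
    """(k,k,Cin,Cout) parameter layout -> (Cout,Cin,k,k) compute layout."""
    return np.ascontiguousarray(W.transpose(3, 2, 0, 1))


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-size 2-D convolution; x is (N,Cin,H,W), W is (k,k,Cin,Cout)."""
    k = W.shape[0]
    p = k // 2
    n, cin, h, w = x.shape
    cout = W.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    Wk = _kernel_layout(W)
    out = np.empty((n, cout, h, w), dtype=x.dtype)
    out[:] = b.astype(x.dtype)[None, :, None, None]
    if _HAVE_NUMBA:
        _nb_conv_fwd(xp, Wk, out)
    else:
        for i in range(k):
            for j in range(k):
                out += np.einsum(
                    "nchw,fc->nfhw", xp[:, :, i : i + h, j : j + w], Wk[:, :, i, j]
                ).astype(x.dtype)
    return out, xp


def _conv_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray):
    k = W.shape[0]
    p = k // 2
    n, cout, h, w = dout.shape
    cin = W.shape[2]
    Wk = _kernel_layout(W)
    dxp = np.zeros_like(xp)
    dWk = np.zeros_like(Wk)
    if _HAVE_NUMBA:
        _nb_conv_bwd_dx(dout, Wk, dxp)
        _nb_conv_bwd_dw(dout, xp, dWk)
    else:
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "nfhw,fc->nchw", dout, Wk[:, :, i, j]
                ).astype(xp.dtype)
                dWk[:, :, i, j] = np.einsum(
                    "nfhw,nchw->fc", dout, xp[:, :, i : i + h, j : j + w]
                ).astype(xp.dtype)
    db = dout.sum(axis=(0, 2, 3))
    dx = dxp[:, :, p : p + h, p : p + w]
    dW = np.ascontiguousarray(dWk.transpose(2, 3, 1, 0))
    return dx, dW, db


# ---------------------------------------------------------------------------
# Batch normalization (per channel over N, H, W)
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _nb_bn_stats(x, mean, var):  # pragma: no cover - compiled
        n, c, h, w = x.shape
        m = n * h * w
        for ci in range(c):
            s = 0.0
            sq = 0.0
            for im in range(n):
                for y in range(h):
                    row = x[im, ci, y]
                    for xi in range(w):
                        v = row[xi]
                        s += v
                        sq += v * v
            mu = s / m
            mean[ci] = mu
            var[ci] = sq / m - mu * mu

    @njit(cache=True, fastmath=True)
    def _nb_bn_normalize(x, mean, inv_std, gamma, beta, xhat, out):  # pragma: no cover
        n, c, h, w = x.shape
        for ci in range(c):
            mu = mean[ci]
            inv = inv_std[ci]
            g = gamma[ci]
            b = beta[ci]
            for im in range(n):
                for y in range(h):
                    row = x[im, ci, y]
                    xh = xhat[im, ci, y]
                    orow = out[im, ci, y]
                    for xi in range(w):
                        v = (row[xi] - mu) * inv
                        xh[xi] = v
                        orow[xi] = g * v + b

    @njit(cache=True, fastmath=True)
    def _nb_bn_backward(dout, xhat, gamma, inv_std, dx, dgamma, dbeta):  # pragma: no cover
        n, c, h, w = dout.shape
        m = n * h * w
        for ci in range(c):
            dg = 0.0
            db = 0.0
            for im in range(n):
                for y in range(h):
                    g_row = dout[im, ci, y]
                    xh = xhat[im, ci, y]
                    for xi in range(w):
                        dg += g_row[xi] * xh[xi]
                        db += g_row[xi]
            dgamma[ci] = dg
            dbeta[ci] = db
            scale = inv_std[ci] * gamma[ci]
            c1 = db / m
            c2 = dg / m
            for im in range(n):
                for y in range(h):
                    g_row = dout[im, ci, y]
                    xh = xhat[im, ci, y]
                    dr = dx[im, ci, y]
                    for xi in range(w):
                        dr[xi] = scale * (g_row[xi] - c1 - xh[xi] * c2)


def _bn_forward(x, gamma, beta, running_mean, running_var, train: bool):
    if not train:
        # fold into one scale/shift per channel using running statistics
        inv_std = (1.0 / np.sqrt(running_var + BN_EPS)).astype(x.dtype)
        a = gamma.astype(x.dtype) * inv_std
        b = beta.astype(x.dtype) - a * running_mean.astype(x.dtype)
        y = a[None, :, None, None] * x + b[None, :, None, None]
        return y, (None, inv_std), (running_mean, running_var)
    if _HAVE_NUMBA:
        c = x.shape[1]
        mean = np.empty(c, dtype=x.dtype)
        var = np.empty(c, dtype=x.dtype)
        _nb_bn_stats(x, mean, var)
        inv_std = (1.0 / np.sqrt(var + BN_EPS)).astype(x.dtype)
        xhat = np.empty_like(x)
        y = np.empty_like(x)
        _nb_bn_normalize(
            x, mean, inv_std, gamma.astype(x.dtype), beta.astype(x.dtype), xhat, y
        )
    else:
        axes = (0, 2, 3)
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        inv_std = (1.0 / np.sqrt(var + BN_EPS)).astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = (
            gamma.astype(x.dtype)[None, :, None, None] * xhat
            + beta.astype(x.dtype)[None, :, None, None]
        )
    new_rm = (1 - BN_MOMENTUM) * running_mean + BN_MOMENTUM * mean
    new_rv = (1 - BN_MOMENTUM) * running_var + BN_MOMENTUM * var
    return y, (xhat, inv_std), (new_rm, new_rv)


def _bn_backward(dout, cache, gamma):
    xhat, inv_std = cache
    if _HAVE_NUMBA:
        c = dout.shape[1]
        dx = np.empty_like(dout)
        dgamma = np.empty(c, dtype=dout.dtype)
        dbeta = np.empty(c, dtype=dout.dtype)
        _nb_bn_backward(
            dout, xhat, gamma.astype(dout.dtype), inv_std.astype(dout.dtype), dx, dgamma, dbeta
        )
        return dx, dgamma, dbeta
    axes = (0, 2, 3)
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma.astype(dout.dtype)[None, :, None, None]
    dx = (inv_std[None, :, None, None] / m) * (
        m * dxhat
        - dxhat.sum(axis=axes)[None, :, None, None]
        - xhat * (dxhat * xhat).sum(axis=axes)[None, :, None, None]
    )
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# Full network forward / backward
# ---------------------------------------------------------------------------


def _as_batch(x: np.ndarray, dtype) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=dtype)
    if x.ndim == 2:
        return x[None, None, :, :], True
    if x.ndim == 3:
        return x[:, None, :, :], False
    raise ValueError("input must be (H, W) or (N, H, W), single channel")


def forward(state: TrainState, x: np.ndarray, mode: str = "eval", want_cache: bool = False):
    """Run the network on a patch/image or batch thereof.

    ``mode='train'`` uses batch statistics in the BN layers and updates the
    running statistics in place; ``mode='eval'`` uses the stored running
    statistics and is deterministic.  Returns the prediction with the same
    shape as the input (and a backprop cache when ``want_cache``).
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    spec = state.spec
    dtype = state.params["W1"].dtype
    a, squeeze = _as_batch(x, dtype)
    if min(a.shape[2], a.shape[3]) < spec.kernel:
        raise ValueError("input smaller than the convolution kernel")
    train = mode == "train"
    bn_layers = set(spec.bn_layers())
    cache: list[dict] = []
    for d in range(1, spec.depth + 1):
        y, xp = _conv_forward(a, state.params[f"W{d}"], state.params[f"b{d}"])
        entry: dict = {"xp": xp}
        if d in bn_layers:
            y, bn_cache, (rm, rv) = _bn_forward(
                y,
                state.params[f"gamma{d}"],
                state.params[f"beta{d}"],
                state.bn_running[f"mean{d}"],
                state.bn_running[f"var{d}"],
                train,
            )
            entry["bn"] = bn_cache
            if train:
                state.bn_running[f"mean{d}"] = rm
                state.bn_running[f"var{d}"] = rv
        if d < spec.depth:
            entry["pre"] = y
            y = relu(y, spec.leaky_slope)
        a = y
        cache.append(entry if want_cache else {})
    out = a[:, 0]
    if squeeze:
        out = out[0]
    return (out, cache) if want_cache else out


def backward(state: TrainState, cache: list[dict], dout: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate d(loss)/d(output) through a cached forward pass."""
    spec = state.spec
    if dout.ndim == 2:
        dout = dout[None]
    da = np.ascontiguousarray(
        np.asarray(dout, dtype=state.params["W1"].dtype)[:, None, :, :]
    )
    grads: dict[str, np.ndarray] = {}
    bn_layers = set(spec.bn_layers())
    slope = spec.leaky_slope
    for d in range(spec.depth, 0, -1):
        entry = cache[d - 1]
        if d < spec.depth:
            pre = entry["pre"]
            if slope == 0.0:
                da = da * (pre > 0)
            else:
                da = np.where(pre > 0, da, da * np.asarray(slope, dtype=da.dtype))
        if d in bn_layers:
            da, dg, db_ = _bn_backward(da, entry["bn"], state.params[f"gamma{d}"])
            grads[f"gamma{d}"] = dg
            grads[f"beta{d}"] = db_
        da, dW, db = _conv_backward(np.ascontiguousarray(da), entry["xp"], state.params[f"W{d}"])
        grads[f"W{d}"] = dW
        grads[f"b{d}"] = db
    return grads


# ---------------------------------------------------------------------------
# HU <-> network scale
# ---------------------------------------------------------------------------


def hu_to_unit(values: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Clip to the HU window and map linearly onto [0, 1]."""
    lo, hi = window
    return (np.clip(values, lo, hi) - lo) / (hi - lo)


def unit_to_hu(values: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    lo, hi = window
    return values * (hi - lo) + lo


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Self-describing .npz checkpoint; round-trips bit-exactly."""
    meta = {
        "spec": vars(state.spec),
        "adam_t": state.adam_t,
        "epoch": state.epoch,
        "rng_seed": state.rng_seed,
        "mode": state.mode,
    }
    arrays = {}
    for prefix, d in (
        ("p_", state.params),
        ("r_", state.bn_running),
        ("m_", state.adam_m),
        ("v_", state.adam_v),
    ):
        for k, v in d.items():
            arrays[prefix + k] = v
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainState:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        groups: dict[str, dict[str, np.ndarray]] = {"p_": {}, "r_": {}, "m_": {}, "v_": {}}
        for k in z.files:
            if k == "meta":
                continue
            groups[k[:2]][k[2:]] = z[k]
    return TrainState(
        spec=NetworkSpec(**meta["spec"]),
        params=groups["p_"],
        bn_running=groups["r_"],
        adam_m=groups["m_"],
        adam_v=groups["v_"],
        adam_t=meta["adam_t"],
        epoch=meta["epoch"],
        rng_seed=meta["rng_seed"],
        mode=meta["mode"],
    )
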