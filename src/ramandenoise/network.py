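"""Fully convolutional 1D denoising network.

Five convolutional units, stride 1, same padding, so every feature map keeps
the input width (600 samples by default).  Units 1-4 are convolution →
batch normalization → ReLU; the final unit is a linear convolution whose
kernel spans the whole spectrum.  Filter counts and widths:

    unit 1: 256 filters, width 9
    unit 2: 128 filters, width 5
    unit 3:  64 filters, width 5
    unit 4:   1 filter,  width 9
    unit 5:   1 filter,  width 600 (linear)

The network consumes raw intensities (0-4000 counts scale); no input
normalization is applied by default.

Implementation notes.  Layers are implemented directly on NumPy with
hand-derived gradients (verified against finite differences in the test
suite).  Convolutions pick a strategy from the layer dimensions: narrow
multi-channel kernels run as k shifted batched matmuls on strided views,
single-channel kernels with few taps run as one im2col matmul, and the
full-width single-channel output layer runs through FFT convolution.  All
large intermediates live in per-layer buffers that are reused across
mini-batches, which keeps the training loop close to BLAS-bound.  float32 is
the default dtype for throughput; float64 is available for verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import fftconvolve

from .spectra import Spectrum

try:  # optional JIT for the memory-bound batch-norm passes
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco


@_njit(cache=False, fastmath=False)
def _bn_backward_fused(x2d, g2d, mean, inv_std, gamma, gx2d):
    """Fused batch-norm backward: returns (Σg, Σg·x̂) and fills gx2d."""
    m, c = x2d.shape
    sum_g = np.zeros(c, dtype=np.float64)
    sum_gx = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            g = np.float64(g2d[i, j])
            xh = (np.float64(x2d[i, j]) - mean[j]) * inv_std[j]
            sum_g[j] += g
            sum_gx[j] += g * xh
    a = np.empty(c, dtype=np.float64)
    b = np.empty(c, dtype=np.float64)
    d = np.empty(c, dtype=np.float64)
    for j in range(c):
        a[j] = gamma[j] * inv_std[j]
        b[j] = -gamma[j] * inv_std[j] * inv_std[j] * sum_gx[j] / m
        d[j] = -gamma[j] * inv_std[j] * sum_g[j] / m
    for i in range(m):
        for j in range(c):
            gx2d[i, j] = (a[j] * g2d[i, j]
                          + b[j] * (np.float64(x2d[i, j]) - mean[j])
                          + d[j])
    return sum_g, sum_gx

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "default_network_spec",
    "count_parameters",
    "build_network",
    "DenoiserCNN",
    "denoise",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional unit: filters, kernel width, and whether BN+ReLU follow."""

    index: int
    n_filters: int
    filter_width: int
    has_batchnorm_relu: bool

    def __post_init__(self) -> None:
        if self.n_filters < 1 or self.filter_width < 1:
            raise ValueError("n_filters and filter_width must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Input length plus the ordered list of convolutional units."""

    input_length: int = 600
    layers: Sequence[LayerSpec] = field(default_factory=lambda: _TABLE_LAYERS)

    def __post_init__(self) -> None:
        if self.input_length < 1:
            raise ValueError("input_length must be positive")
        if not self.layers:
            raise ValueError("network needs at least one layer")
        for i, layer in enumerate(self.layers, start=1):
            if layer.index != i:
                raise ValueError(f"layer indices must be 1..{len(self.layers)} "
                                 f"in order, got {layer.index} at position {i}")
            if layer.filter_width > self.input_length:
                raise ValueError(
                    f"layer {i}: filter width {layer.filter_width} exceeds "
                    f"input length {self.input_length}")

    def channel_sizes(self) -> List[int]:
        """Input channels of each layer (the input spectrum is 1 channel)."""
        return [1] + [l.n_filters for l in self.layers[:-1]]


_TABLE_LAYERS = (
    LayerSpec(1, 256, 9, True),
    LayerSpec(2, 128, 5, True),
    LayerSpec(3, 64, 5, True),
    LayerSpec(4, 1, 9, True),
    LayerSpec(5, 1, 600, False),
)


def default_network_spec(input_length: int = 600) -> NetworkSpec:
    """The reference architecture; the final kernel spans the input length."""
    layers = list(_TABLE_LAYERS[:-1]) + [LayerSpec(5, 1, input_length, False)]
    return NetworkSpec(input_length=input_length, layers=tuple(layers))


def count_parameters(spec: NetworkSpec) -> List[int]:
    """Weights + biases per convolutional unit (batch-norm affine params
    are counted separately by ``DenoiserCNN.n_batchnorm_parameters``)."""
    counts = []
    for c_in, layer in zip(spec.channel_sizes(), spec.layers):
        counts.append(layer.n_filters * layer.filter_width * c_in + layer.n_filters)
    return counts


# ---------------------------------------------------------------------------
# layers


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Buffers:
    """Per-layer scratch arrays reused across mini-batches (keyed by shape)."""

    def __init__(self):
        self._store: Dict[Tuple, np.ndarray] = {}

    def get(self, name: str, shape: Tuple[int, ...], dtype,
            zeroed: bool = False) -> np.ndarray:
        key = (name, shape, np.dtype(dtype).str)
        buf = self._store.get(key)
        if buf is None:
            buf = np.zeros(shape, dtype) if zeroed else np.empty(shape, dtype)
            self._store[key] = buf
        elif zeroed:
            buf[...] = 0
        return buf


def _correlate(xp: np.ndarray, w: np.ndarray, bufs: _Buffers, tag: str
               ) -> np.ndarray:
    """Valid-mode correlation of a padded (B, Lp, C_in) signal with a
    (C_out, k, C_in) kernel -> (B, L, C_out), choosing the cheapest route."""
    b, lp, c_in = xp.shape
    c_out, k, _ = w.shape
    l = lp - k + 1
    if c_in == 1 and c_out == 1 and k >= 64:
        # single-channel wide kernel: FFT convolution
        out = fftconvolve(xp[:, :, 0], w[0, ::-1, 0][None, :], mode="valid",
                          axes=1)
        return out.astype(xp.dtype, copy=False)[:, :, None]
    if c_in * k <= 64:
        # thin patch matrix: one small im2col + a single matmul
        s0, s1, s2 = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp, (b, l, k, c_in), (s0, s1, s1, s2))
        cols = bufs.get(tag + "cols", (b, l, k * c_in), xp.dtype)
        cols[...] = windows.reshape(b, l, k * c_in)
        out = bufs.get(tag + "out", (b, l, c_out), xp.dtype)
        np.matmul(cols.reshape(b * l, k * c_in), w.reshape(c_out, k * c_in).T,
                  out=out.reshape(b * l, c_out))
        return out
    # general case: k shifted batched matmuls on strided views
    out = bufs.get(tag + "out", (b, l, c_out), xp.dtype)
    tmp = bufs.get(tag + "tmp", (b, l, c_out), xp.dtype)
    np.matmul(xp[:, 0:l, :], w[:, 0, :].T, out=out)
    for j in range(1, k):
        np.matmul(xp[:, j:j + l, :], w[:, j, :].T, out=tmp)
        out += tmp
    return out


class Conv1d:
    """Same-padding stride-1 1D convolution.

    Weights are stored as (c_out, k, c_in).  Even kernel widths pad
    asymmetrically: left = (k-1)//2, right = k - 1 - left.
    """

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, relu_follows: bool,
                 dtype=np.float32):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad_left = (k - 1) // 2
        self.pad_right = k - 1 - self.pad_left
        # He-style init scaled for the following nonlinearity (gain sqrt(2)
        # for ReLU units, 1 for the linear output layer)
        gain = np.sqrt(2.0) if relu_follows else 1.0
        std = gain / np.sqrt(k * c_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_out, k, c_in)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self._bufs = _Buffers()
        self._xp: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def _pad(self, x: np.ndarray, pl: int, pr: int, tag: str) -> np.ndarray:
        b, l, c = x.shape
        xp = self._bufs.get(tag, (b, l + pl + pr, c), x.dtype, zeroed=False)
        if pl:
            xp[:, :pl, :] = 0
        if pr:
            xp[:, l + pl:, :] = 0
        xp[:, pl:pl + l, :] = x
        return xp

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        xp = self._pad(x, self.pad_left, self.pad_right, "xp")
        out = _correlate(xp, self.weight.value, self._bufs, "f")
        out += self.bias.value
        self._xp = xp if training else None
        return out

    def _grad_weight(self, grad_out: np.ndarray) -> None:
        b, l, _ = grad_out.shape
        xp = self._xp
        if self.c_in == 1 and self.c_out == 1 and self.k >= 64:
            # gW[j] = Σ_b correlate(xp_b, g_b)[j]
            gw = fftconvolve(xp[:, :, 0], grad_out[:, ::-1, 0], mode="valid",
                             axes=1).sum(axis=0)
            self.weight.grad += gw.astype(self.weight.grad.dtype)[None, :, None]
        elif self.c_in * self.k <= 64:
            # reuse the forward patch matrix: one gemm gives the full gradient
            cols = self._bufs.get("fcols", (b, l, self.k * self.c_in),
                                  grad_out.dtype)
            gw = grad_out.reshape(b * l, self.c_out).T @ cols.reshape(
                b * l, self.k * self.c_in)
            self.weight.grad += gw.reshape(self.weight.grad.shape)
        else:
            gt = self._bufs.get("gt", (b, self.c_out, l), grad_out.dtype)
            gt[...] = grad_out.transpose(0, 2, 1)
            acc = self._bufs.get("acc", (b, self.c_out, self.c_in), grad_out.dtype)
            for j in range(self.k):
                np.matmul(gt, xp[:, j:j + l, :], out=acc)
                self.weight.grad[:, j, :] += acc.sum(axis=0)
        self.bias.grad += grad_out.sum(axis=(0, 1))

    def backward(self, grad_out: np.ndarray, need_input_grad: bool = True
                 ) -> Optional[np.ndarray]:
        self._grad_weight(grad_out)
        self._xp = None
        if not need_input_grad:
            return None
        # input gradient = full correlation with the flipped, transposed kernel
        gp = self._pad(grad_out, self.k - 1 - self.pad_left,
                       self.k - 1 - self.pad_right, "gp")
        w_flip = np.ascontiguousarray(
            self.weight.value[:, ::-1, :].transpose(2, 1, 0))  # (c_in, k, c_out)
        return _correlate(gp, w_flip, self._bufs, "b")


class BatchNorm1d:
    """Per-channel batch normalization over (batch, length).

    momentum 0.1 and eps 1e-5; inference uses the accumulated running
    statistics, so a trained model in eval mode is a pure function.
    """

    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._bufs = _Buffers()
        self._x: Optional[np.ndarray] = None
        self._mean: Optional[np.ndarray] = None
        self._inv_std: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c = x.shape[-1]
        x2d = x.reshape(-1, c)
        if training:
            m = x2d.shape[0]
            mean = x2d.mean(axis=0, dtype=np.float64)
            sq = np.einsum("ij,ij->j", x2d, x2d, dtype=np.float64)
            var = np.maximum(sq / m - mean * mean, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            mean = mean.astype(x.dtype)
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            self._x, self._mean, self._inv_std = x, mean, inv_std
        else:
            mean = self.running_mean.astype(x.dtype)
            inv_std = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        scale = self.gamma.value * inv_std
        shift = self.beta.value - mean * scale
        out = self._bufs.get("out", x.shape, x.dtype)
        np.multiply(x, scale, out=out)
        out += shift
        return out

    def backward(self, grad_out: np.ndarray, need_input_grad: bool = True
                 ) -> np.ndarray:
        # dx = inv_std/m * (m*g*γ - γ*Σg - γ*x̂*Σ(g·x̂))
        x, mean, inv_std = self._x, self._mean, self._inv_std
        c = x.shape[-1]
        m = x.size // c
        gx = self._bufs.get("gx", x.shape, x.dtype)
        if _HAVE_NUMBA:
            sum_g, sum_gx = _bn_backward_fused(
                x.reshape(-1, c), grad_out.reshape(-1, c),
                mean.astype(np.float64), inv_std.astype(np.float64),
                self.gamma.value.astype(np.float64), gx.reshape(-1, c))
        else:
            xhat = self._bufs.get("xhat", x.shape, x.dtype)
            np.subtract(x, mean, out=xhat)
            xhat *= inv_std
            g2 = grad_out.reshape(-1, c)
            sum_g = g2.sum(axis=0, dtype=np.float64)
            sum_gx = np.einsum("ij,ij->j", g2, xhat.reshape(-1, c),
                               dtype=np.float64)
            np.multiply(grad_out, self.gamma.value, out=gx)
            gx -= (self.gamma.value * (sum_gx / m)).astype(x.dtype) * xhat
            gx -= (self.gamma.value * (sum_g / m)).astype(x.dtype)
            gx *= inv_std
        self.beta.grad += sum_g.astype(self.beta.grad.dtype)
        self.gamma.grad += sum_gx.astype(self.gamma.grad.dtype)
        self._x = self._mean = self._inv_std = None
        return gx


class ReLU:
    def __init__(self):
        self._bufs = _Buffers()
        self._x: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = self._bufs.get("out", x.shape, x.dtype)
        np.maximum(x, 0.0, out=out)
        self._x = x if training else None
        return out

    def backward(self, grad_out: np.ndarray, need_input_grad: bool = True
                 ) -> np.ndarray:
        # gate in place: the upstream gradient buffer is ours to reuse
        mask = self._bufs.get("mask", self._x.shape, np.bool_)
        np.greater(self._x, 0.0, out=mask)
        grad_out *= mask
        self._x = None
        return grad_out


# ---------------------------------------------------------------------------
# the model


class DenoiserCNN:
    """The assembled network: spectra in, denoised spectra out."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = int(seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.blocks: List[object] = []
        self.conv_layers: List[Conv1d] = []
        for c_in, layer in zip(spec.channel_sizes(), spec.layers):
            conv = Conv1d(c_in, layer.n_filters, layer.filter_width, rng,
                          relu_follows=layer.has_batchnorm_relu, dtype=dtype)
            self.blocks.append(conv)
            self.conv_layers.append(conv)
            if layer.has_batchnorm_relu:
                self.blocks.append(BatchNorm1d(layer.n_filters, dtype=dtype))
                self.blocks.append(ReLU())

    # -- bookkeeping ---------------------------------------------------

    def parameters(self) -> List[Parameter]:
        return [p for blk in self.blocks for p in blk.parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_conv_parameters(self) -> List[int]:
        """Per-unit convolution parameter counts (weights + biases)."""
        return [c.weight.value.size + c.bias.value.size for c in self.conv_layers]

    def n_batchnorm_parameters(self) -> int:
        return sum(b.gamma.value.size + b.beta.value.size
                   for b in self.blocks if isinstance(b, BatchNorm1d))

    # -- compute ---------------------------------------------------------

    def _check_length(self, x: np.ndarray) -> None:
        if x.shape[-1] != self.spec.input_length:
            raise ValueError(
                f"expected spectra of length {self.spec.input_length}, "
                f"got {x.shape[-1]}")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, N) raw intensities -> (B, N) denoised intensities.

        The result is a fresh array (internal buffers are reused between
        calls).
        """
        x = np.atleast_2d(np.asarray(x))
        self._check_length(x)
        h = x.astype(self.dtype)[:, :, None]  # (B, L, 1)
        for blk in self.blocks:
            h = blk.forward(h, training)
        return h[:, :, 0].copy()

    def feature_maps(self, x: np.ndarray) -> List[np.ndarray]:
        """Per-convolutional-unit outputs for a (B, N) input (eval mode)."""
        x = np.atleast_2d(np.asarray(x))
        self._check_length(x)
        h = x.astype(self.dtype)[:, :, None]
        maps = []
        for blk in self.blocks:
            h = blk.forward(h, False)
            if isinstance(blk, Conv1d):
                maps.append(h.copy())
        return maps

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output), (B, N)."""
        g = np.ascontiguousarray(grad_out, dtype=self.dtype)[:, :, None]
        n_blocks = len(self.blocks)
        for i, blk in enumerate(reversed(self.blocks)):
            g = blk.backward(g, need_input_grad=i < n_blocks - 1)

    def finalize_batchnorm(self, x: np.ndarray, batch_size: int = 128) -> None:
        """Replace the EMA running statistics with population statistics.

        Feeds ``x`` (a (B, N) matrix, normally the training inputs) through
        the network with the final weights, normalizing each batch with its
        own statistics exactly as training does, and stores the average
        batch mean/variance per channel as the inference statistics.  This
        removes the lag of the exponential moving average behind the final
        weights.
        """
        x = np.atleast_2d(np.asarray(x))
        self._check_length(x)
        bns = [b for b in self.blocks if isinstance(b, BatchNorm1d)]
        acc = {bn: [np.zeros_like(bn.running_mean),
                    np.zeros_like(bn.running_var), 0.0] for bn in bns}
        for start in range(0, x.shape[0], batch_size):
            h = x[start:start + batch_size].astype(self.dtype)[:, :, None]
            weight = float(h.shape[0])
            for blk in self.blocks:
                if isinstance(blk, BatchNorm1d):
                    c = h.shape[-1]
                    h2d = h.reshape(-1, c)
                    mean = h2d.mean(axis=0, dtype=np.float64)
                    sq = np.einsum("ij,ij->j", h2d, h2d, dtype=np.float64)
                    var = np.maximum(sq / h2d.shape[0] - mean * mean, 0.0)
                    a = acc[blk]
                    a[0] += weight * mean
                    a[1] += weight * var
                    a[2] += weight
                    inv = 1.0 / np.sqrt(var + blk.eps)
                    scale = blk.gamma.value * inv.astype(h.dtype)
                    shift = blk.beta.value - mean.astype(h.dtype) * scale
                    h = h * scale + shift
                else:
                    h = blk.forward(h, False)
        for bn, (s_mean, s_var, w) in acc.items():
            bn.running_mean = s_mean / w
            bn.running_var = s_var / w

    __call__ = forward


def build_network(spec: Optional[NetworkSpec] = None, seed: int = 0,
                  dtype=np.float32) -> DenoiserCNN:
    """Construct a trainable model with reproducible initial weights."""
    return DenoiserCNN(spec or default_network_spec(), seed=seed, dtype=dtype)


def denoise(model: DenoiserCNN,
            spectra: Union[Spectrum, Sequence[Spectrum], np.ndarray]
            ) -> Union[Spectrum, List[Spectrum], np.ndarray]:
    """Run the model in inference mode on one or many spectra.

    Accepts a :class:`Spectrum`, a sequence of them, or a (B, N) array, and
    returns the matching type (Spectrum outputs reuse the input axis).
    """
    if isinstance(spectra, Spectrum):
        out = model.forward(spectra.intensity[None, :], training=False)
        return spectra.with_intensity(out[0].astype(float))
    if isinstance(spectra, np.ndarray):
        return model.forward(spectra, training=False)
    outs = model.forward(np.stack([s.intensity for s in spectra]), training=False)
    return [s.with_intensity(o.astype(float)) for s, o in zip(spectra, outs)]


# ---------------------------------------------------------------------------
# persistence


def save_model(model: DenoiserCNN, path: Union[str, Path]) -> None:
    """Checkpoint weights (npz) plus a JSON sidecar with the architecture."""
    path = Path(path)
    arrays = {}
    for i, blk in enumerate(model.blocks):
        if isinstance(blk, Conv1d):
            arrays[f"b{i}_weight"] = blk.weight.value
            arrays[f"b{i}_bias"] = blk.bias.value
        elif isinstance(blk, BatchNorm1d):
            arrays[f"b{i}_gamma"] = blk.gamma.value
            arrays[f"b{i}_beta"] = blk.beta.value
            arrays[f"b{i}_rmean"] = blk.running_mean
            arrays[f"b{i}_rvar"] = blk.running_var
    np.savez(path, **arrays)
    sidecar = {
        "input_length": model.spec.input_length,
        "seed": model.seed,
        "dtype": np.dtype(model.dtype).name,
        "layers": [
            {"index": l.index, "n_filters": l.n_filters,
             "filter_width": l.filter_width,
             "has_batchnorm_relu": l.has_batchnorm_relu}
            for l in model.spec.layers
        ],
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: Union[str, Path]) -> DenoiserCNN:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with open(npz_path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    spec = NetworkSpec(
        input_length=sidecar["input_length"],
        layers=tuple(LayerSpec(**l) for l in sidecar["layers"]),
    )
    model = DenoiserCNN(spec, seed=sidecar["seed"],
                        dtype=np.dtype(sidecar["dtype"]).type)
    data = np.load(npz_path)
    for i, blk in enumerate(model.blocks):
        if isinstance(blk, Conv1d):
            blk.weight.value = data[f"b{i}_weight"]
            blk.bias.value = data[f"b{i}_bias"]
            blk.weight.grad = np.zeros_like(blk.weight.value)
            blk.bias.grad = np.zeros_like(blk.bias.value)
        elif isinstance(blk, BatchNorm1d):
            blk.gamma.value = data[f"b{i}_gamma"]
            blk.beta.value = data[f"b{i}_beta"]
            blk.gamma.grad = np.zeros_like(blk.gamma.value)
            blk.beta.grad = np.zeros_like(blk.beta.value)
            blk.running_mean = data[f"b{i}_rmean"]
            blk.running_var = data[f"b{i}_rvar"]
    return model
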