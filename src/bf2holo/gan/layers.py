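"""Minimal CNN building blocks (forward + backward) on numpy arrays.

All layers operate on NCHW float arrays and implement explicit
backpropagation; convolutions are evaluated as GEMMs over sliding windows, so
a single BLAS matmul carries the bulk of the arithmetic.  This is deliberately
small: just what the BF-to-hologram translation network needs (3x3 "same"
convolutions with stride 1 or 2, leaky ReLU, exact bilinear up-sampling by an
integer factor, channel concatenation and fully connected heads).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "FFTConv2d", "LeakyReLU", "BilinearUpsample", "Dense", "init_rng_split"]


def init_rng_split(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Deterministically split an RNG into n child generators."""
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [np.random.default_rng(int(s)) for s in seeds]


def _conv_gemm(x_pad: np.ndarray, weight: np.ndarray, stride: int) -> np.ndarray:
    """Correlate padded NCHW input with OIHW weights via one tensordot."""
    k = weight.shape[-1]
    windows = sliding_window_view(x_pad, (k, k), axis=(2, 3))  # B,C,H',W',k,k
    if stride > 1:
        windows = windows[:, :, ::stride, ::stride]
    out = np.tensordot(windows, weight, axes=([1, 4, 5], [1, 2, 3]))  # B,H,W,O
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


class Conv2d:
    """kxk convolution, "same" padding (zero or reflect), stride 1 or 2.

    Reflect padding avoids the frame of edge artifacts that zero padding
    imprints on image-synthesis outputs; its backward pass folds the
    gradient at the reflected positions back into the interior.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        pad_mode: str = "zero",
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU nets
        self.weight = (rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size))).astype(dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self.stride = stride
        self.pad = kernel_size // 2
        if pad_mode not in ("zero", "reflect"):
            raise ValueError("pad_mode must be 'zero' or 'reflect'")
        self.pad_mode = pad_mode
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._x_pad: np.ndarray | None = None

    @property
    def params(self):
        return [
            (self.weight, self.grad_weight),
            (self.bias, self.grad_bias),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        mode = "reflect" if self.pad_mode == "reflect" else "constant"
        x_pad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode=mode)
        self._x_pad = x_pad
        self._in_shape = x.shape
        out = _conv_gemm(x_pad, self.weight, self.stride)
        return out + self.bias[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        k = self.weight.shape[-1]
        p = self.pad
        x_pad = self._x_pad
        self.grad_bias[...] = grad_out.sum(axis=(0, 2, 3))
        # dW: correlate input windows with the output gradient
        windows = sliding_window_view(x_pad, (k, k), axis=(2, 3))
        if self.stride > 1:
            windows = windows[:, :, :: self.stride, :: self.stride]
        gw = np.tensordot(
            grad_out, windows, axes=([0, 2, 3], [0, 2, 3])
        )  # O, C, k, k
        self.grad_weight[...] = gw.astype(self.weight.dtype)
        # dX: full correlation of (zero-stuffed) grad with the flipped kernel
        if self.stride > 1:
            b, o, ho, wo = grad_out.shape
            stuffed = np.zeros(
                (b, o, self._in_shape[2] + 2 * p - k + 1, self._in_shape[3] + 2 * p - k + 1),
                dtype=grad_out.dtype,
            )
            stuffed[:, :, :: self.stride, :: self.stride] = grad_out
            grad_out = stuffed
        w_flip = np.ascontiguousarray(self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        if self.pad_mode == "zero":
            g_pad = np.pad(grad_out, ((0, 0), (0, 0), (k - 1 - p, k - 1 - p), (k - 1 - p, k - 1 - p)))
            return _conv_gemm(g_pad, w_flip, 1)
        # reflect: gradient w.r.t. the padded input, then fold the pad strips
        # back onto their reflected interior sources
        g_pad = np.pad(grad_out, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        dx_pad = _conv_gemm(g_pad, w_flip, 1)  # B, C, H+2p, W+2p
        tmp = dx_pad[:, :, p:-p, :].copy()
        for j in range(p):
            tmp[:, :, p - j, :] += dx_pad[:, :, j, :]
            tmp[:, :, -(1 + p - j), :] += dx_pad[:, :, -1 - j, :]
        dx = tmp[:, :, :, p:-p].copy()
        for j in range(p):
            dx[:, :, :, p - j] += tmp[:, :, :, j]
            dx[:, :, :, -(1 + p - j)] += tmp[:, :, :, -1 - j]
        return dx


class FFTConv2d:
    """Single-channel 'same' convolution with a wide kernel, via FFT.

    Used for the generator's linear skip path: for kernels of a few tens of
    pixels the FFT route is far cheaper than the GEMM formulation.  The
    input gradient is not propagated (the skip reads the raw network input),
    only the kernel/bias gradients are produced.  Reflect padding keeps the
    borders clean.
    """

    def __init__(self, kernel_size: int, dtype=np.float32):
        self.weight = np.zeros((1, 1, kernel_size, kernel_size), dtype=dtype)
        self.bias = np.zeros(1, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self.k = kernel_size
        self._x_pad: np.ndarray | None = None

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        from scipy.signal import fftconvolve

        p = self.k // 2
        x_pad = np.pad(x[:, 0], ((0, 0), (p, p), (p, p)), mode="reflect")
        self._x_pad = x_pad
        kernel = self.weight[0, 0, ::-1, ::-1]  # correlation via convolution
        out = fftconvolve(x_pad, kernel[None], mode="valid", axes=(1, 2))
        return out[:, None].astype(x.dtype) + self.bias[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray | None:
        from scipy.signal import fftconvolve

        g = grad_out[:, 0]
        self.grad_bias[...] = g.sum()
        # dW[i, j] = sum_b sum_hw x_pad[b, h+i, w+j] * g[b, h, w]
        corr = fftconvolve(self._x_pad, g[:, ::-1, ::-1], mode="valid", axes=(1, 2))
        self.grad_weight[...] = corr.sum(axis=0)[None, None].astype(self.weight.dtype)
        return None


class LeakyReLU:
    """max(x, alpha*x); alpha = 0.2 by default."""

    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, self.alpha * grad_out)


def _bilinear_matrix(n_in: int, factor: int, dtype=np.float32) -> np.ndarray:
    """Exact 1-D bilinear interpolation matrix (n_in*factor, n_in).

    Output sample centers map to input coordinates (i + 0.5)/factor - 0.5
    (the align_corners=False convention); edges clamp.
    """
    n_out = n_in * factor
    mat = np.zeros((n_out, n_in), dtype=dtype)
    for i in range(n_out):
        src = (i + 0.5) / factor - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        mat[i, lo_c] += 1.0 - frac
        mat[i, hi_c] += frac
    return mat


class BilinearUpsample:
    """Bilinear upsampling by an integer factor, exact and linear."""

    def __init__(self, factor: int, dtype=np.float32):
        self.factor = factor
        self.dtype = dtype
        self._mats: dict[int, np.ndarray] = {}

    params: list = []

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _bilinear_matrix(n, self.factor, self.dtype)
        return self._mats[n]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mh, mw = self._mat(x.shape[2]), self._mat(x.shape[3])
        self._shapes = (x.shape[2], x.shape[3])
        out = np.einsum("ij,bcjk->bcik", mh, x, optimize=True)
        return np.einsum("bcik,lk->bcil", out, mw, optimize=True)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        mh, mw = self._mat(self._shapes[0]), self._mat(self._shapes[1])
        g = np.einsum("ij,bcjk->bcik", mh.T, grad_out, optimize=True)
        return np.einsum("bcik,lk->bcil", g, mw.T, optimize=True)


class Dense:
    """Fully connected layer on flattened features."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.weight = rng.normal(0.0, scale, (n_out, n_in)).astype(dtype)
        self.bias = np.zeros(n_out, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grad_weight[...] = grad_out.T @ self._x
        self.grad_bias[...] = grad_out.sum(axis=0)
        return grad_out @ self.weight
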