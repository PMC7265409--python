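"""Multiscale generator and scoring discriminator for BF-to-hologram translation.

The generator is a coarse-to-fine multiscale CNN: the defocused bright-field
image is presented at four resolutions (1, 1/2, 1/4 and 1/16 of the linear
size, i.e. pixel counts n, n/2^2, n/2^4 and n/2^8).  Processing starts at the
coarsest scale; each scale's features are bilinearly upsampled and
concatenated with the next finer input, so the network can express both the
long-range fringe structure and fine local detail.  The exact layer counts
and widths are configurable (three 3x3 convolutions per scale by default);
the network is fully convolutional, so inference runs at any resolution
divisible by 16.

The discriminator is a strided convolutional feature extractor followed by
fully connected layers emitting a score strictly inside (0, 1): values near 1
mean "looks like a recorded hologram", near 0 "looks generated".  Because of
the dense head it is tied to the training crop size and is not used at test
time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from ..metrics import bce, mse_rms
from .layers import BilinearUpsample, Conv2d, Dense, FFTConv2d, LeakyReLU, init_rng_split

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "MultiscaleGenerator",
    "Discriminator",
    "build_multiscale_inputs",
    "generator_loss",
    "discriminator_loss",
]

#: linear downscale factor of each generator input, coarse to fine
SCALE_FACTORS = (16, 4, 2, 1)


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the multiscale generator (coarse-to-fine widths)."""

    widths: tuple[int, ...] = (6, 12, 12, 12)
    convs_per_scale: int = 3
    kernel_size: int = 3
    #: width of the zero-initialized linear skip from the full-resolution
    #: input to the output.  The BF-to-hologram map is close to a linear
    #: convolution (the hologram is, to first order, the blurred particle
    #: silhouette re-convolved with a ring kernel), so a direct linear path
    #: converges quickly and keeps the synthesized pattern centered on the
    #: particle while the multiscale CNN learns the nonlinear corrections.
    skip_kernel_size: int = 25

    def __post_init__(self) -> None:
        if len(self.widths) != len(SCALE_FACTORS):
            raise ValueError(f"widths must have {len(SCALE_FACTORS)} entries (one per scale)")
        if self.convs_per_scale < 1:
            raise ValueError("convs_per_scale must be >= 1")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the scoring discriminator."""

    conv_widths: tuple[int, ...] = (8, 16, 32, 64)
    dense_width: int = 64
    input_size: int = 64  # training crop size the dense head is built for


def build_multiscale_inputs(bf: np.ndarray) -> list[np.ndarray]:
    """Downsample a BF image to the generator's four input scales.

    Returns [I0, I1, I2, I3] with linear sizes 1, 1/2, 1/4 and 1/16 of the
    input.  Downsampling is anti-aliased area interpolation (Gaussian
    pre-filter + resampling), which preserves both the mean intensity and,
    crucially, the *centroid* of features smaller than a coarse pixel --
    plain block averaging would quantize a small particle's position to the
    coarse grid and cap the translation accuracy of the whole network.
    Dimensions not divisible by 16 are edge-padded with a warning.
    """
    bf = np.asarray(bf, dtype=np.float64)
    if bf.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    pad_r = (-bf.shape[0]) % 16
    pad_c = (-bf.shape[1]) % 16
    if pad_r or pad_c:
        warnings.warn(
            f"image shape {bf.shape} not divisible by 16; edge-padding by ({pad_r}, {pad_c})"
        )
        bf = np.pad(bf, ((0, pad_r), (0, pad_c)), mode="edge")
    return [bf] + [
        resize(bf, (bf.shape[0] // f, bf.shape[1] // f), anti_aliasing=True)
        for f in (2, 4, 16)
    ]


class MultiscaleGenerator:
    """Coarse-to-fine fully convolutional generator."""

    def __init__(self, spec: GeneratorSpec | None = None, rng: np.random.Generator | None = None, dtype=np.float32):
        self.spec = spec or GeneratorSpec()
        self.dtype = dtype
        rng = rng or np.random.default_rng()
        n_scales = len(SCALE_FACTORS)
        rngs = iter(init_rng_split(rng, n_scales * self.spec.convs_per_scale + 1))
        self.stages: list[list] = []
        self.upsamplers: list[BilinearUpsample] = []
        for i, width in enumerate(self.spec.widths):
            in_ch = 1 if i == 0 else 1 + self.spec.widths[i - 1]
            stage = []
            for j in range(self.spec.convs_per_scale):
                stage.append(
                    Conv2d(
                        in_ch if j == 0 else width, width, self.spec.kernel_size,
                        rng=next(rngs), dtype=dtype, pad_mode="reflect",
                    )
                )
                stage.append(LeakyReLU())
            self.stages.append(stage)
            if i < n_scales - 1:
                self.upsamplers.append(
                    BilinearUpsample(SCALE_FACTORS[i] // SCALE_FACTORS[i + 1], dtype=dtype)
                )
        self.out_conv = Conv2d(
            self.spec.widths[-1], 1, self.spec.kernel_size,
            rng=next(rngs), dtype=dtype, pad_mode="reflect",
        )
        # the CNN's output head starts at zero: the convex linear-skip path
        # then shapes the first approximation (a centered ring response) and
        # the multiscale CNN grows only the nonlinear residual, which keeps
        # run-to-run asymmetries of the nonconvex path from displacing the
        # synthesized pattern
        self.out_conv.weight[...] = 0.0
        self.skip_conv = None
        if self.spec.skip_kernel_size:
            self.skip_conv = FFTConv2d(self.spec.skip_kernel_size, dtype=dtype)

    @property
    def params(self):
        out = []
        for stage in self.stages:
            for layer in stage:
                out.extend(layer.params)
        out.extend(self.out_conv.params)
        if self.skip_conv is not None:
            out.extend(self.skip_conv.params)
        return out

    def forward(self, inputs: list[np.ndarray]) -> np.ndarray:
        """inputs = [I0 (finest) .. I3 (coarsest)] as NCHW single-channel."""
        coarse_to_fine = inputs[::-1]
        feat = None
        self._concat_channels: list[int] = []
        for i, (x, stage) in enumerate(zip(coarse_to_fine, self.stages)):
            if feat is not None:
                self._concat_channels.append(x.shape[1])
                x = np.concatenate([x, feat], axis=1)
            for layer in stage:
                x = layer.forward(x)
            if i < len(self.stages) - 1:
                feat = self.upsamplers[i].forward(x)
            else:
                feat = x
        out = self.out_conv.forward(feat)
        if self.skip_conv is not None:
            out = out + self.skip_conv.forward(inputs[0])
        return out

    def backward(self, grad_out: np.ndarray) -> None:
        if self.skip_conv is not None:
            self.skip_conv.backward(grad_out)  # input-gradient not needed
        g = self.out_conv.backward(grad_out)
        for i in range(len(self.stages) - 1, -1, -1):
            for layer in reversed(self.stages[i]):
                g = layer.backward(g)
            if i > 0:
                n_raw = self._concat_channels[i - 1]
                g = g[:, n_raw:]  # gradient w.r.t. the raw input scale is dropped
                g = self.upsamplers[i - 1].backward(g)

    def zero_grads(self) -> None:
        for p, grad in self.params:
            grad[...] = 0.0


class Discriminator:
    """Strided CNN + dense head emitting a realism score in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec | None = None, rng: np.random.Generator | None = None, dtype=np.float32):
        self.spec = spec or DiscriminatorSpec()
        rng = rng or np.random.default_rng()
        rngs = iter(init_rng_split(rng, len(self.spec.conv_widths) + 2))
        self.layers: list = []
        in_ch = 1
        size = self.spec.input_size
        for width in self.spec.conv_widths:
            self.layers.append(Conv2d(in_ch, width, 3, stride=2, rng=next(rngs), dtype=dtype))
            self.layers.append(LeakyReLU())
            in_ch = width
            size = (size + 1) // 2
        self._flat_dim = in_ch * size * size
        self._feat_shape = (in_ch, size, size)
        self.dense1 = Dense(self._flat_dim, self.spec.dense_width, rng=next(rngs), dtype=dtype)
        self.act1 = LeakyReLU()
        self.dense2 = Dense(self.spec.dense_width, 1, rng=next(rngs), dtype=dtype)
        # small-gain output head: the score starts near 0.5 with a gentle
        # input Jacobian, so the adversarial gradient does not drown the
        # image term before the discriminator has learned anything
        self.dense2.weight *= 0.01

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend(self.dense1.params)
        out.extend(self.dense2.params)
        return out

    def forward_logit(self, x: np.ndarray) -> np.ndarray:
        """Raw logit per batch item; score = sigmoid(logit) in (0, 1)."""
        for layer in self.layers:
            x = layer.forward(x)
        self._batch = x.shape[0]
        flat = x.reshape(self._batch, -1)
        h = self.act1.forward(self.dense1.forward(flat))
        return self.dense2.forward(h)[:, 0]

    def forward_score(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward_logit(x)))

    def backward_from_logit(self, grad_logit: np.ndarray) -> np.ndarray:
        """Backprop from d(loss)/d(logit); returns d(loss)/d(input image)."""
        g = self.dense2.backward(grad_logit[:, None].astype(self.dense2.weight.dtype))
        g = self.act1.backward(g)
        g = self.dense1.backward(g)
        g = g.reshape(self._batch, *self._feat_shape)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grads(self) -> None:
        for p, grad in self.params:
            grad[...] = 0.0


def generator_loss(gen_holo: np.ndarray, truth_holo: np.ndarray, disc_score_on_gen: float) -> float:
    """L_G = RMS image error + BCE of the discriminator score against 1."""
    return mse_rms(gen_holo, truth_holo) + bce(disc_score_on_gen, 1.0)


def discriminator_loss(score_on_gen: float, score_on_truth: float) -> float:
    """L_D = BCE(score on generated, 0) + BCE(score on ground truth, 1)."""
    return bce(score_on_gen, 0.0) + bce(score_on_truth, 1.0)
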