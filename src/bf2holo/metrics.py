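"""Scalar image-quality metrics: SNR, global SSIM, root-mean-square L2, BCE.

These are the quantities used to score generated holograms against ground
truth and to build the adversarial losses:

* ``snr`` -- mean signal intensity over the standard deviation of the
  background, given a boolean signal mask;
* ``ssim_global`` -- structural similarity computed from *whole-image* means,
  variances and covariance (a single index per image pair, not the common
  sliding-window variant; a windowed mode is offered separately for
  comparability with scikit-image);
* ``mse_rms`` -- the square root of the mean squared difference between two
  images, i.e. the L2 error per pixel;
* ``bce`` -- binary cross-entropy between a score in (0, 1) and a 0/1 label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalMask",
    "SSIMConstants",
    "snr",
    "ssim_global",
    "ssim_windowed",
    "mse_rms",
    "bce",
    "fringe_signal_mask",
]

#: scores passed to :func:`bce` are clamped into [BCE_EPS, 1 - BCE_EPS]
BCE_EPS = 1e-7


@dataclass
class SignalMask:
    """Boolean mask splitting an image into signal (True) and background pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("SignalMask must be 2D")

    def check_against(self, image: np.ndarray) -> None:
        if self.values.shape != image.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != image shape {image.shape}"
            )
        if not self.values.any() or self.values.all():
            raise ValueError("SignalMask needs at least one signal and one background pixel")


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizers preventing division by a small denominator in SSIM.

    Defaults follow the conventional (0.01 L)^2 and (0.03 L)^2 with dynamic
    range L = 1 for [0, 1] images.
    """

    C1: float = (0.01) ** 2
    C2: float = (0.03) ** 2

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("SSIM constants must be positive")


def snr(image: np.ndarray, mask: SignalMask) -> float:
    """Signal-to-noise ratio: mean signal intensity / background std. dev.

    The background noise level is the standard deviation of intensities over
    the mask-False pixels (everything except the particle signal).
    """
    image = np.asarray(image, dtype=np.float64)
    mask.check_against(image)
    signal_mean = float(image[mask.values].mean())
    sigma = float(image[~mask.values].std())
    if sigma == 0.0:
        raise ValueError("background standard deviation is zero (constant background)")
    return signal_mean / sigma


def ssim_global(
    img_a: np.ndarray, img_b: np.ndarray, consts: SSIMConstants | None = None
) -> float:
    """Global structural similarity index from whole-image moments.

    SSIM(A, B) = (2 mu_A mu_B + C1)(2 cov_AB + C2)
                 / ((mu_A^2 + mu_B^2 + C1)(var_A + var_B + C2))

    Returns 1 exactly iff the images are identical (given C1, C2 > 0).
    """
    consts = consts or SSIMConstants()
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = float(((a - mu_a) * (b - mu_b)).mean())
    num = (2.0 * mu_a * mu_b + consts.C1) * (2.0 * cov + consts.C2)
    den = (mu_a**2 + mu_b**2 + consts.C1) * (var_a + var_b + consts.C2)
    return float(num / den)


def ssim_windowed(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Sliding-window SSIM (Gaussian window) via scikit-image.

    Provided only for comparability with common SSIM implementations; the
    canonical metric in this package is the single global index
    (:func:`ssim_global`).
    """
    from skimage.metrics import structural_similarity

    return float(
        structural_similarity(
            np.asarray(img_a, float), np.asarray(img_b, float),
            gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            data_range=1.0,
        )
    )


def mse_rms(x: np.ndarray, y: np.ndarray) -> float:
    """Root of the mean squared difference between two equally-shaped images.

    This quantity is both the per-pixel L2 error tracked during GAN training
    and the image term of the generator loss.  (It is the root of the mean of
    *squared* differences; the name keeps the MSE/L2 pairing used when
    reporting training curves.)
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def bce(score: float | np.ndarray, label: float) -> float:
    """Binary cross-entropy -y log(x) - (1-y) log(1-x) for a score in (0, 1).

    Scores of exactly 0 or 1 are clamped to [1e-7, 1 - 1e-7] so the loss stays
    finite at the saturated ends.
    """
    x = np.clip(np.asarray(score, dtype=np.float64), BCE_EPS, 1.0 - BCE_EPS)
    y = float(label)
    return float(np.mean(-y * np.log(x) - (1.0 - y) * np.log1p(-x)))


def fringe_signal_mask(
    shape: tuple[int, int],
    centers_px: list[tuple[float, float]],
    radii_px: list[float],
) -> SignalMask:
    """Analytic signal mask for simulated holograms.

    Signal pixels are those within the expected fringe support of any
    particle: a disk of the given radius (particle radius plus a fringe
    allowance, in pixels) around each particle center ``(row, col)``.
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for (rc, cc), radius in zip(centers_px, radii_px):
        mask |= (rows - rc) ** 2 + (cols - cc) ** 2 <= radius**2
    return SignalMask(mask)
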