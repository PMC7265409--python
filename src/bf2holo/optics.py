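"""Complex optical wavefields and angular-spectrum free-space propagation.

This is the physics engine shared by the hologram simulator and the numerical
reconstructor.  A recorded in-line hologram ``h(x, y)`` is treated as a complex
field with zero imaginary part and propagated to any axial distance ``z`` by
multiplying its 2D Fourier spectrum with the free-space transfer function

    H_z(f_x, f_y) = exp(i z (2*pi/lambda) * sqrt(1 - (lambda f_x)^2 - (lambda f_y)^2))

and inverting the transform.  Evanescent components, for which the argument of
the square root is negative, are zeroed rather than allowed to grow
exponentially under back-propagation; this keeps propagation by ``+z`` and
``-z`` exact inverses of each other on the propagating band.

Conventions
-----------
* arrays are row-major ``(y, x)``, origin at the top-left, 0-based indices;
* all physical lengths are micrometres; positions are measured from the image
  corner;
* spectral coordinates follow the discrete-Fourier convention with spacing
  ``1 / (N * pixel_pitch)``; the zero frequency is the constant component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["OpticalConfig", "ComplexField", "propagate", "amplitude"]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical sampling of an image: wavelength, object-space pixel pitch, shape.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in micrometres (default 0.532, green laser).
    pixel_pitch : float
        Object-space sampling in micrometres per pixel.  0.53 corresponds to a
        20x water-immersion objective, 0.18 to a 60x objective.
    image_shape : (int, int)
        Image dimensions ``(rows, cols)``.
    """

    wavelength: float = 0.532
    pixel_pitch: float = 0.53
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if not np.isfinite(self.wavelength) or self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if not np.isfinite(self.pixel_pitch) or self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        shape = tuple(int(n) for n in self.image_shape)
        if len(shape) != 2 or any(n < 2 for n in shape):
            raise ValueError(f"image_shape components must be >= 2, got {self.image_shape}")
        object.__setattr__(self, "image_shape", shape)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical field-of-view (height, width) in micrometres."""
        return (self.image_shape[0] * self.pixel_pitch, self.image_shape[1] * self.pixel_pitch)


@dataclass
class ComplexField:
    """A 2D complex optical wavefield sampled on a uniform pixel grid."""

    values: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("ComplexField values must be a 2D array")
        if self.values.shape != self.config.image_shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match "
                f"config.image_shape {self.config.image_shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ComplexField values must be finite")

    @classmethod
    def from_real(cls, image: np.ndarray, config: OpticalConfig) -> "ComplexField":
        """Wrap a real-valued intensity image as a field with zero imaginary part."""
        return cls(np.asarray(image, dtype=np.float64).astype(np.complex128), config)


@lru_cache(maxsize=8)
def _axial_wavenumber(config: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (k_z grid, propagating-band mask) for a sampling configuration.

    k_z = (2*pi/lambda) sqrt(1 - (lambda f_x)^2 - (lambda f_y)^2) on the band
    where the root is real; the mask is False on the evanescent band.
    """
    ny, nx = config.image_shape
    fy = np.fft.fftfreq(ny, d=config.pixel_pitch)
    fx = np.fft.fftfreq(nx, d=config.pixel_pitch)
    lam = config.wavelength
    arg = 1.0 - (lam * fy[:, None]) ** 2 - (lam * fx[None, :]) ** 2
    band = arg > 0.0
    kz = np.zeros_like(arg)
    kz[band] = (2.0 * np.pi / lam) * np.sqrt(arg[band])
    return kz, band


def propagate(field: ComplexField, z: float) -> ComplexField:
    """Propagate a wavefield by an axial distance ``z`` (micrometres).

    Positive ``z`` propagates forward, negative ``z`` back-propagates; the two
    are exact inverses on the propagating band because the transfer functions
    are complex conjugates there.  Evanescent spectral components are zeroed.
    """
    if not np.isscalar(z) or not np.isfinite(z):
        raise ValueError(f"propagation distance must be a finite scalar, got {z!r}")
    if field.values.size == 0:
        raise ValueError("cannot propagate an empty field")
    kz, band = _axial_wavenumber(field.config)
    spectrum = np.fft.fft2(field.values)
    spectrum *= band * np.exp(1j * float(z) * kz)
    return ComplexField(np.fft.ifft2(spectrum), field.config)


def amplitude(field: ComplexField) -> np.ndarray:
    """Elementwise modulus |field|; the amplitude image of a reconstruction."""
    return np.abs(field.values)
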