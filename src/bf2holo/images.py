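"""Real-valued intensity image containers with optical metadata.

A :class:`Hologram` is a recorded (or generated, or simulated) in-line
interference pattern normalized to [0, 1]; a :class:`BFImage` is a defocused
bright-field micrograph on the same grid.  Both carry the
:class:`~bf2holo.optics.OpticalConfig` needed to interpret pixel coordinates
physically, and simulated images additionally carry the ground-truth particle
records used by the closed-loop tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .optics import ComplexField, OpticalConfig

__all__ = ["Hologram", "BFImage"]

_PROVENANCES = ("ground_truth", "generated", "simulated")


def _check_intensity(values: np.ndarray, config: OpticalConfig) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != config.image_shape:
        raise ValueError(
            f"image shape {values.shape} does not match optics {config.image_shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("image intensities must be finite")
    return values


@dataclass
class Hologram:
    """An in-line hologram: intensities in [0, 1] plus optical metadata."""

    values: np.ndarray
    optics: OpticalConfig
    provenance: str = "ground_truth"
    particles: list[Any] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _check_intensity(self.values, self.optics)
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {_PROVENANCES}")

    def as_field(self) -> ComplexField:
        """The hologram as a complex field with zero imaginary part."""
        return ComplexField.from_real(self.values, self.optics)


@dataclass
class BFImage:
    """A (possibly defocused) bright-field micrograph normalized to [0, 1]."""

    values: np.ndarray
    optics: OpticalConfig
    particles: list[Any] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _check_intensity(self.values, self.optics)
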