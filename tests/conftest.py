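"""Shared fixtures: small optical configs and deterministic test scenes."""

import numpy as np
import pytest

from bf2holo.optics import ComplexField, OpticalConfig
from bf2holo.simulate import ParticleSpec, SceneConfig


@pytest.fixture(scope="session")
def optics_small() -> OpticalConfig:
    return OpticalConfig(image_shape=(128, 128))


@pytest.fixture(scope="session")
def optics_bead() -> OpticalConfig:
    """20x sampling, large enough for a 14.92 um bead's fringes."""
    return OpticalConfig(image_shape=(256, 256))


@pytest.fixture()
def bandlimited_field(optics_small) -> ComplexField:
    """A random field whose spectrum is confined to the propagating band."""
    rng = np.random.default_rng(7)
    spectrum = np.fft.fft2(rng.normal(size=optics_small.image_shape))
    mask = np.zeros(optics_small.image_shape)
    mask[:20, :20] = mask[-20:, :20] = mask[:20, -20:] = mask[-20:, -20:] = 1.0
    return ComplexField(np.fft.ifft2(spectrum * mask), optics_small)


@pytest.fixture(scope="session")
def single_bead_scene(optics_bead) -> SceneConfig:
    return SceneConfig(
        particles=[ParticleSpec(x=70.0, y=65.0, z=50.0)],
        optics=optics_bead,
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def noise_free_bead_scene(optics_bead) -> SceneConfig:
    return SceneConfig(
        particles=[ParticleSpec(x=70.0, y=65.0, z=50.0)],
        optics=optics_bead,
        noise_sigma_hologram=0.0,
        noise_sigma_bf=0.0,
        rng_seed=3,
    )
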