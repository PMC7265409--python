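"""Synthetic paired defocused bright-field images and in-line holograms.

This module emulates a hybrid microscope that records, for the same scene, a
defocused bright-field (BF) image with white light and an in-line hologram
with a collimated laser.  Scenes contain spherical polystyrene-like beads
(default diameter 14.92 um) and erythrocyte-like phase objects (biconcave
discocytes and spiculated echinocytes) at known depths z above the recording
plane, so every rendered pair carries exact ground truth for training the
BF-to-hologram translation network and for validating 3D localization.

Hologram forward model
----------------------
Each particle is a thin complex transmission mask at its own plane: amplitude
attenuation plus a phase proportional to the local optical thickness
(refractive-index contrast times geometric thickness).  The diffracted field
of each particle is propagated to the sensor plane by the angular-spectrum
method and the per-particle scattered waves are superposed *coherently* on a
unit-amplitude reference wave (first-order scattering; inter-particle
interference is therefore present, as in real in-line holography).  The
recorded image is the intensity |field|^2 with additive zero-mean Gaussian
noise, clipped to [0, 1].

Bright-field forward model
--------------------------
BF formation is incoherent: each particle is drawn as an in-focus absorption
disk and convolved with a geometric defocus kernel (a uniform disk) whose
radius grows linearly with z; blurred contributions are summed in intensity.
Contrast consequently falls monotonically with depth, which is the only
property of BF defocus the translation network must learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .images import BFImage, Hologram
from .optics import ComplexField, OpticalConfig, propagate

__all__ = [
    "ParticleSpec",
    "SceneConfig",
    "render_hologram",
    "render_brightfield",
    "render_pair",
    "make_dataset",
]

_KINDS = ("sphere", "discocyte", "echinocyte")

#: default *effective* refractive-index contrast per particle kind.  These are
#: thin-phase-screen parameters of the collected (aperture-limited) light, not
#: bulk material constants.  For beads at 20x the collection aperture rejects
#: nearly all refracted light, so the default bead is a pure amplitude
#: silhouette (0.0); a transparent lens-like bead for scattering studies is
#: obtained by setting refractive_index_contrast explicitly (about 0.12 puts
#: the bead's focal spot a couple of diameters upstream of the particle).
#: The erythrocyte values are chosen so that the reconstructed x-z maps show
#: the discocyte's real+virtual focus pair and the echinocyte's single real
#: focus with their focal spots outside the particle's own refocus zone.
DEFAULT_INDEX_CONTRAST = {"sphere": 0.0, "discocyte": 0.18, "echinocyte": 0.25}

#: amplitude transmission inside a particle (light scattered outside the
#: collection aperture is lost, so particles appear dark in intensity)
AMPLITUDE_TRANSMISSION = {"sphere": 0.85, "discocyte": 0.92, "echinocyte": 0.92}

#: the bead silhouette's dark rim: fraction of the radius where it starts,
#: its amplitude transmission, and the number of azimuthal texture periods.
#: The rim is azimuthally dashed (surface texture) so the refocused image has
#: high-frequency contrast without the on-axis lobe a uniform annulus would
#: create by acting as a ring lens.
SPHERE_RIM = dict(start_frac=0.85, transmission=0.02, n_dashes=12)

#: echinocyte spicule geometry: sinusoidal perimeter perturbation
ECHINOCYTE_SPICULES = dict(n=12, depth=0.08)


@dataclass(frozen=True)
class ParticleSpec:
    """One particle: in-plane position, depth, size, kind and optical contrast.

    Positions and lengths are micrometres measured from the image corner
    (x along columns, y along rows); ``z`` is the depth above the recording
    plane (0 = in focus at the sensor).  ``refractive_index_contrast`` of None
    resolves to a per-kind default.
    """

    x: float
    y: float
    z: float
    radius: float = 7.46
    kind: str = "sphere"
    refractive_index_contrast: float | None = None
    #: angular offset (radians) of the bead's rim surface texture; randomized
    #: per particle in generated datasets so no fixed arc pattern is shared
    #: across a training set
    rim_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        if self.z < 0:
            raise ValueError("particle depth z must be >= 0")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def index_contrast(self) -> float:
        if self.refractive_index_contrast is not None:
            return self.refractive_index_contrast
        return DEFAULT_INDEX_CONTRAST[self.kind]


@dataclass
class SceneConfig:
    """A renderable scene: particles, optics, noise levels and an RNG seed.

    The default hologram noise level (sigma = 0.06) emulates the background
    noise of experimentally recorded in-line holograms (sigma in the
    5.0-7.0e-2 range); bright-field cameras are quieter by default.
    With a fixed seed, rendering is bit-reproducible.
    """

    particles: list[ParticleSpec] = field(default_factory=list)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    noise_sigma_hologram: float = 0.06
    noise_sigma_bf: float = 0.02
    rng_seed: int = 0
    allow_overlap: bool = False
    #: bright-field defocus-kernel radius per micrometre of depth
    bf_blur_coefficient: float = 0.12
    #: bright-field absorption contrast of an in-focus particle
    bf_contrast: float = 0.85
    #: hologram auto-exposure percentile (100 = expose for the absolute peak,
    #: keeping caustic foci unsaturated; the default saturates the top 0.5%)
    exposure_percentile: float = 99.5
    #: fixed exposure divisor overriding the per-scene percentile.  Datasets
    #: use one camera setting for every frame: per-scene auto-exposure would
    #: make the recorded background level an unlearnable per-image nuisance
    #: for the translation network.
    exposure_scale: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma_hologram < 0 or self.noise_sigma_bf < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0.0 < self.exposure_percentile <= 100.0:
            raise ValueError("exposure_percentile must be in (0, 100]")


def _visible_particles(scene: SceneConfig) -> list[ParticleSpec]:
    """Filter particles to the field of view; warn on skips and overlaps."""
    height, width = scene.optics.extent
    kept: list[ParticleSpec] = []
    for p in scene.particles:
        if not (0.0 <= p.x < width and 0.0 <= p.y < height):
            warnings.warn(
                f"particle at ({p.x:.1f}, {p.y:.1f}) um is outside the "
                f"{width:.0f}x{height:.0f} um field of view; skipped",
                stacklevel=3,
            )
            continue
        kept.append(p)
    if not scene.allow_overlap:
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if np.hypot(a.x - b.x, a.y - b.y) < a.radius + b.radius:
                    warnings.warn(
                        "particles overlap in (x, y); set allow_overlap=True to silence",
                        stacklevel=3,
                    )
    return kept


def _radial_grids(p: ParticleSpec, optics: OpticalConfig):
    """Radial distance (um) from the particle axis, and polar angle."""
    ny, nx = optics.image_shape
    pitch = optics.pixel_pitch
    y = (np.arange(ny) + 0.5) * pitch - p.y
    x = (np.arange(nx) + 0.5) * pitch - p.x
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return np.hypot(yy, xx), np.arctan2(yy, xx)


def _thickness_profile(p: ParticleSpec, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Geometric thickness (um) of the particle as a function of radius.

    sphere      : chord length 2*sqrt(R^2 - rho^2)
    discocyte   : biconcave Evans-Fung-style profile (central dimple, thick
                  toroidal rim) scaled to the particle radius
    echinocyte  : convex spherical-cap profile with a sinusoidal perimeter
                  perturbation (spicules); no central concavity
    """
    R = p.radius
    if p.kind == "sphere":
        inside = rho < R
        t = np.zeros_like(rho)
        t[inside] = 2.0 * np.sqrt(R**2 - rho[inside] ** 2)
        return t
    if p.kind == "discocyte":
        # Evans & Fung biconcave disc, coefficients in um for R0 = 3.91 um,
        # rescaled to the requested radius.
        scale = R / 3.91
        r_hat = np.clip(rho / R, 0.0, 1.0)
        shape_poly = 0.81 + 7.83 * r_hat**2 - 4.39 * r_hat**4
        t = scale * np.sqrt(np.clip(1.0 - r_hat**2, 0.0, None)) * shape_poly
        t[rho >= R] = 0.0
        return np.clip(t, 0.0, None)
    # echinocyte: spiculated convex body
    spic = ECHINOCYTE_SPICULES
    r_eff = R * (1.0 + spic["depth"] * np.sin(spic["n"] * theta))
    r_hat = np.clip(rho / r_eff, 0.0, 1.0)
    t = 2.0 * 0.45 * R * np.sqrt(1.0 - r_hat**2)
    t[rho >= r_eff] = 0.0
    return t


def _amplitude_profile(p: ParticleSpec, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Amplitude transmission of one particle (the aperture-limited silhouette).

    Cells are weakly absorbing disks.  Beads additionally carry a dark,
    azimuthally dashed rim: at the bead's edge the steep thickness gradient
    refracts light outside the collection aperture, so the rim records as
    nearly opaque; the dashes emulate surface texture and keep the rim from
    acting as a coherent ring lens (whose on-axis lobe would confound depth
    assignment).
    """
    R = p.radius
    amp = np.ones_like(rho)
    inside = rho < R
    amp[inside] = AMPLITUDE_TRANSMISSION[p.kind]
    if p.kind == "sphere":
        rim = SPHERE_RIM
        dashed = (
            inside
            & (rho >= rim["start_frac"] * R)
            & (np.sin(rim["n_dashes"] * theta + p.rim_phase) > 0)
        )
        amp[dashed] = rim["transmission"]
    return amp


def transmission_mask(p: ParticleSpec, optics: OpticalConfig) -> np.ndarray:
    """Complex transmission of one particle at its own plane."""
    rho, theta = _radial_grids(p, optics)
    amp = _amplitude_profile(p, rho, theta)
    phase = (2.0 * np.pi / optics.wavelength) * p.index_contrast * _thickness_profile(
        p, rho, theta
    )
    return amp * np.exp(1j * phase)


def render_hologram(scene: SceneConfig) -> Hologram:
    """Render the in-line hologram of a scene (coherent forward model)."""
    particles = _visible_particles(scene)
    optics = scene.optics
    sensor = np.ones(optics.image_shape, dtype=np.complex128)
    for p in particles:
        scattered = ComplexField(transmission_mask(p, optics) - 1.0, optics)
        sensor += propagate(scattered, p.z).values
    intensity = np.abs(sensor) ** 2
    # exposure: constructive fringes exceed the unit reference level, so the
    # recorded frame is scaled into the [0, 1] dynamic range.  A fixed
    # exposure_scale emulates one camera setting shared by a whole dataset;
    # otherwise the frame is auto-exposed for the given intensity percentile
    # (letting rare caustic highlights saturate; 100 exposes for the absolute
    # peak).  An empty scene stays at exactly 1.0 under auto-exposure.
    if scene.exposure_scale is not None:
        intensity = intensity / scene.exposure_scale
    else:
        scale = np.percentile(intensity, scene.exposure_percentile)
        if scale > 1.0:
            intensity = intensity / scale
    # child streams of the scene seed keep the BF/hologram pair jointly
    # reproducible while making their noise draws independent
    rng = np.random.default_rng([scene.rng_seed, 0])
    if scene.noise_sigma_hologram > 0:
        intensity = intensity + rng.normal(0.0, scene.noise_sigma_hologram, intensity.shape)
    return Hologram(
        np.clip(intensity, 0.0, 1.0), optics, provenance="simulated", particles=list(particles)
    )


def _disk_kernel(radius_px: float, max_px: int) -> np.ndarray:
    """Area-normalized uniform disk kernel (geometric defocus blur)."""
    r = max(radius_px, 0.5)
    n = min(int(np.ceil(r)) * 2 + 1, 2 * max_px + 1)
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    kernel = ((yy - c) ** 2 + (xx - c) ** 2 <= r**2).astype(np.float64)
    return kernel / kernel.sum()


def render_brightfield(scene: SceneConfig) -> BFImage:
    """Render the defocused bright-field image of a scene (incoherent model)."""
    particles = _visible_particles(scene)
    optics = scene.optics
    pitch = optics.pixel_pitch
    absorption = np.zeros(optics.image_shape)
    for p in particles:
        rho, _ = _radial_grids(p, optics)
        disk = (rho < p.radius).astype(np.float64) * scene.bf_contrast
        blur_px = scene.bf_blur_coefficient * p.z / pitch
        if blur_px > 0.5:
            kernel = _disk_kernel(blur_px, max(optics.image_shape))
            disk = fftconvolve(disk, kernel, mode="same")
        absorption += disk
    image = 1.0 - absorption
    rng = np.random.default_rng([scene.rng_seed, 1])
    if scene.noise_sigma_bf > 0:
        image = image + rng.normal(0.0, scene.noise_sigma_bf, image.shape)
    return BFImage(np.clip(image, 0.0, 1.0), optics, particles=list(particles))


def render_pair(scene: SceneConfig) -> tuple[BFImage, Hologram]:
    """Render the registered BF/hologram pair of one scene."""
    return render_brightfield(scene), render_hologram(scene)


def _random_scene(
    rng: np.random.Generator,
    optics: OpticalConfig,
    n_particles: int,
    depth_range: tuple[float, float],
    radius: float,
    kind: str,
    noise_sigma_hologram: float,
    noise_sigma_bf: float,
    seed: int,
    margin_um: float | None = None,
) -> SceneConfig:
    """Draw non-overlapping particle positions uniformly inside the FOV."""
    height, width = optics.extent
    margin = radius * 1.5 if margin_um is None else margin_um
    particles: list[ParticleSpec] = []
    attempts = 0
    while len(particles) < n_particles and attempts < 2000:
        attempts += 1
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, height - margin)
        if any(np.hypot(p.x - x, p.y - y) < 3.0 * radius for p in particles):
            continue
        z = rng.uniform(*depth_range)
        particles.append(
            ParticleSpec(
                x=x, y=y, z=z, radius=radius, kind=kind,
                rim_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
            )
        )
    return SceneConfig(
        particles=particles,
        optics=optics,
        noise_sigma_hologram=noise_sigma_hologram,
        noise_sigma_bf=noise_sigma_bf,
        rng_seed=seed,
    )


def make_dataset(
    n_pairs: int,
    out_dir: str | Path,
    seed: int,
    particle_density: tuple[int, int] = (1, 3),
    depth_range: tuple[float, float] = (0.0, 200.0),
    optics: OpticalConfig | None = None,
    radius: float = 7.46,
    kind: str = "sphere",
    noise_sigma_hologram: float = 0.06,
    noise_sigma_bf: float = 0.02,
    exposure_scale: float | None = 1.5,
    margin_um: float | None = None,
    write_images: bool = True,
) -> pd.DataFrame:
    """Generate a paired BF/hologram training set with a ground-truth manifest.

    Every pair shows a different random particle distribution; depths are
    drawn uniformly from ``depth_range``.  Images are written as 16-bit
    single-channel TIFFs and the manifest as ``manifest.csv`` with one row per
    particle (columns pair_id, bf_path, holo_path, particle_id, x_um, y_um,
    z_um, radius_um, kind).  The same ``seed`` replays the dataset bit-exactly.

    Returns the manifest DataFrame.  With ``write_images=False`` only the
    manifest (with empty path columns) is produced in memory -- useful for
    pipelines that keep the arrays resident.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    lo, hi = int(particle_density[0]), int(particle_density[1])
    if not (1 <= lo <= hi):
        raise ValueError("particle_density must be a positive (low, high) range")
    optics = optics or OpticalConfig()
    out_dir = Path(out_dir)
    if write_images:
        out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for pair_id in range(n_pairs):
        n_particles = int(rng.integers(lo, hi + 1))
        scene = _random_scene(
            rng, optics, n_particles, depth_range, radius, kind,
            noise_sigma_hologram, noise_sigma_bf,
            seed=int(rng.integers(0, 2**31 - 1)),
            margin_um=margin_um,
        )
        scene = replace(scene, exposure_scale=exposure_scale)
        bf, holo = render_pair(scene)
        bf_path = holo_path = ""
        if write_images:
            from .imgio import write_image

            bf_path = str(out_dir / f"pair{pair_id:05d}_bf.tif")
            holo_path = str(out_dir / f"pair{pair_id:05d}_holo.tif")
            write_image(bf.values, bf_path)
            write_image(holo.values, holo_path)
        for particle_id, p in enumerate(scene.particles):
            rows.append(
                dict(
                    pair_id=pair_id, bf_path=bf_path, holo_path=holo_path,
                    particle_id=particle_id, x_um=p.x, y_um=p.y, z_um=p.z,
                    radius_um=p.radius, kind=p.kind, rim_phase=p.rim_phase,
                    scene_seed=scene.rng_seed,
                )
            )
    manifest = pd.DataFrame(rows)
    if write_images:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def scene_from_manifest_rows(
    rows: pd.DataFrame,
    optics: OpticalConfig,
    noise_sigma_hologram: float = 0.06,
    noise_sigma_bf: float = 0.02,
    exposure_scale: float | None = 1.5,
) -> SceneConfig:
    """Rebuild the SceneConfig of one manifest pair (for in-memory replay)."""
    particles = [
        ParticleSpec(
            x=r.x_um, y=r.y_um, z=r.z_um, radius=r.radius_um, kind=r.kind,
            rim_phase=getattr(r, "rim_phase", 0.0),
        )
        for r in rows.itertuples()
    ]
    return SceneConfig(
        particles=particles, optics=optics,
        noise_sigma_hologram=noise_sigma_hologram, noise_sigma_bf=noise_sigma_bf,
        rng_seed=int(rows.iloc[0].scene_seed),
        exposure_scale=exposure_scale,
    )
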