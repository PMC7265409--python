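"""Light-scattering x-z maps and real/virtual focal lengths of particles.

A transparent microparticle acts as a micro-lens.  Stacking, for every
reconstructed depth, the intensity profile along a line through the particle
center yields an x-z scattering map in which the lensing shows up as bright
on-axis spots away from the particle plane.  Under the default
back-propagation convention the illumination travels from the particle toward
the recording plane (decreasing reconstruction depth), so a *converging*
particle (a bead, an echinocyte, a discocyte's toroidal rim) concentrates
light at depths *shallower* than the particle -- the real focus -- while a
diverging feature (the discocyte's central dimple) back-projects to an
apparent source *deeper* than the particle -- the virtual focus.  Flipping
the reconstruction's propagation sign inverts the meaning of the depth axis
and therefore swaps the two labels.

A discocyte thus shows two foci (real + virtual), while a sphere or an
echinocyte shows a single real focus: the morphology signature used to
distinguish the two erythrocyte states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .locate import Particle3D
from .reconstruct import ReconstructionStack

__all__ = ["Focus", "ScatterMap", "extract_scatter_map", "find_foci"]


@dataclass(frozen=True)
class Focus:
    """One detected focal spot: its type, focal length and peak intensity."""

    kind: str  # "real" or "virtual"
    focal_length: float  # |z_peak - particle_z| in um
    peak_intensity: float
    z: float  # depth of the peak in the reconstruction volume


@dataclass
class ScatterMap:
    """x-z intensity map of one particle plus its detected foci."""

    intensity: np.ndarray  # (n_z, line_length)
    z_values: np.ndarray
    line: tuple[tuple[int, int], tuple[int, int]]  # (row, col) endpoints in pixels
    center_index: int  # index of the particle axis within the line
    particle_z: float
    particle_radius: float
    foci: list[Focus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("scatter map intensities must be nonnegative")

    @property
    def on_axis(self) -> np.ndarray:
        """Intensity along the particle axis as a function of depth."""
        return self.intensity[:, self.center_index]


def extract_scatter_map(
    stack: ReconstructionStack,
    particle: Particle3D,
    half_length_px: int | None = None,
    orientation: str = "horizontal",
) -> ScatterMap:
    """Stack the line profile through a particle's center across all depths.

    The sampled segment is horizontal by default (``orientation`` may be
    "vertical"); it is clipped, with a warning, where it would leave the
    image.  Rows of the returned map are ordered by increasing z and all rows
    have equal width.
    """
    pitch = stack.optics.pixel_pitch
    col = int(round(particle.x / pitch - 0.5))
    row = int(round(particle.y / pitch - 0.5))
    n_rows, n_cols = stack.amplitudes.shape[1:]
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise ValueError("particle center lies outside the reconstruction volume")
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    axis_len = n_cols if orientation == "horizontal" else n_rows
    along = col if orientation == "horizontal" else row
    if half_length_px is None:
        half_length_px = axis_len // 2
    lo, hi = along - half_length_px, along + half_length_px + 1
    if lo < 0 or hi > axis_len:
        warnings.warn("scatter-map line clipped at the image border", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, axis_len)
    if orientation == "horizontal":
        profile = stack.amplitudes[:, row, lo:hi]
        line = ((row, lo), (row, hi - 1))
    else:
        profile = stack.amplitudes[:, lo:hi, col]
        line = ((lo, col), (hi - 1, col))
    return ScatterMap(
        intensity=np.asarray(profile, dtype=np.float64),
        z_values=stack.z_values,
        line=line,
        center_index=along - lo,
        particle_z=float(particle.z),
        particle_radius=getattr(particle, "radius", 7.46),
    )


def find_foci(
    scatter_map: ScatterMap,
    particle_z: float | None = None,
    prominence: float = 0.35,
    dead_zone: float | None = None,
    propagation_sign: int = -1,
) -> list[Focus]:
    """Detect focal spots on the on-axis depth profile of a scattering map.

    1-D peaks are found on the on-axis intensity column (prominence is
    relative to the profile maximum, so the detection is invariant to global
    intensity scaling), excluding a dead zone of +/- one particle diameter
    around the particle plane so the particle's own refocused image is not
    counted.  With the default back-propagation convention
    (``propagation_sign = -1``) peaks shallower than the particle are real
    foci and deeper peaks are virtual; the labels swap for ``+1``.
    The focal length is |z_peak - particle_z|.
    """
    if particle_z is None:
        particle_z = scatter_map.particle_z
    if dead_zone is None:
        dead_zone = 2.0 * scatter_map.particle_radius
    profile = scatter_map.on_axis
    scale = float(profile.max())
    if scale <= 0:
        return []
    indices, props = find_peaks(profile / scale, prominence=prominence)
    real_is_shallow = propagation_sign == -1
    foci = []
    for idx in indices:
        z = float(scatter_map.z_values[idx])
        if abs(z - particle_z) <= dead_zone:
            continue
        shallow = z < particle_z
        kind = "real" if shallow == real_is_shallow else "virtual"
        foci.append(
            Focus(
                kind=kind,
                focal_length=abs(z - particle_z),
                peak_intensity=float(profile[idx]),
                z=z,
            )
        )
    return foci
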