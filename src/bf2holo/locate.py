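"""3D particle localization from a reconstruction volume.

The pipeline is the standard one for in-line holography:

1. project the amplitude volume onto a single 2D contrast map and find the
   in-plane (x, y) particle positions as local intensity maxima (with 3x3
   centroid sub-pixel refinement);
2. segment a window around each position and scan it through every
   reconstructed depth, scoring sharpness with the 2D intensity variance

       VAR(z) = (1 / Nx Ny) * sum_xy (I(x, y, z) - mean I(z))^2 ;

3. assign each particle the depth at which VAR peaks (ties break toward the
   smallest z).

The variance autofocus is invariant to adding a constant to the window and
scales quadratically under intensity scaling; the full focus curve is kept on
every detection for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .reconstruct import ReconstructionStack, project_stack

__all__ = [
    "PeakParams",
    "Particle3D",
    "find_inplane_positions",
    "variance_focus",
    "assign_depth",
    "locate_all",
]


@dataclass(frozen=True)
class PeakParams:
    """In-plane peak detection parameters.

    min_distance: non-maximum-suppression radius in pixels; threshold:
    relative intensity floor (fraction of the global maximum); the window
    half-size (pixels) controls the segmentation used for depth assignment
    (default 28 px, about twice a 14.92 um bead's radius at the 20x pitch,
    which captures the refocused core plus the first fringe).
    """

    min_distance: int = 15
    threshold: float = 0.45
    window_half_size: int = 28
    #: Gaussian smoothing (pixels) applied to the projection before peak
    #: detection.  A refocused particle projects as a dark disk plus a sharp
    #: rim, i.e. an annular contrast pattern; smoothing at roughly the
    #: particle radius merges it into a single centered blob so the local
    #: maximum falls on the particle center.  None resolves to half the
    #: window half-size; 0 disables smoothing.
    smooth_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.window_half_size < 1:
            raise ValueError("window_half_size must be >= 1")

    @property
    def resolved_smooth_sigma(self) -> float:
        if self.smooth_sigma is None:
            return 0.5 * self.window_half_size
        return float(self.smooth_sigma)


@dataclass
class Particle3D:
    """One detected particle: position (um), peak strength and its focus curve."""

    x: float
    y: float
    z: float
    peak_intensity: float
    focus_curve: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    window_half_size: int = 0


def _centroid_refine(
    image: np.ndarray, row: int, col: int, radius: int = 1, n_iter: int = 1
) -> tuple[float, float]:
    """Iterative (mean-shift) intensity-centroid refinement around a peak.

    The default radius of 1 with one iteration is the classic 3x3 centroid.
    Peaks found on a smoothed projection are broad — and for a particle that
    projects as an annulus the raw local maximum can sit on the ring rather
    than at its center — so the caller widens the patch with the smoothing
    scale and iterates: each pass recenters the window on the previous
    centroid, which converges onto the blob's center of mass.
    """
    r, c = float(row), float(col)
    for _ in range(max(n_iter, 1)):
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = max(ri - radius, 0), min(ri + radius + 1, image.shape[0])
        c0, c1 = max(ci - radius, 0), min(ci + radius + 1, image.shape[1])
        patch = image[r0:r1, c0:c1].astype(np.float64)
        patch = patch - patch.min()
        total = patch.sum()
        if total <= 0:
            return r, c
        rr, cc = np.mgrid[r0:r1, c0:c1]
        r_new = float((patch * rr).sum() / total)
        c_new = float((patch * cc).sum() / total)
        if abs(r_new - r) < 0.05 and abs(c_new - c) < 0.05:
            r, c = r_new, c_new
            break
        r, c = r_new, c_new
    return r, c


def find_inplane_positions(
    projection: np.ndarray, params: PeakParams, pixel_pitch: float = 1.0
) -> list[tuple[float, float]]:
    """Locate in-plane particle positions on a projection image.

    Returns (x, y) positions in micrometres (x along columns, y along rows,
    measured from the image corner; positions refer to pixel centers).  An
    image without peaks yields an empty list.
    """
    projection = np.asarray(projection, dtype=np.float64)
    if projection.size == 0:
        raise ValueError("projection image is empty")
    if not np.all(np.isfinite(projection)):
        raise ValueError("projection image must be finite")
    if projection.max() <= 0 or np.ptp(projection) == 0:
        return []
    sigma = params.resolved_smooth_sigma
    if sigma > 0:
        projection = gaussian_filter(projection, sigma)
    # the border strip is excluded: convolutional edge effects (and the
    # generator's frame artifacts on translated holograms) otherwise both
    # spawn false maxima and inflate the relative threshold
    margin = min(params.min_distance, min(projection.shape) // 4)
    interior = projection[margin:-margin, margin:-margin] if margin else projection
    peaks = peak_local_max(
        projection,
        min_distance=params.min_distance,
        threshold_abs=params.threshold * float(interior.max()),
        exclude_border=margin,
    )
    radius = max(1, int(round(sigma)))
    n_iter = 1 if sigma == 0 else 4
    positions = []
    for row, col in peaks:
        r, c = _centroid_refine(projection, int(row), int(col), radius, n_iter)
        positions.append(((c + 0.5) * pixel_pitch, (r + 0.5) * pixel_pitch))
    return positions


def variance_focus(window: np.ndarray) -> float:
    """2D intensity variance of a window: the autofocus (sharpness) value."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("focus window is empty")
    return float(np.mean((window - window.mean()) ** 2))


def _window_bounds(
    shape: tuple[int, int], row: int, col: int, half: int
) -> tuple[int, int, int, int]:
    r0, r1 = max(row - half, 0), min(row + half + 1, shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        raise ValueError("segmentation window lies entirely outside the image")
    return r0, r1, c0, c1


def assign_depth(
    stack: ReconstructionStack,
    xy: tuple[float, float],
    window_half_size: int = 28,
) -> Particle3D:
    """Assign a depth to one in-plane position by variance autofocus.

    The window around (x, y) is scored with :func:`variance_focus` at every
    reconstructed depth; the depth of the maximum is the particle's z.  Equal
    focus values break toward the smaller z.  The window is clipped at image
    borders.
    """
    pitch = stack.optics.pixel_pitch
    col = int(round(xy[0] / pitch - 0.5))
    row = int(round(xy[1] / pitch - 0.5))
    shape = stack.amplitudes.shape[1:]
    if not (0 <= row < shape[0] and 0 <= col < shape[1]):
        raise ValueError(f"position {xy} um lies outside the image")
    r0, r1, c0, c1 = _window_bounds(shape, row, col, window_half_size)
    windows = stack.amplitudes[:, r0:r1, c0:c1].astype(np.float64)
    means = windows.mean(axis=(1, 2), keepdims=True)
    curve = np.mean((windows - means) ** 2, axis=(1, 2))
    best = int(np.argmax(curve))  # argmax returns the first (smallest-z) tie
    return Particle3D(
        x=float(xy[0]),
        y=float(xy[1]),
        z=float(stack.z_values[best]),
        peak_intensity=float(stack.amplitudes[best, row, col]),
        focus_curve=np.column_stack([stack.z_values, curve]),
        window_half_size=window_half_size,
    )


def refine_depth_parabolic(particle: Particle3D) -> float:
    """Optional 3-point parabolic interpolation of the focus-curve maximum.

    Returns a sub-interval depth estimate; at 1 um depth steps the plain
    argmax is normally sufficient, so this is not applied by default.
    """
    z, var = particle.focus_curve[:, 0], particle.focus_curve[:, 1]
    k = int(np.argmax(var))
    if k == 0 or k == len(z) - 1:
        return float(z[k])
    denom = var[k - 1] - 2.0 * var[k] + var[k + 1]
    if denom >= 0:
        return float(z[k])
    return float(z[k] + 0.5 * (var[k - 1] - var[k + 1]) / denom * (z[k + 1] - z[k]))


def locate_all(
    stack: ReconstructionStack,
    params: PeakParams | None = None,
    reducer: str = "max",
) -> list[Particle3D]:
    """Full 3D localization: projection -> in-plane peaks -> depth assignment.

    ``reducer`` selects the projection (see
    :func:`~bf2holo.reconstruct.project_stack`); "max_intensity" follows the
    refocused bright particle cores only, which is the robust choice for
    network-generated holograms whose dark structure is less faithful.
    """
    params = params or PeakParams()
    projection = project_stack(stack, reducer=reducer)
    positions = find_inplane_positions(projection, params, stack.optics.pixel_pitch)
    return [assign_depth(stack, xy, params.window_half_size) for xy in positions]
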