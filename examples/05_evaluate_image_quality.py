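"""Score hologram quality with the package's metrics: SNR, SSIM, L2.

Constructs a ground-truth hologram plus a denoised counterpart (background
noise reduced fourfold, as a stand-in for a generated hologram) and prints
how each metric responds.
"""

import numpy as np

from bf2holo import OpticalConfig, ParticleSpec, SceneConfig, render_hologram
from bf2holo.metrics import fringe_signal_mask, mse_rms, snr, ssim_global

optics = OpticalConfig(image_shape=(256, 256))
particle = ParticleSpec(x=70.0, y=65.0, z=80.0)

truth = render_hologram(
    SceneConfig(particles=[particle], optics=optics, noise_sigma_hologram=0.06, rng_seed=5)
).values
denoised = render_hologram(
    SceneConfig(particles=[particle], optics=optics, noise_sigma_hologram=0.015, rng_seed=5)
).values

pitch = optics.pixel_pitch
center = (particle.y / pitch - 0.5, particle.x / pitch - 0.5)
support = (particle.radius + 2.0 * np.sqrt(optics.wavelength * particle.z)) / pitch
mask = fringe_signal_mask(truth.shape, [center], [support])

print(f"signal mask: {mask.values.sum()} fringe pixels of {mask.values.size}")
print(f"SNR (noisy ground truth):      {snr(truth, mask):6.2f}")
print(f"SNR (noise reduced fourfold):  {snr(denoised, mask):6.2f}")
print(f"SSIM between the two:          {ssim_global(denoised, truth):6.3f}")
print(f"L2 (RMS) difference:           {mse_rms(denoised, truth):6.4f}")
print("\nSNR scales inversely with the background noise level: cutting the")
print("detector noise fourfold yields a several-fold SNR gain at equal signal")
print("(residual coherent fringe tails in the background keep it below 4x).")
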