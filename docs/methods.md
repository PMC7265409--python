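# Methods

`bf2holo` implements, end to end and on synthetic data, the computational
chain of GAN-assisted digital in-line holographic microscopy (DIHM): a
translation network converts a defocused bright-field (BF) micrograph into an
in-line hologram, and the hologram is then analyzed numerically — refocused
over a depth range, searched for particles in 3D, and probed for the
light-scattering foci that distinguish particle morphologies.  This note
records the models, the parameter choices that matter, and what the
synthetic experiments do and do not demonstrate.

## Wave optics

A recorded hologram `h(x, y)` is treated as a complex field with zero
imaginary part and propagated by the angular spectrum method: multiply its
2D FFT by the free-space transfer function

    H_z(f_x, f_y) = exp( i z (2π/λ) sqrt(1 − (λ f_x)² − (λ f_y)²) )

and invert.  Spectral coordinates follow the discrete-Fourier convention
with spacing `1/(N·pixel_pitch)`.  Components with `(λf)² > 1` are
evanescent; they are zeroed rather than allowed to grow exponentially under
back-propagation, which keeps `+z` and `−z` exact inverses on the
propagating band and makes energy exactly conserved there (both properties
are tested at 1e−10).  No window or apodization is applied before the FFT.

Reconstruction uses the conjugate (back-propagation) direction so that a
particle recorded at depth `z` above the sensor refocuses at reconstruction
depth `z`; a `propagation_sign` flag flips the convention.  A 0–300 µm
volume at 1 µm steps therefore contains 301 planes.  Plane k is the modulus
`|Γ(ξ, η, z_k)|`.  An optional mean-subtraction flag removes the hologram's
DC term before propagation; the localization pipeline uses it by default
because the modulus of the zero-mean field gives a much sharper contrast
between a refocused particle and its own defocused fringe pattern.  Volumes
can be streamed plane by plane (`iter_planes`), so a full-resolution stack
never has to be resident.

Default optical sampling: λ = 0.532 µm; 0.53 µm/pixel (20× objective, beads)
or 0.18 µm/pixel (60×, erythrocytes).

## Synthetic scenes

The simulator replaces a hybrid two-camera microscope that records a BF
image and a hologram of the same scene simultaneously.  Both views are
rendered from one ground-truth particle list, so every dataset carries
exact 3D positions for training and validation.

**Holograms (coherent).**  Each particle is a thin complex transmission mask
at its own plane — an amplitude silhouette times a phase proportional to the
local optical thickness (index contrast × geometric thickness).  Each
particle's scattered field `t − 1` is propagated to the sensor by its depth
and the per-particle waves are superposed coherently on a unit reference
wave (first-order scattering), so inter-particle interference is present.
The recorded intensity `|field|²` is auto-exposed — divided by its 99.5th
percentile, emulating a camera exposed for the fringes with rare caustic
highlights saturating — then zero-mean Gaussian noise is added (default
σ = 0.06, matching the background noise level of experimentally recorded
in-line holograms, σ ≈ 5–7 × 10⁻²) and the result is clipped to [0, 1].
An empty scene records exactly 1.0.  Scenes set `exposure_percentile=100`
when an unsaturated caustic matters (scattering studies).

**The bead model.**  A 14.92 µm polystyrene bead at 20×/NA 0.5 is modeled
by what the *collection aperture* sees, not by its bulk optics: at the bead
edge the thickness gradient refracts light far outside the aperture, so the
rim records as nearly opaque (transmission 0.02 beyond 0.85 R) while the
interior keeps transmission 0.85, and the default phase contrast is zero.
Two deliberate choices here:

* *Zero default phase.*  A thin-screen lens phase concentrates light into an
  axial caustic that stays inside any segmentation window at every depth and
  systematically defeats window-variance autofocus.  Since the collected
  paraxial phase of a real bead is weak after NA truncation, the default
  bead is a pure amplitude silhouette; transparent "lens" beads for
  scattering studies set `refractive_index_contrast` explicitly (0.12 puts
  the focal spot a few bead diameters upstream).
* *Azimuthally dashed rim.*  A uniform dark annulus is itself a ring lens
  whose on-axis lobe (at ~ρ²/2λ) rivals the refocused image; texturing the
  rim azimuthally (12 dashes, emulating surface roughness) removes the
  coherent ring focus while keeping the sharp high-frequency rim that makes
  the variance focus curve peak hard at the true depth.

**Erythrocytes (60×).**  Discocytes use an Evans–Fung biconcave thickness
profile (central dimple, toroidal rim; default radius 3.91 µm, effective
phase contrast 0.18); echinocytes a convex spherical-cap profile with a
sinusoidal perimeter perturbation (12 spicules, depth 0.08 R, contrast
0.25).  These contrasts are *effective* thin-screen parameters calibrated so
the reconstructed x–z maps show the morphology signatures — the discocyte's
real + virtual focus pair, the echinocyte's single real focus — with the
focal spots outside the particle's own refocus dead zone.  The resulting
focal lengths (~8–10 µm) are shorter than those measured on real cells
(tens of µm), because a thin phase screen at the cell's actual curvature
produces foci too weak to detect at this wavelength; the *pair versus
single* signature, not the focal length value, is the validated feature.

**Bright field (incoherent).**  Each particle is an in-focus absorption disk
(contrast 0.85) convolved with a uniform-disk defocus kernel whose radius
grows linearly with depth (0.12 µm of kernel radius per µm of depth, an
effective geometric blur for a mid-NA objective); blurred disks add in
intensity, plus Gaussian noise (σ = 0.02).  Only the monotone
blur-and-contrast-versus-depth relationship matters: it is the cue the
translation network must learn to invert.  BF formation is otherwise not a
faithful imaging model.

All randomness in a scene flows from one seed (hologram and BF noise are
independent child streams), so rendering is bit-reproducible; datasets
(`make_dataset`) draw non-overlapping positions and uniform depths and write
16-bit TIFFs plus a CSV manifest with one row per ground-truth particle.

## 3D localization

1. **Projection.**  The amplitude volume is collapsed per pixel by the
   maximum over depth of the contrast `|amplitude − plane mean|`, so both
   dark (absorbing) and bright (refocused) structures project positively.
2. **In-plane peaks.**  The projection is smoothed with a Gaussian of about
   the particle radius (a refocused bead projects as a disk-plus-rim annulus
   that must merge into one centered blob), then local maxima above a
   relative threshold are taken with non-maximum suppression, excluding a
   border strip one suppression radius wide (convolutional edge artifacts on
   translated holograms otherwise dominate the global maximum).  Sub-pixel
   positions come from an intensity centroid whose radius tracks the
   smoothing scale.  Defaults: min_distance 15 px, threshold 0.45,
   window half-size 28 px (≈ 2 bead radii at 20×), smoothing = half the
   window half-size.
3. **Depth.**  Around each in-plane position a window is scanned through
   every reconstructed plane and scored with the 2D intensity variance
   `VAR(z) = mean((I − mean I)²)`; the depth of the maximum is the particle's
   z.  Ties break toward the smaller z (tested).  Variance is invariant to
   constant offsets and quadratic under intensity scaling.  No interpolation
   of the focus curve is applied by default; a 3-point parabolic refinement
   is available (`refine_depth_parabolic`) but at 1 µm steps the plain
   argmax is already grid-limited.

Measured on the synthetic study conditions (256² holograms, noise σ = 0.06,
depth steps of 1 µm): lateral RMS error ≈ 0.3 µm (about half a pixel), axial
errors at the 1 µm grid limit for depths above ~10 µm.  **Known
limitation:** within about one bead diameter of the recording plane
(z ≲ 10 µm) the hologram, its twin image and the refocused image overlap so
strongly that the variance maximum sits at the hologram plane itself — the
assigned depth collapses to ~0 even without noise.  This shallow degeneracy
is intrinsic to in-line holography with this autofocus, not a numerical
artifact; consequently axial RMS error *decreases* from the shallowest
depth bin outward instead of growing with depth the way real-instrument
data do (real deep-depth degradation comes from speckled backgrounds,
aberrations and motion that these clean synthetic holograms do not carry).

## Light scattering

For one particle, the intensity profile along the horizontal (optionally
vertical) line through its center is extracted from every plane and stacked
into an x–z map.  1-D peaks on the on-axis column (relative prominence
≥ 0.35, invariant to intensity scaling) outside a dead zone of ± one
particle diameter around the particle plane are classified: with the
default back-propagation convention, illumination travels from the particle
toward the recording plane, so a *converging* particle concentrates light
at depths shallower than itself — the **real** focus — while a diverging
feature back-projects to an apparent source deeper than the particle — the
**virtual** focus.  Flipping the reconstruction's propagation sign inverts
the depth axis's meaning and therefore swaps the labels.  (For a
real-valued hologram the amplitude volume itself is identical under either
sign, so only the labelling can flip.)  The focal length is
`|z_peak − z_particle|`.

## The translation network

**Generator.**  A coarse-to-fine multiscale CNN with a linear shortcut.
The BF image enters at four resolutions (linear scales 1, 1/2, 1/4, 1/16 —
pixel counts n, n/2², n/2⁴, n/2⁸); downsampling is *anti-aliased* area
interpolation because plain block averaging quantizes a sub-coarse-pixel
particle's position to the 16-pixel grid and caps the whole network's
translation accuracy.  Processing starts at the coarsest scale, and each
scale's features are bilinearly upsampled and concatenated with the next
finer input.  Per scale: three 3×3 reflect-padded convolutions with leaky
ReLU (zero padding imprints a frame of border artifacts that later defeats
peak detection on translated holograms); widths 6, 12, 12, 12 coarse→fine;
a final 3×3 convolution (zero-initialized) emits the CNN's contribution.
In parallel, a zero-initialized 25-pixel *linear* convolution maps the
full-resolution input directly to the output: the BF-to-hologram map is,
to first order, a linear re-convolution of the particle silhouette with a
ring kernel, and this convex path converges quickly to a centered response
while the nonconvex CNN grows only the residual.  The sum is clipped to
[0, 1] at inference; inputs of any size divisible by 16 work (others are
edge-padded), and full-image inference adds a 32-pixel edge apron that is
cropped away.  None of this is canonical — the sizes are chosen for
single-CPU training and are configurable through `GeneratorSpec`.

**Discriminator.**  Four stride-2 3×3 convolutions (widths 8, 16, 32, 64)
with leaky ReLU, then two fully connected layers and a sigmoid: a realism
score strictly inside (0, 1).  The dense head ties it to the training crop
size; it is not used at inference.

**Losses.**  Generator: RMS image error against the paired ground-truth
hologram plus the binary cross-entropy of its discriminator score against 1.
Discriminator: BCE of its scores on generated crops against 0 and on real
crops against 1.  Scores of exactly 0/1 are clamped at 1e−7.  The image
term is the root of the *mean of squared* differences; the same quantity is
the "L2 error" tracked on held-out pairs during training.

**Optimization.**  Per iteration, four 256×256 crops are taken at random
positions from randomly chosen training pairs; one discriminator step
(SGD, learning rate 2e−2, momentum 0.9, weight decay 5e−5) then one
generator step (Adam, learning rate 4e−6, default betas) — that is the
reference protocol, intended for runs of order 10⁵ iterations.  The
discriminator's gradient is clipped to unit global norm: without any
normalization layers, SGD at 2e−2 otherwise enters an exploding-activation
regime within tens of iterations.  All randomness (initialization, pair
selection, crop positions) derives from one seed; training is bit
reproducible, and checkpoints (weights + config + iteration) are single
`.npz` archives that support resuming.

**Desk-scale profile** (`TrainConfig.smoke`): 64×64 crops, a few thousand
iterations, generator Adam at 5e−4 annealed 10× over the run, and the
discriminator slowed to SGD at 1e−6.  The rates are rescaled with the
~100× shorter schedule, and deliberately asymmetrically: a discriminator
that is only half-trained does not produce a useful realism gradient — its
input Jacobian is a systematic bias that measurably displaces the
synthesized pattern by several pixels — so at this schedule the adversary
is made effectively inert and the image term leads.  (Both loss terms are
still computed and optimized exactly as defined.)  The learning-rate
anneal matters for a different reason: at a constant high rate the
optimizer's gradient noise floor erases the weak input-conditional
structure and the network collapses to predicting the mean background.
The network engine is a small self-contained numpy stack (explicit
backpropagation, GEMM convolutions, FFT for the wide skip kernel) —
sufficient for these model sizes on one CPU.

At this scale, training on ~200 simulated 128² pairs (depths 20–80 µm)
reduces held-out L2 error about six-fold relative to the untrained network
(≈0.68 → ≈0.11, approaching the ≈0.06 noise floor), and the translated
holograms show the coarse structure of the truth: a centered core-plus-ring
pattern at each particle.  **Known limitation:** the desk-scale schedule is
not enough for particle-accurate synthesis.  The synthesized pattern
carries a seed-dependent residual displacement of roughly 2–6 pixels, so
re-localizing particles from translated holograms at a 2-pixel tolerance
recovers only a small fraction of them (a few percent to a few tens of
percent depending on the seed).  The reference protocol behind the
full-quality result — 5×10⁵ iterations over 10⁴ image pairs on GPU
hardware — is about two orders of magnitude beyond this profile, and the
held-out-error curve of the reference run only converges on the 10⁵
iteration scale.  What a desk-scale pass does show is the direction of the
mapping (blur → fringe structure, error decreasing steadily); what it does
not show is end-to-end positional fidelity.

## What the synthetic data do not show

* Real paired acquisitions have sub-pixel registration error between the
  two cameras; the simulator is perfectly registered.
* Real hologram backgrounds carry structured coherent noise (dust rings,
  reflections, speckle); the simulator's background noise is white, which
  makes deep-particle localization easier than on real data (and flattens
  the growth of axial error with depth).
* The bead and cell masks are thin screens with effective, aperture-aware
  parameters, not rigorous Lorenz–Mie scatterers; focal-length *values* for
  cells are not comparable to real measurements, only focal *signatures*.
* Flow motion, exposure blur, and camera shot noise are not modeled.
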