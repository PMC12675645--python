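# Methods

This note documents the models, numerical choices and limitations behind
`fluorosynth`, in the order the pipeline runs.

## Digital thorax phantom

The phantom is a set of analytic solids rasterized onto a voxel grid
(axes x = left–right, y = anterior–posterior, z = superior–inferior, voxel
centers at `(i+0.5)·spacing` mm):

- an elliptic soft-tissue cylinder for the torso (semi-axes 0.44/0.36 of
  the grid extent);
- two ellipsoidal lungs (semi-axes 0.14/0.20/0.32 of extent, lateral
  offset ±0.20);
- a posterior spine cylinder (radius 0.06 of the smaller transverse
  extent);
- 9 curved rib arcs per side: a radial band (0.80–0.95 of the normalized
  torso radius) intersected with an azimuthal band (12°–150° from
  posterior) and a per-rib z-slab of ±4 mm half-thickness that droops
  15 mm from posterior to anterior — enough to recreate the rib/tumor
  overlap that motivates bone suppression;
- a spherical tumor (default 10 mm diameter) inside the right lung.

Respiration is the standard surrogate `d(p) = A·sin²(π(p−1)/P)` with
P = 10 phases and default amplitude A = 10 mm; phase 1 is the full-exhale
reference. Lungs and tumor translate rigidly together in z (so tumor
containment needs checking only once); torso, ribs and spine are static.
This is a deliberate simplification of diaphragmatic breathing: it
conserves per-material voxel counts across phases and produces a clean,
exactly known tumor trajectory, at the cost of no hysteresis, no tissue
deformation and no rib motion.

Attenuation is assigned per material at two effective monoenergetic
energies standing in for 120/60 kVp spectra (1/cm): soft tissue 0.18/0.25,
lung 0.04/0.06, rib and spine 0.30/0.60, tumor 0.19/0.27, air exactly 0.
The bone HE/LE ratio is exactly 0.5, so the soft-tissue weight ω = 0.5
cancels the bone *attenuation* contribution analytically — the central
oracle of the test suite. Note one physical consequence used below: a rib
voxel displaces soft tissue, so even perfectly cancelled bone leaves a
soft-tissue *deficit* ("rib void") of 0.055/cm·pathlength in the DES
image; this is real DES physics for binary materials, not an artifact.

## Rotation and projection

Volumes are rotated about the grid center with the composition
`R = Rx(θ)·Ry(φ)·Rz(γ)` of the elemental matrices in their printed form
(the stray entry at position (3,2) of Rz is read as a typographical 0; Ry
carries −sin φ in its first row, the transpose of the more common
right-handed convention — both forms are proper rotations, and the
convention is documented rather than "corrected"). Resampling is trilinear
with air fill; `V_rot(r) = V(R r)`, so a feature at `v0` appears at
`Rᵀ(v0−c)+c`, which gives the exact projected tumor-centroid ground truth.

DRRs are parallel-beam: per detector pixel
`I = I0·exp(−∫ μ dl)`, the line integral sampled at half-voxel steps with
linear interpolation across the full physical extent, which makes uniform
slabs exact (the e⁻¹ closed form holds to 1e-6) and keeps `−ln I` linear
in pathlengths to <1 % for 1 mm voxels. No noise, scatter, spectra or
detector blur are simulated. Detector resampling (e.g. 96² native → 64²)
is performed on the *line integrals*, not the intensities, so the
log-domain additivity that the subtraction algebra relies on survives
binning exactly. Cone-beam geometry is not implemented; parallel beams
admit closed-form oracles and nothing downstream needs divergence.

## Subtraction, grid and augmentation

`des_subtract` floors intensities at 1e-8 before the logarithm (the
subtraction is undefined at 0) and carries the raw log-domain array in the
image metadata; exported images are the exponentiated, per-image
max-normalized version. `bone_cancel_weight` returns
μ_HE(rib)/μ_LE(rib); at that weight the DES of a ribbed phantom equals
the DES of the same phantom with rib/spine attenuation zeroed, pixel-wise
at machine precision, because rotation and integration are linear and the
bone HE grid is exactly ω times the bone LE grid.

The training grid enumerates 10 phases × 36 equal couch pairs
(0,0)…(35,35) × 100 gantry angles 3.6°…360° = 36,000 entries,
phase-major. Augmentation samples one transform per pair — scale in
[0.8, 1.2], crop to 50–100 % of the side length at a uniform-random
position, zero-padding back in place — applied identically to both
members, with the record and derived per-pair seed stored in the manifest
so any pair regenerates bit-identically.

## Residual U-Net and training

Architecture (depth 3, base 8 filters): encoder levels of one residual
block each (3×3 conv → instance norm → leaky ReLU(0.05) → 3×3 conv →
instance norm, additive shortcut with a 1×1 projection on channel
mismatch, leaky ReLU on the sum) at 8/16/32 channels with 2×2 max-pooling,
a 64-channel bottleneck block, and a decoder that nearest-neighbour
upsamples, halves channels with a 1×1 convolution, concatenates the skip
and applies one residual block per level; a final 1×1 convolution maps to
one channel, and a global identity shortcut adds the input to the output.
118,881 parameters. Design rationale, in decreasing order of consequence:

- **Optical-depth domain.** Images enter the model as per-image min-max
  normalized optical depth `u = −ln I`. Projection, subtraction and the
  compositing of overlapping anatomy are all *additive* in u, so the
  function the network must learn — remove the bone component — is itself
  an additive image, which a residual architecture fits far faster than
  the equivalent multiplicative problem in the intensity domain.
- **Global identity shortcut.** With it, the convolutional path regresses
  only the (sparse, bone-shaped) difference between SE and DES.
- **Instance normalization + leaky rectifier.** The prescribed optimizer
  setting (Adam, initial learning rate 0.02 with linear decay to 1e-4) is
  aggressive for a small convolutional network; without per-channel
  normalization training diverges, and with plain ReLU a substantial
  fraction of seeds die irrecoverably (all-zero gradients) during the
  early high-rate phase. Instance norm makes activations scale-invariant
  and is deterministic at inference (no running statistics); the 0.05
  negative slope keeps units recoverable.
- **Batch size 2.** At a fixed budget of ≤20 epochs over ~500 pairs, the
  step count — not the data — limits convergence; batch 2 provides ~4,500
  Adam steps in ~5 CPU-minutes.

Training minimizes pixel MSE; a seeded 90/10 split holds out validation
pairs; the loss history is recorded per epoch; non-finite loss aborts with
a diagnostic. Forward/backward passes are hand-written NumPy
(`sliding_window_view` + `tensordot` convolutions; the input gradient is
correlation with the flipped, channel-transposed kernel) and verified
against central finite differences to ~1e-8 relative error.

## Desk-scale study conditions

The simulation grid is 96³ voxels at 2 mm with a 64×64 detector (3 mm
pixels) for synthesis work, chosen so that dataset generation (~500 pairs,
~1.5 min), training (≤20 epochs, ~5 min) and evaluation all fit on one
CPU; tracking sequences use a 128×128 detector (1.5 mm pixels). Training
pairs are drawn uniformly at random (seeded) from the 36,000-entry grid
*without* augmentation: the augmentation transforms emulate clinical
field-of-view variability, and in the clean DRR-only desk-scale evaluation
they dilute the small sample budget (measurably lower held-out SSIM at the
same budget). `generate_dataset`, the full-pipeline path, augments by
default.

Synthesis quality is evaluated on four held-out cases at couch pairs
(9°, 28°), (17°, 5°), (20°, 32°), (25°, 21°) — none representable in the
equal-angle training grid — with the gantry sweeping 3.6°–360° across the
frames of five breathing cycles. Synthesized and analytic DES frames are
both taken to normalized optical-depth display, quantized to 8 bits, and
compared with PSNR (max 255) and single-scale SSIM (11×11 Gaussian window,
σ = 1.5, C1 = (0.01·255)², C2 = (0.03·255)²). At this training scale the
model reaches held-out SSIM ≈ 0.87–0.93 and PSNR ≈ 27–31 dB: clearly
learned bone suppression, but short of the ≥0.99 / ≥40 dB regime a
full-scale training run (tens of thousands of pairs, hundreds of epochs)
attains — the step budget, not the architecture, is the binding
constraint, and passing tests at this scale demonstrate the pipeline and
the direction of the effect, not clinical-grade synthesis.

## Tracking and its evaluation

The tracker maximizes the energy-normalized cross-correlation
`NCC(u,v) = Σ I·T / (√ΣI² · √ΣT²)` — deliberately *without* mean
subtraction, following the printed form used by this line of work; a
zero-mean variant sits behind a flag. Matching is integer-pixel over a
window centered on the previous position. Ties keep the previous position
when it attains the maximum (so constant sequences stay put), otherwise
the first maximum in row-major order; for unique maxima this equals
exhaustive search, which the tests verify by brute force.

Tracking cases sample tumor diameter 18–35 mm, motion amplitude 5–15 mm,
couch angles in [0°, 35°] and a fixed random gantry — the clinical ranges
for this application. The template is a square patch around the projected
tumor in frame 1, sized to the tumor (+2 px margin); the search radius
(default 4 px) bounds the inter-frame displacement, about one pixel at 30
frames per cycle. Ground truth is the analytically projected tumor
centroid rounded to the detector grid (the tracker is integer-precision,
so sub-pixel ground truth would bias both arms identically). RMSE is in
mm; TSR counts frames with error strictly below 25 % of the per-case
maximum ground-truth displacement; per-arm 95 % confidence intervals and
the SE-vs-DES comparison use a paired bootstrap (frames resampled i.i.d.,
B = 1000, two-sided p = 2·min(P(Δ≤0), P(Δ≥0)) with +1 smoothing).

A structural caveat that the tracking comparison exposes: with the default
attenuation coefficients, the tumor-to-rib-clutter contrast ratio is
(0.19−0.04)/(0.30−0.18) = 1.25 on SE images but 0.045/0.055 = 0.82 on
analytic DES images, because bone cancellation removes the bone signal yet
keeps the full soft-tissue rib void while also shrinking tumor contrast
3.3-fold. On noiseless binary-material simulations, NCC tracking on
analytic DES is therefore *not* generically better than on SE — the
clinical benefit of DES synthesis rides on noise and contrast conditions
(and on the network's learned suppression) that this simulation pipeline
intentionally omits. The comparison harness reports whatever the
conditions yield rather than building the expected direction in.

## Clinical adjustment path

For real fluoroscopy, frames are adjusted toward the DRR domain before
synthesis: a 2D similarity registration (translation, rotation, isotropic
scale about the image center) is estimated once between the reference DRR
and the first frame by Powell minimization of negative zero-normalized
correlation over a 4×/2×/1× resolution pyramid (recovery accurate to
≤0.5 px / 0.2° / 0.01 scale on synthetic displacements; below a 0.2
similarity floor it warns and returns identity). Each frame is then pulled
into the DRR geometry, histogram matched to the DRR by exact quantile
mapping (monotone; constant references map to the constant), and smoothed
with a 5×5 median filter (reflecting borders). The order —
register, match, smooth — is fixed.

## Determinism and seeds

Every stochastic step is seeded: phantom geometry is purely analytic;
dataset subsampling, augmentation, weight initialization, batch shuffling
and the bootstrap all derive from explicit seeds, with the pipeline
fanning a single master seed out per stage via SHA-256-labelled
`SeedSequence`s. Identical configurations reproduce reports byte-for-byte
on the same machine.

## Known limitations

- Parallel-beam only; no noise, scatter, spectra, beam hardening or
  detector physics; monoenergetic surrogate energies.
- Rigid-translation breathing of lungs+tumor; no deformation, hysteresis
  or cardiac motion.
- The phantom's binary materials make DES rib voids stronger relative to
  tumor contrast than in real tissue (see the tracking caveat above).
- Desk-scale training does not reach full-scale synthesis quality; the
  architecture supports the full 36,000-pair protocol but at hours of CPU
  time.
- The clinical adjustment path is validated on synthetic stand-ins for
  fluoroscopy (no public paired clinical data exists for this task).
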