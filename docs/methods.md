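# Methods

`vbmflow` re-implements a neural-network preprocessing chain for voxel-based
morphometry (VBM) at desk scale: every stage of the pipeline — intensity
normalization, augmentation, cascaded patchwise tissue segmentation,
symmetric diffeomorphic registration, affine registration, and the
downstream voxel-wise GLM statistics — is present and tested, but the grids,
networks and training budgets are shrunk so the whole chain trains and runs
in minutes on one CPU core.

## Coordinate and grid conventions

Volumes are 3D float32 grids with a 4x4 voxel-to-world affine; voxel indexing
is 0-based.  Registration works in normalized coordinates spanning [-1, 1]
with the extremes at the *centers* of the first and last voxels.  The
production template grids are 0.5 mm (339x411x339, analysis crop 336x384x336,
divisible by 16), 0.75 mm (224x256x224) and 1.5 mm (113x137x113).  The crop
origin inside the 0.5 mm grid is the recorded constant (1, 13, 1) — a
centered crop.  The desk presets keep every structural ratio: 48^3 at 3 mm
(high), 32^3 at 4.5 mm (coarse stage, 2/3 of the high resolution, as in the
production pair), 24^3 at 6 mm (registration and VBM).  Out-of-field voxels
are 0 everywhere; B-spline (order 3) interpolation is used for the
high-resolution affine resample, trilinear elsewhere, nearest neighbor for
labels and flips.

## Automatic differentiation engine

All gradient-based components run on a compact reverse-mode autodiff engine
(`vbmflow.autodiff`): float32 tensors, a dynamic tape, and exactly the
operations the package needs (elementwise algebra and activations,
reductions, slicing/concatenation/flip, stride-1 "same" 3D convolution,
factor-2 average pooling and nearest upsampling, and trilinear
`grid_sample3d` with zero or border padding, differentiable in both the image
and the sampling grid).  Gradients were verified against central finite
differences during development.  Determinism: all training loops draw
randomness from seeded `numpy` generators and run single-threaded numpy
kernels, so loss trajectories are bitwise reproducible.

## Intensity normalization

Inputs are assumed skull-stripped (the brain mask is an external interface;
no brain extractor is bundled) and bias-corrected.  Intensities are min-max
scaled between the 0.5th and 99.5th percentile of the in-mask voxels
(linear-interpolation percentile definition).  Values above the upper anchor
are not clipped: the scaled value s > 1 maps to 1 + log10(s), which is
continuous and monotone at the breakpoint and keeps extreme intensities
(vessels) ordered.  Values below the lower anchor clip to 0 — the scheme
defines only the upper tail, and a symmetric lower log tail would move the
background level, so clipping is the minimal completion.

## Augmentation

Twelve kinds: bias field, motion, chi noise, blur, ghosting, spike,
downsample, translate, flip, brightness, contrast, Gibbs ringing.  The bias
field is exp(s * G) where G is the inverse FFT of Gaussian noise restricted
to a k-space box of <= 4 cycles per field of view (strictly positive,
band-limited by construction).  Chi noise adds k Gaussian channels in
quadrature with the signal (default k = 2, the Rician magnitude limit; a
zero image yields Rayleigh(sigma) statistics).  Ghosting attenuates every
4th phase-encode line; a spike adds one high-amplitude k-space point; Gibbs
ringing truncates k-space radially; motion averages the k-spaces of the
image under up to three small random translations.  Translation and flip use
nearest-neighbor resampling only.  Every kind is the identity at strength 0
and reproducible from (kind, strength, seed).  The seven-artifact test
protocol (noise, bias field, blur, ghosting, motion, ringing, spike at
medium and strong presets — numeric strengths are recorded constants in
`config.ARTIFACT_PRESETS`) yields 14 corrupted volumes per original.

## Tissue segmentation

Tissue maps are continuous labels in [0, 3] (1 CSF, 2 GM, 3 WM; 1.5 and 2.5
the adjacent-class mixtures).  Probability channels are recovered with
triangular kernels p_k(x) = max(0, 1 - |x - k|) (background max(0, 1 - x));
this is the simplest decoding that makes the decode/encode round trip exact
on voxels mixing at most two adjacent classes.

The final network layer is the multilevel activation
f(x) = S(ax) + sum_{i in {1.5, 2, 2.5, 3}} S(a(x - i))/2, S the logistic
sigmoid and the slope `a` a trainable parameter (initialized at 4.0, floored
at 0.01 during optimization).  It maps network outputs onto plateaus at 0,
1, 1.5, 2, 2.5 and 3, matching the label histogram; training uses MAE loss.

Stage 1 is a full-view UNet at the coarse resolution (depth-d encoder with
channel doubling from `base_channels`, instance norm, ReLU, average-pool
down / nearest-neighbor up; production depth 4 with 8 base channels, desk
default depth 2 with 4-6).  Stage 2 tiles the analysis crop with a 3x3x3
grid of patches (128^3 in production, 16^3 on the desk grid).  Patch
positions start on the regular grid and move one voxel at a time toward the
image center — axes swept in order (sagittal, coronal, axial) until a full
pass makes no move — as long as every tissue voxel of every training mask
stays covered; mirrored left/right patch pairs move in lockstep so their
weight sharing is exact.  Right-hemisphere patches are sagittally flipped,
passed through the corresponding left-hemisphere model, and flipped back (27
patches, 18 effective models).  Mid-column models are symmetrized at
inference (average of the prediction and the unflipped prediction of the
flipped patch), which makes the assembled map *exactly* equivariant under a
sagittal mirror — hemisphere pairs get this from weight sharing; the
mid-column needs the explicit average.  Overlapping predictions are blended
with separable Gaussian importance weights, sigma = patch edge / 8,
normalized to sum to 1 per voxel.

Training follows the cascade: stage 1 for `stage1_epochs` (batch 1); then a
two-channel foundation UNet (image + upsampled stage-1 prediction, trilinear
upsampling) across all effective patch positions; then one fine-tuned copy
per position (batch 2).  Flip augmentation is applied only to mid-column
patches.  All loops use the one-cycle learning-rate schedule; the production
peak rate is 0.001.  The single-phantom overfit exercised in the tests uses
a desk configuration (depth 2, 6 channels, 120/6/25 epochs, peak rate 0.01 —
small nets tolerate and need the larger rate at this scale).

## Diffeomorphic registration

A stationary velocity field v is exponentiated by scaling and squaring with
tau = 7: u <- v / 2^tau, then u <- u o u seven times, compositions sampling
displacements with edge-clamped trilinear interpolation (image warps use
zero fill).  The symmetric construction uses two half velocity fields:
phi = SS(v_fwd) o SS(-v_bwd) and phi_inv = SS(v_bwd) o SS(-v_fwd) — the only
reading of "composition with the negated half map" under which
phi o phi_inv = id holds exactly in the continuum.

The Jacobian determinant is computed from central differences of the
coordinate map in voxel units (one-sided at faces); identity gives exactly 1
and a uniform zoom (1+e)x gives (1+e)^3.  The linear elasticity
R = mu ||eps||^2 + (lambda/2) tr(eps)^2, eps the symmetrized displacement
gradient in normalized coordinates, is reported as the *mean* energy density
(integral normalized to unit domain volume) so the closed form
(3 mu + 4.5 lambda) e^2 for a uniform zoom holds on any grid.  Defaults
mu = lambda = 1, trade-off Lambda = 0.01 — none of the three is prescribed
by the source method, and results in the tests only use the closed forms.

The symmetric loss is D(I.phi, J) + D(I, J.phi_inv) +
D(I.phi_half, J.phi_inv_half) + Lambda R(phi) with D the voxel MSE.
Supervised training targets are distilled velocity pairs: L_v is the sum of
the two velocity-field MSEs, L_{v,J} adds the Jacobian-determinant MSE, and
the full loss adds beta * L_SyN with beta = 2e-5.

Velocity distillation (`velocity_from_deformation`) minimizes the mean
squared coordinate residual (in voxel units, both directions) by gradient
descent through the scaling-and-squaring graph.  It initializes each half
velocity at half the target displacement — the first-order series of the
log map — and uses backtracking line search with step growth (initial step
0.1, halving on failure, 1.3x growth after clean steps).  From a zero
initialization with a fixed step the residual plateaus above the desired
0.1-voxel reproduction; with the first-order initialization it reaches
~0.01 voxel in about 100 iterations at 24^3.  Velocity recovery is not
unique (different pairs can produce the same composed map), so tests assert
reproduction of the *deformations*, not the velocities.

The registration network is a UNet (LeakyReLU, instance norm, tanh head
bounding outputs to (-1, 1) in normalized coordinates) mapping the stacked
moving GM/WM and template GM/WM maps to both half fields.  Whether the two
half fields should be predicted independently or antisymmetrically is an
open choice; independent prediction is the default and an antisymmetric mode
(v_bwd = -v_fwd) is available in `RegNetConfig`.  No augmentation is applied
during registration training.

## Affine registration

Twelve parameters — translation, Euler rotation (X, Y, Z factors),
log-scale, shear — composed as R * S * H and optimized with Adam in world
coordinates (translations scaled by the template half-extent so all
parameters are comparably scaled).  The loss is the image MSE plus a
soft-Dice loss on the brain masks, in a coarse-to-fine schedule: 500
iterations at 12 mm working resolution (lr 0.01), then 100 at 6 mm
(lr 0.003), zero padding throughout.  Two numerical choices matter on
smooth, nearly symmetric heads:

* both working images are pre-smoothed (0.8 voxels), and the template gets
  extra blur of variance 1/6 voxel^2 — the mean variance trilinear
  resampling adds to the warped moving image.  Without this, exact-grid
  sampling of the moving image is artificially sharp and the identity
  becomes a spurious local minimum;
* the Dice term compares masks re-binarized through a steep sigmoid at the
  0.5 level (sharpness 40), scoring boundary geometry rather than
  interpolation blur.

The best-seen iterate (never worse than the initialization) is returned as
a 4x4 world matrix mapping the moving image into template space.

## Metrics

DSC = 2|A n B| / (|A| + |B|), JSC = |A n B| / |A u B|; two empty masks score
1 by convention.  The probabilistic Dice uses the min-overlap form
2 sum min(p, q) / (sum p + sum q) — selected because it reduces exactly to
DSC on binary inputs (the squared soft-Dice does not).  Per-class scores
binarize by argmax over the decoded channels (background included, ties to
the lower class); the foreground score is the unweighted mean of CSF, GM and
WM, reported on a 0-100 scale.  Registration quality is the voxel MSE to
the template plus the linear elasticity of the deformation; score lists are
summarized by median, 95th percentile, max and min (the distributions are
skewed, so the median is the reported central tendency).

## VBM statistics

GM masking zeroes the GM probability inside a resource mask (generated from
the phantom's ventricle/brainstem geometry at desk scale; user-supplied for
real data).  Modulation multiplies the warped map by the Jacobian
determinant (on by default; negative determinants are flagged).  Smoothing
is a separable Gaussian with sigma = FWHM / (2 sqrt(2 ln 2)) per axis,
zero-padded, default FWHM 6 mm.  The GLM is an ordinary least-squares fit
per voxel with an intercept, the covariate of interest and optional nuisance
columns; t = coefficient / standard error, df = n - rank.  The analysis
mask keeps voxels whose mean smoothed map exceeds 0.1 (configurable).
Stability analyses repeat the GLM on `reps` = 100 random 80% subsets
(without replacement, per-repetition seeds spawned from a root seed) and
take the per-voxel median t; map similarity is the Pearson correlation over
the mask intersection.

## Phantom generator

Phantoms are nested ellipsoids — WM core, cortical GM shell (WM radius +
thickness), CSF envelope — plus paired ventricles (CSF), a brainstem stub,
and a posterior cortical protrusion that breaks the rotational
near-symmetry of a plain ellipsoid (a real head is not an ellipsoid; without
it, affine rotation recovery is ill-posed at coarse resolutions).  Labels
are built from soft ellipsoid indicators with a linear one-voxel
partial-volume ramp, so the continuous-label semantics are exact by
construction; intensities mix class means (0.22 / 0.55 / 0.85 for CSF / GM /
WM on a [0, 1] scale) through the decoded partial volumes plus smooth
within-class texture (3% amplitude).  Atrophy thins the GM shell in 0.1 mm
steps at a fixed head envelope and WM core.  Ground-truth deformations are
scaling-and-squaring flows of Gaussian-smoothed random velocity fields
(antisymmetric pair, regenerated on folding).  Cohorts add a
covariate-scaled effect inside a spherical GM region plus smooth noise
(2% standard deviation).

What the phantoms do *not* emulate: MR acquisition physics (the augmentation
module simulates artifacts), cortical folding, real anatomical variability,
and site effects.  Passing tests therefore demonstrate that the machinery is
correct and the training loops can fit data at desk scale — not that the
desk-trained networks generalize to real MRI.

## Problem sizes and budgets

Test and demonstration sizes were chosen to keep a full run in the
minutes range on one CPU: 48^3 phantoms, 16^3 patches, 24^3 registration
grids, 32^3 diffeomorphism checks, single-phantom overfits, and cohorts of
50-60 subjects with 100 resampled GLMs.  Production-scale grid constants are
exposed in `vbmflow.config` but are not exercised by the test suite.

## Known limitations

* No pretrained production weights are distributed; all networks train from
  scratch at desk scale.
* Brain extraction and bias-field correction are interfaces, not
  implementations.
* The affine registration assumes both inputs on centered canonical grids
  (the phantom/template convention).
* Velocity distillation recovers deformations, not unique velocities.
* The engine is single-threaded numpy; it favors reproducibility and
  clarity over speed and does not scale to the production grids.
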