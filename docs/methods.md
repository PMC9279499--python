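# Methods

This note records the models, conventions and design choices behind
`depchain`, in the order the pipeline runs.

## Synthetic micrographs and the voltage–chain-length model

Scenes emulate micrographs of a single suspension observed at drive voltages
1–10 V (200 kHz): filled disks of intensity `particle_level` (default 200) on
a uniform background (default 10), plus additive Gaussian noise (default
sd 8 on the 0–255 scale, configurable; real textile-electrode backgrounds
are more structured — see *Limitations*).  Default frame 512×512 px with
particle radius 10 px; neither a pixel pitch nor a particle size in pixels is
dictated by the application, so these are conventional choices.

Chain lengths are drawn from a voltage-conditioned categorical distribution
defined by anchor distributions at 1, 3, 5, 7 and 10 V and linear
interpolation of the probabilities in between (a convex combination of
normalized distributions, so the interpolant is normalized and its mean is
monotone between anchor means).  The anchors encode the experimentally
reported behaviour:

* 3 V: P(L=2) = 0.84, P(L=3) = 0.15, remainder at L=4;
* 5 V: 40% of chains have more than 4 particles;
* 7 V and above: the majority of chains have 8+ particles, the 8–10 band
  retains a significant share, and 2–5 particle chains are rare;
* from 7 to 10 V the mean length keeps growing roughly one particle per
  volt (reaching ~11.7 at 10 V), consistent with the 10–12 bead chains
  reported for comparable bead systems at higher drive amplitudes.

Chaining is voltage-gated: pearl chains appear only from about 2 V, so each
scene splits a fixed particle budget (default 150 particles) into a chained
fraction (0.10 at 1 V rising to 0.98 at 10 V, linearly interpolated) and
dispersed singletons.  A 1 V scene is therefore mostly isolated particles,
while a 10 V scene is a few long chains — with the same particle density,
as for one suspension.

Chains are straight lines of touching disks (center spacing exactly 2r;
curvature is not modelled), with uniformly random orientation.  Member
centers are rounded to integer pixels.  Placement is rejection sampling: a
chain is accepted only if every member center keeps more than
2r + c + 4 px (c = r/4) to every center of every other group; the extra
4 px guarantee that ±1 px detection error can never bridge two distinct
groups.  Chains that cannot be placed in 300 attempts are dropped (this
happens mainly in crowded 1–3 V scenes and simply lowers the realized count).
Ground truth records the exact centers, the chain partition, and the binned
counts; the conservation identity Σ L·C_L + singletons + overflow particles
= total particles holds by construction and is asserted throughout the tests.

Augmentation follows the training-data convention for the imaging models:
an independent random left–right flip plus integer translations uniform in
[−30, +30] px per axis, padding with the background level.

## Particle detection

The score map is the plain normalized cross-correlation

R(x,y) = Σ T·I / sqrt(Σ T² · Σ I²),

computed at every valid top-left offset via FFT correlation; for
multi-channel images the numerator and each denominator sum run over all
channels.  Windows of zero energy score 0 (they cannot contain a particle,
and 0 never crosses a positive threshold); a floor of 1e-9 × total image
energy guards the zero-window classification against FFT round-off.  The
map is clipped to [0, 1], the Cauchy–Schwarz range for non-negative inputs.

Detections are 3×3 local maxima with score ≥ threshold, accepted greedily in
descending score order while suppressing any candidate within Euclidean
distance r of an accepted one — half the touching-particle spacing 2r, so
adjacent chain members are never merged.  Centers are the template's central
pixel (offset + ((b−1)/2, (l−1)/2), rounded half up), which is exact for
odd-sized templates; no subpixel refinement is attempted, since the chain
rule's tolerance c absorbs rounding error.

The default threshold is 0.9.  This metric (unlike its zero-mean variant)
does not discount a uniform bright background: a constant window scores the
cosine between the disk template and an all-ones window, ≈ 0.86 for the
default rendering, and noisy-background local maxima stay below ≈ 0.87,
while true particle peaks score ≥ 0.94 even at the default noise level.
0.9 sits between those bands; it remains a CLI flag because real templates
and illumination differ.

## Chain assembly and features

Particles are linked when their center distance is at most 2r + c; chains
are the connected components of this graph (union-find, deterministic
ordering by smallest member index).  Only a distance condition is available,
so branched clusters count by total size — no collinearity test is applied.
The feature vector holds C_L for L = 2..18 plus a singleton count and an
overflow bucket (groups longer than 18, also tracked in particles for the
conservation identity).  Learning uses 18 predictors C1..C18, where C1 is
the singleton count: the ranking analysis that motivates this pipeline
treats C1 as a (weak but defined) predictor, and at low voltages it is the
dominant population.  The tolerance c is an explicit parameter (default
r/4); no auto-correction loop is run, since no stopping rule can be stated
for one.

## Segmentation pipeline

Order: grayscale (luma weights 0.299/0.587/0.114) → per-image global
histogram threshold → binarize (foreground = I ≥ α) → dilate by S1 →
erode-then-dilate by S2 → fill holes + clear border → dilate-then-erode by
S2 → replicate to three channels.  S1 defaults to a 3×3 cross (union of
horizontal and vertical 3 px lines), S2 to a horizontal 1×3 line; no SE
dimensions are dictated by the application, and both are overridable.

The threshold maximizes between-class variance (Otsu's criterion) over the
256 candidate splits, smallest maximizer on ties; constant images are
rejected.  "Adaptive" here means per-image, not locally varying.  Dilation
and erosion implement the set definitions directly (union/intersection of
shifts by the structuring-element offsets), with out-of-image pixels as
background.  The erode-then-dilate stage is written exactly as stated — an
opening in standard terminology, although the surrounding prose calls it a
closing; the discrepancy is deliberate and documented here.  The
dilate-then-erode stage (a true closing) runs on a frame padded by the SE
extent and is cropped back, so extensivity holds on the full raster.  Hole
filling and border clearing use 4-connectivity.

## DEP physics

Permittivities entering the Clausius–Mossotti factor and the dipole force
are absolute (ε_rel · ε₀, ε₀ = 8.8541878128e-12 F/m); conductivities in
S/m, angular frequencies in rad/s.  The surface force form
F = ε_E ε₀ E E_n − ½ ε_E ε₀ E² n uses the relative medium permittivity with
an explicit ε₀ and is evaluated pointwise along the surface normal — no
surface integration, since reconstructing fields from micrographs of
textile electrodes is not well-posed.  ∇E²_rms is a user-supplied scalar;
no field solving is attempted.  The crossover frequency uses the closed
form ω_c² = −(σ_p−σ_m)(σ_p+2σ_m)/((ε_p−ε_m)(ε_p+2ε_m)) and returns None
when the DC and high-frequency limits share a sign.

## RReliefF

Standard regression Relief: for each instance and its k nearest neighbors
(Euclidean distance in min–max-normalized feature space, ties broken by
index), accumulate N_dC, N_dA[f] and N_dC&dA[f] with uniform neighbor
influence 1/k and diff() = absolute difference over the observed range;
W[f] = N_dC&dA/N_dC − (N_dA − N_dC&dA)/(m − N_dC).  Both terms are
probabilities, so |W| ≤ 1; constant features get exactly 0.  Defaults:
k = 10, all instances used (m = n), which makes the estimate deterministic
and sample-order invariant; subsampling is available and seeded.  A
zero-variance target is rejected (N_dC would vanish).

## Regression harness

Median imputation fills missing feature cells per column (even counts:
mean of the two middle values).  The split is uniform without replacement,
default 80/20, seeded.  Metrics follow the standard definitions (MAE, MRE,
MSE, R², RMSE) with accuracy the strict half-volt band |y−ŷ| < 0.5; MRE is
omitted (None) when any actual value is zero.  Voltages act as sorted ranks
with absolute cost C[y,u] = |y−u|.

The network is one hidden ReLU layer (default 32 units) with a linear
output, trained on mean-squared loss by mini-batch gradient descent
(default batch 10, learning rate 1e-4, 100 epochs — the hyperparameters of
the imaging study this harness mirrors).  Hidden weights use He
initialization; the output bias starts at the training-target mean, so the
untrained network is the null model and training only has to learn
deviations — important at learning rate 1e-4, where a bias would otherwise
have to travel several volts in 4000 steps.  Optimizer update rules are
exactly the published forms, with two corrections: ADAM's second moment
accumulates V (the printed rule reuses S, an evident typo), and its
bias-correction divisors are the standard (1 − βᵗ) rather than the printed
(1 − β)ᵗ, which would shrink to zero and blow up the step as t grows.  The
stabilizer ε sits inside the square root as printed.  Divergence
(non-finite loss) raises with the offending epoch.  Baselines: in-package
k-nearest-neighbor regression (mean of k targets, default k = 5) and
ordinary least squares.

## Problem sizes and determinism

The shipped tests and the acceptance script use 10 voltages × 50 images for
the end-to-end recovery check, 100 (test) / 50 (script) scenes for exact
chain recovery, 50 random image/template pairs for the matching oracle, 200
random 32×32 binaries for the morphology oracles, and 10,000 draws for the
generator calibration and Clausius–Mossotti bound — sizes at which every
check is stable and the whole suite runs in a couple of minutes on one CPU.
All randomness flows through explicit integer seeds; identical seeds give
bit-identical images, splits, initializations and batch orders.

## Limitations

* The generator renders uniform disks on a flat background; it does not
  model textile-electrode texture, illumination gradients, defocus,
  particle size dispersion, curved or branched chains, or overlapping
  particles.  Passing tests therefore demonstrate correctness of the
  measurement pipeline on well-separated, in-focus scenes, not robustness
  to real optical artifacts.
* Template matching is single-scale and rotation-dependent (immaterial for
  circular particles) and does not handle occlusion.
* The voltage–length anchors between the calibrated points are linear
  interpolations; the true voltage dependence need not be piecewise linear.
* The surface force expression is evaluated pointwise only, and chain-chain
  multipole interactions are out of scope.
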