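# Methods

This note records the models, the numerical choices and the limits of the
synthetic study the package implements. It is the design rationale; all
empirical numbers quoted here are produced by the test suite or
`scripts/acceptance.py`, not asserted independently.

## Phantoms and count model

Activity phantoms are axis-aligned ellipsoids and spheres rasterised on a
64×64×24 grid of 4 mm isotropic voxels, with values in SUV: body 1.0,
liver 2.2, two lungs 0.5, and 3–5 spherical lesions of radius 2–4 voxels
and SUV 5–10 placed by seeded rejection sampling (inside the body, clear
of each other and of the organ VOIs used for quantification). The
innermost structure wins where structures nest. These values are typical
of whole-body FDG imaging: liver SUV\_mean near 2, lung amplitudes well
below soft tissue, and clearly avid lesions.

Projection data follow the standard emission model: expected counts are
`scale × duration_fraction × A·x`, with `A` the projector below and
`scale` the count calibration. The clinical noise-equivalent count level
has no published desk-scale analogue, so `scale` is a free calibration
knob; the default (3.0 counts per unit SUV·voxel line integral, about
7 × 10⁶ counts per phantom at full duration) was chosen once so that the
full-duration 2-iteration OSEM reconstruction shows a liver coefficient
of variation of roughly 13 % — a realistic noisy-but-diagnostic operating
point — and was not revisited afterwards.

Reduced scan durations are emulated by binomial thinning of the full
sinogram (each count kept with probability *f*). With no event
timestamps in the simulator this is the statistically exact surrogate for
truncating the acquisition: a thinned Poisson(λ) count is Poisson(*f* λ),
so means scale linearly and the distributional family is preserved (both
are verified by Monte-Carlo chi-square tests).

## Projector and reconstruction

The projector is pixel-driven parallel-beam: for each of 48 angles over
180°, every in-plane voxel deposits its value into the two radial bins
adjacent to its projected coordinate with linear weights (96 bins cover
the 64-voxel grid diagonal). The operator is materialised once per grid
as a sparse matrix, so back projection is its exact transpose —
adjointness is what makes the EM algorithms correct, and it is tested
against an explicitly constructed matrix. Detector/system resolution is
modelled as an image-space Gaussian of 6 mm FWHM applied before
projection; a symmetric kernel with zero boundary is self-adjoint, so the
back projector applies the same blur after spreading. Sinogram-space
resolution modelling, attenuation, scatter, randoms and time-of-flight
are all outside the model: the enhancement method operates on
reconstructed images and needs the contrast/noise phenomenology, not
scanner physics.

OSEM uses the classic multiplicative update with interleaved angle
subsets and an ε-guard of 1e-8 in every ratio. The input series uses
2 iterations × 24 subsets — a partially converged, noisy regime (more
subset updates mean more convergence *and* more noise). A "standard
z-filter" is applied once after the final iteration: a (1, 4, 1)/6 axial
kernel with renormalised edge slices; the exact clinical kernel is not
public, so this conventional light smoothing is the documented choice.

BSREM-style reconstruction interleaves the OSEM data step with a relaxed
gradient step on β·R(x), R the relative difference prior over the
6-neighbourhood with edge-preservation parameter γ = 2 and ε = 1e-8 in
the denominator, relaxation αₙ = 1/(1 + 0.05 n), and clipping at zero.
The published descriptions of commercial BSREM do not pin down the exact
update; this formulation was adopted because it (a) reduces *exactly* to
OSEM at β = 0, and (b) reproduces the trade-off the method depends on:
over a β grid, liver noise decreases strictly while lesion SUV\_max is
non-increasing. Subset algorithms are not monotone in the penalised
objective, so the divergence detector only counts epochs whose objective
rises by more than 0.1 %; five consecutive such epochs abort the run.
The target series uses 20 iterations × 8 subsets (near convergence).

β itself is never copied from clinical values — the toy projector's β
scale is not comparable to a scanner's — but calibrated per corpus the
way sites calibrate it: the first training case is reconstructed over the
grid {8, 16, 32, 64} and the β whose liver-VOI noise SD lands closest to
the configured target (0.16 SUV, i.e. roughly half the OSEM input noise)
is used for every case of the corpus.

## Enhancement network

A residual 3D encoder–decoder: per level two (3×3×3 convolution → batch
normalisation → ReLU) blocks; 2×2×2 max-pooling between encoder levels;
tri-linear ×2 up-sampling and channel concatenation with the matching
skip on the decoder side; a final 3×3×3 convolution to one channel; and a
global residual connection, so the network predicts a signed residue
added to the input. The final convolution is zero-initialised by
default, making the untrained network the identity — a stable start for
residual learning and a free invariant for testing.

The smooth/standard/sharp family is realised purely through a channel
multiplier (0.5 / 1.0 / 1.5 on a base width of 6), so the variants differ
only in trainable-parameter count; a wider bottleneck preserves more
detail and more noise. Three levels and base width 6 are the desk-scale
default: wide enough to learn the noise-to-target mapping on these
phantoms, small enough that a full training run takes minutes on one CPU.

The implementation is numpy with hand-written backward passes for every
layer, all verified against central finite differences in the test suite.
The convolutions are fused direct kernels (JIT-compiled with numba,
channels-first, innermost loop contiguous along x with local
accumulators) because at these channel widths the operation is
cache-bandwidth-bound and BLAS-via-im2col reshuffles far more memory than
it computes. Training uses float32; gradient checks run the same kernels
in float64. Batch-normalisation inference uses standard running
statistics (momentum 0.1).

## Training

Pairs are (OSEM at fraction f, full-duration BSREM of the same case) for
f ∈ {1, ¾, ½, ¼} — one generic model sees all noise levels. Volumes are
cropped transversely to the body bounding box (never more than 40 % of an
axis removed; mask = 5 % of max, largest connected component), padded to
the patch grid, and divided axially into equally spaced patches covering
every slice, minimal in count, identical placements for input and target
(the default patch, 60×48×24, covers the cropped torso in one piece).
Optimisation is shuffled mini-batch MSE with Adam (lr 3e-3, batch 4 —
unpublished in the source protocol; the rate was set so the standard
model reaches its validation plateau within the CPU-scale epoch budget,
and training is stable there).
Enhanced output is clipped at zero only before SUV quantification, never
inside the loss.

After each epoch the validation loss and the validation SUV metrics
(mean |lesion SUV\_max % difference| and liver-noise % difference against
the target) are recorded, with per-epoch checkpoints. The stopping rule
has two criteria that can disagree, so epochs are ranked by validation
MSE and by the lesion-SUV metric and the epoch with the smallest rank sum
wins, earlier epoch on ties — deterministic and symmetric in the two
criteria. Patch reassembly at inference is overlap-averaging with
uniform weights (simplest artefact-free blend).

Desk-scale training lengths — 10 epochs for the standard model and
roughly wall-clock-matched short trainings for the comparison variants
(18 epochs for smooth, 4 for sharp), on 20 training + 4 validation
cases × 4 durations — were fixed as the package's default study size;
the standard model's validation metrics plateau around epoch 8–10.

## Quantification and statistics

Organ statistics use five 7×7×7-voxel VOIs in the liver and five in the
lungs, placed deterministically inside the noise-free organ masks (cube
fully inside the mask; deepest-first greedy packing with seeded-restart
fallback), defined once and transferred verbatim to every series of every
case. Per VOI: mean and population SD over the 343 voxels. Liver noise
is the mean of the five VOI SDs. "Background variability" is not a
standardised term; it is implemented as the coefficient of variation of
the five VOI means (sample SD / mean), flagged here as an interpretation.

Lesions are segmented per series (the threshold adapts to each series'
own range): T = min + 0.42·(max − min) over the 7×7×7 bounding box,
mask = voxels ≥ T. The boundary is inclusive so the arg-max voxel is
always in the mask and lesion SUV\_max equals the box maximum; a constant
box degenerates to the full cube with a warning.

Percent differences against full-duration BSREM are reported both as
signed means and as mean absolute values (published summaries are
ambiguous about which is shown, so both are always produced). The
scatter fit is OLS with free intercept (through-origin available behind a
flag). Bland–Altman uses mean ± 1.96 × sample SD (ddof 1) of the
differences. The Wilcoxon signed-rank test drops zero differences,
mid-ranks ties, and is exact by full 2ⁿ sign-pattern enumeration up to
n = 12 (2¹² enumerations are instant); beyond that, a normal
approximation with tie-corrected variance and 0.5 continuity correction
(good to about a percentage point at n = 12). Quadratic weighted kappa
follows the textbook O/E/w tables; it is undefined (raised as a distinct
error) when both raters use one identical category. Reader tables
validate Likert scores in 0–5 and competition ranking (tied series share
a rank, the next number is skipped) before pooling.

## What the synthetic study does and does not show

The generator reproduces the *statistical structure* the method depends
on: Poisson counts scaling with duration, partial-convergence bias plus
noise in the input series, and a converged, regularised, low-noise
target. It does not reproduce patient anatomy or texture, attenuation or
scatter, scanner-specific PSFs, TOF, or inter-site protocol variation —
in particular, here the dominant lesion SUV\_max error of the noisy OSEM
input is upward (noise maxima), whereas in clinical data under-convergence
can dominate and bias lesions downward. Passing tests therefore show
that the pipeline learns to map noisy partially converged images onto
their regularised targets and that every quantitative instrument behaves
as specified — not that the trained weights transfer to real scanners.
The human reader study is out of scope; only its statistics (kappa,
score/rank aggregation) are implemented and exercised on synthetic
tables.

## Known limitations

- Single-slice (2D) projector stacked axially; axial blur enters only
  through the z-filter and the network.
- The β scale is projector-specific; only the calibrated operating point
  (target liver noise) is meaningful.
- Parameter-recovery margins shrink at ¼ duration, as expected — the
  enhancement acts like a β that grows with noise, trading lesion
  contrast for stability.
- The capacity-driven smoothness ordering of the variant family does not
  separate at desk scale: with anatomically identical phantoms even the
  half-width model can learn the target mapping to near its noise floor,
  so trained to plateau the variants converge toward the target series'
  own noise level, and at matched short training the *wider* model is
  the smoother one simply because it converges faster. The parameter
  counts order strictly (smooth < standard < sharp), but the liver-noise
  ordering among trained variants is a clinical-scale phenomenon this
  synthetic corpus does not reproduce.
- The numpy/numba network is single-device by design; no augmentation,
  learning-rate schedules or mixed precision.
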