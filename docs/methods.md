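# Methods

This note documents the models, conventions and numerical choices behind
`segensemble`, and what the synthetic studies do and do not show about
real data.

## Geometry and metric conventions

All masks of one image share a grid; spacing (mm per voxel, per axis) is
the only geometric information used in computation. The affine carried
in NIfTI headers is preserved for provenance but never consulted —
volumes are treated as co-registered, and a shape or spacing mismatch
(beyond 1e-6 relative) is an error rather than something to resample
away.

**DSC** = 2|A∩B|/(|A|+|B|). **RVD** = | |pred| − |ref| | / |ref| is
reported as an absolute (non-negative) quantity so it can be aggregated
as a loss; a signed variant (`rvd_signed`) is exposed for users who care
about over- vs under-segmentation.

**Surface distances** are computed between boundaries, where a boundary
voxel is a foreground voxel with at least one background 6-neighbour and
the grid border counts as background. Directed nearest distances are
taken in both directions via the exact Euclidean distance transform with
anisotropic sampling; ASSD is the mean and MSSD the maximum of the
pooled multiset. For speed the transform runs on the joint bounding box
of the two boundaries plus a one-voxel pad — exact, because every
nearest boundary voxel lies inside that box. An exhaustive
all-boundary-pairs oracle in the test suite pins this to 1e-9 mm.

**Degenerate masks.** Two empty masks agree perfectly (DSC 1, RVD 0,
distances 0, flagged). Exactly one empty side gives DSC 0; RVD 1 for an
empty prediction and NaN (undefined, flagged) for an empty reference;
surface distances are capped at the image physical diagonal with
`surface_defined = False`. The cap keeps catastrophic empty outputs
finite and rankable as outliers instead of crashing the analysis.

**Thresholding** is `≥` everywhere: a voxel exactly at the threshold is
foreground. A fixed convention documented once beats a configurable one.

## Fusion schemes

*Averaging*: the voxel-wise (optionally weighted) mean of J masks is a
probability map, binarised at `p_thr`. The default `p_thr = 0.35` is the
value that maximises mean Dice in the organ-ensemble setting this
package models; its exact choice matters little above 0.25 (the package
verifies this plateau on its own synthetic study). *Majority voting* is
strict (> half); for odd J it equals averaging + threshold at 0.5 + ε
for any ε ∈ (0, 1/(2J)], verified exhaustively.

*STAPLE* estimates a hidden true segmentation and per-rater
(sensitivity, specificity) by EM, assuming raters are conditionally
independent given the truth — an assumption ensemble members trained on
shared data violate, which is precisely why it is worth testing rather
than assuming. Implementation choices: scalar spatially-uniform prior γ
defaulting to the mean foreground fraction of the inputs; init
p = q = 0.9; log-space products with probabilities clamped to
[1e-7, 1−1e-7]; convergence when the normalised change in Σ W drops
below 1e-6 (max 100 iterations). The observed-data log-likelihood is
recorded per iteration; tests assert it never decreases (the EM
guarantee), and an independent reference implementation reproduces the
weight field to ~1e-7.

*Regression combiner*: per model, ordinary least squares of its
ground-truth Dice on its J−1 pairwise Dices across training images
(needs n_train ≥ J); an optional ridge penalty (default 0) is available
for near-collinear ensembles, and an exactly rank-deficient design is an
error naming the model. At apply time the highest predicted score wins,
ties to the lowest model index.

## Robustness analysis

Outlier boundaries are linear-interpolation quantiles of the *pooled*
per-(image, model) single-model values, per organ and metric: DSC below
its 5th percentile, RVD/ASSD/MSSD above their 95th. Pooling over models
(rather than per-model distributions) matches drawing a single boundary
per organ/metric panel; a `per_model` mode is exposed for the other
reading. Outliers are *strictly* beyond the cutoff, so a degenerate
all-equal sample yields none. Fused results are flagged against the
single-model boundaries — the question is whether the ensemble stays on
the safe side of the scale its members defined.

A *high-risk image* has at least one model with any outlier metric; the
*rescue rate* is the fraction of high-risk images where the fused mask
is not an outlier, reported per metric and undefined (None, not 0 or 1)
when no image is high-risk.

*Ensemble gain* g = L_ens − L_ref uses the Dice loss 1−DSC, RVD, ASSD
and MSSD, with the mean or the worst single model as reference; negative
g is improvement. Gain-vs-loss trends are fitted with the York
estimator: iteratively reweighted least squares with weights
W_i = 1/(s_y² + b² s_x²) (zero error correlation), initialised at the
OLS slope, iterated to |Δb| < 1e-10 (max 200), with parameter standard
deviations from the standard York variance expressions. With s_x ≡ 0 and
constant s_y it reduces exactly to OLS; tests check it against
brute-force grid minimisation of the objective and verify ±2 sd coverage
≥ 90 % over seeded simulations.

*Ensemble-size subsampling* draws distinct model subsets uniformly
without replacement (the same subsets applied to every image, as when
subsampling trained models), fuses each with averaging + threshold by
default, and reports per-size means and sds over the repeats — fully
reproducible from a seed.

## The synthetic generator

The generator emulates the statistical structure of trained-ensemble
predictions on a desk-scale grid (default 64³ at 1 mm³; larger grids are
supported, and grid-dependent defaults scale linearly). Phantoms are
ellipsoids (default semi-axes 16 × 14 × 12 voxels, varied ±25 % per image
with ±4-voxel centre jitter) or smoothed-noise blobs.

Each simulated model output is built from the truth by:

1. **Shared bias** (per image, common to all J models): a random affine
   deviation ≤ 2° rotation, ≤ 2 % shear, ≤ 1 voxel translation, volume
   preserving. Members trained on the same data make correlated
   mistakes; this component is irreducible by averaging and is what
   makes ensemble gains saturate with J rather than vanish.
2. **Per-model affine jitter** ≤ 1.5° rotation, ≤ 1.5 % scale and shear,
   ≤ 0.75 voxel translation. These amplitudes are calibrated to the
   *output* disagreement of trained models (ASSD between members of
   ~1 voxel), not to training-time augmentation ranges, which describe
   input variation an order of magnitude larger. On a phantom of
   ~15 voxel radius the surface-to-volume ratio is several times that of
   a real organ crop, so realistic *relative* behaviour (Dice ≈ 0.9,
   broad threshold plateau) requires sub-voxel absolute amplitudes.
3. **Surface roughening**: each voxel of the one-voxel outer (inner)
   shell is added (removed) independently with a per-model rate drawn
   from U(0, 0.15) — non-affine, spatially rough disagreement at
   sub-voxel expected amplitude. Whole-shell dilate/erode iterations are
   available (`boundary_noise_max_iter`) but default to 0: one full
   shell displaces the entire surface by a voxel, far coarser than real
   inter-model variation at this scale.
4. **Catastrophic failures**, independently per model and image: with
   probability `p_spurious = 0.05` a disconnected false-positive
   component (60–400 voxels) at ≥ 20 mm surface distance from the truth;
   with probability `p_dropout = 0.02` removal of a connected chunk
   (25–75 % of the volume). These reproduce the two observed failure
   modes of single networks — distant spurious regions and gross
   dropouts — and are what the robustness analysis exists to measure.

The iid rater model (keep each true-foreground voxel with probability =
sensitivity, flip each background voxel with probability =
1 − specificity) matches STAPLE's generative assumptions exactly and
anchors the parameter-recovery tests.

Randomness is hierarchical: every mask derives from
`SeedSequence([master, image, model])`, so any artifact can be
regenerated in isolation and failure events are independent across
models (tested by a binomial goodness-of-fit across seeds).

**What the synthetic studies do not show.** Real CT ensembles have
anatomy-dependent difficulty (a few hard images concentrate most
failures), spatially structured inter-model correlation beyond a global
affine, and organ-specific shape priors. The generator's difficulty is
homogeneous across images, so the *fraction* of high-risk images is much
higher than in clinical test sets (failures spread thinly over many
images rather than piling onto a few), even though the per-comparison
behaviour — rescue rates, gain ordering, size saturation, threshold
plateau — mirrors the real phenomenology. Passing tests demonstrate the
correctness of the machinery and the qualitative ensemble effects, not
clinical performance numbers.

## Problem sizes and defaults

The default study is 40 images × 16 models at 64³ — large enough for
stable 5 %/95 % quantiles (640 pooled records) and ensemble-size curves,
small enough that the full pipeline runs in tens of seconds per study.
STAPLE recovery uses 8 raters on a 48³ phantom (~110 k voxels), where
binomial fluctuations of the estimates are well below the ±0.02
assertion band. Subsampling uses 10 repeats per size, matching the
convention of averaging over 10 random model subsets.

Key defaults in one place: `p_thr = 0.35` (averaging), `0.5` (STAPLE,
insensitive within 0.05–0.95 on converged fields), outlier percentile
0.05, STAPLE tol 1e-6 / max 100 iterations, York tol 1e-10 / max 200,
regression ridge 0. All are exposed as parameters.
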