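# Methods

## Pipeline overview

`wdcpipe` analyses a placebo-controlled crossover pharmaco-imaging design in
five stages, each usable on its own:

1. **Motion QC** (`motion_qc`): per-volume framewise displacement (FD, mm) is
   censored when FD > 3 mm or FD > mean + 2 sd of the session's own trace
   (sample sd, ddof = 1; both inequalities strict, so a volume exactly at the
   limit is kept). A session passes QC when its censored fraction is <= 0.20
   (boundary inclusive). The mFD covariate is the mean of the *full*
   uncensored trace — it characterises the session's motion, it is not a
   post-censoring quantity. By default censored volumes are also dropped from
   the time series before connectivity estimation; `drop_censored=False`
   restricts censoring to QC exclusion only, since published descriptions of
   such pipelines are often ambiguous on this point.
2. **Connectivity** (`connectivity`): voxel time series inside the common
   gray-matter mask are z-scored (mean 0, sample sd 1); weighted degree
   centrality of voxel `a` is the sum of cosine similarities to all *other*
   in-mask voxels that exceed the threshold (default 0.25, strict, one-sided
   — sub-threshold and negative similarities contribute zero rather than
   being clipped). On z-scored series cosine similarity equals Pearson's r,
   which the tests verify to 1e-10. Self-connections are excluded; including
   them would only add a constant that map z-scoring removes. The similarity
   matrix is processed in column blocks (default 1024) so memory stays
   O(N x chunk); results are chunk-size invariant to ~1e-12. The wDC image is
   then z-scored across in-mask voxels (sample sd again).
3. **Masks** (`masks`, `image_io`): the common gray-matter mask is the
   voxelwise intersection of all participant gray-matter probability maps at
   probability > 0.85. (A printed threshold of "0.85%" is read as the
   probability 0.85: a literal 0.85% would include essentially the whole
   head.) The two network submasks are resampled to the BOLD grid by nearest
   neighbour in world coordinates (linear interpolation with a 0.5 cut is
   available), binarized, and intersected with the common mask; an empty
   result is an error. Standardized wDC is averaged within each submask,
   giving one outcome per participant x condition x network. All voxel
   bookkeeping uses one fixed linear order (x fastest, then y, then z —
   Fortran ravel order, matching NIfTI's on-disk layout); grids are
   "compatible" when shapes match and affines agree within 1e-4 mm, enough
   to absorb I/O float noise without hiding real mismatches.
4. **Inference** (`stats_models`): per network, a random-intercept linear
   mixed model `y ~ group * drug + mfd + (1 | participant)` (reference
   levels nonautistic, placebo; mFD uncentered) and within-group models
   `y ~ drug + mfd + (1 | participant)`. REML is the default for estimation;
   AIC/BIC always come from ML refits because REML likelihoods are not
   comparable across fixed-effect structures (AIC = -2l + 2k,
   BIC = -2l + k log n, k = fixed effects + 2 variance components).
5. **Multiplicity**: permutation p-values per model are corrected within
   that model's family of tested (non-intercept) fixed effects by a
   two-stage procedure built on the Benjamini-Yekutieli step-up (valid under
   arbitrary dependence): stage 1 runs BY at alpha/(1+alpha) and estimates
   the number of true nulls m0 = m - r1; stage 2 reruns BY at
   alpha/(1+alpha) * m/m0. Which exact "two-stage BY" variant a given R
   workflow uses is not standardised; this definition is pinned by an
   independently coded step-by-step reference in the test suite. Reported
   adjusted p-values are scaled so that `p_fdr <= alpha` reproduces the
   two-stage decision.

## Mixed-model fitting

With a single random intercept the marginal covariance is block diagonal,
`Var(y) = sigma_e^2 (I + lambda Z Z')` with `lambda = sigma_b^2 / sigma_e^2`,
so for fixed `lambda` the GLS fixed effects, the profiled residual variance
and the (restricted) likelihood all have closed forms from per-participant
sums. The fitter maximises the profiled criterion by golden-section search
on `log(lambda)` over [-25, 20] with 64 iterations (interval ~3e-13, far
below statistical precision), is deterministic, and is vectorised over many
outcome columns at once — one call fits thousands of permuted outcomes in
milliseconds, which is what makes 5000-permutation tests and Monte-Carlo
calibration studies routine. Against statsmodels' MixedLM (an independent
implementation used as the oracle in the tests) REML fixed effects agree to
~1e-6 and REML/ML log-likelihoods to ~1e-9; standard errors agree to ~1%,
the residual difference being the usual covariance-convention gap between
mixed-model implementations.

Wald t statistics use a residual degrees-of-freedom convention
(df = n_obs - n_fixed), recorded in every result. Conventions differ across
ecosystems (Satterthwaite, Kenward-Roger, residual); no attempt is made to
match any particular one numerically, and none is needed: observed and
permuted statistics always use the identical fitter, so permutation
p-values are convention-invariant. A fit with numerically zero
random-intercept variance is flagged `singular`, not fatal. Degenerate
designs (constant drug column, fewer observations than fixed effects, no
participant with repeated measures) raise errors.

## Permutation test

The outcome column is permuted without restriction across all rows of the
per-network table (the within-participant scheme is available behind
`scheme="within_participant"`), the model refitted, and two-sided add-one
p-values computed: p = (1 + #{|t*| >= |t|}) / (m + 1), never zero, floor
1/(m+1). Unrestricted outcome permutation ignores the repeated-measures
correlation structure; because every refit restandardises its statistic
under its own variance estimates, the test remains approximately calibrated
— the suite's null study (500 cohorts, intraclass correlation 0.5) observes
rejection rates statistically indistinguishable from 5% for the interaction
and within-group drug terms. Permutations whose refit yields non-finite
statistics are redrawn (counted; more than 5% is an error).

## Synthetic cohorts

The generator emulates the statistical structure of the study, not scanner
physics. Per session, in-network voxels follow
`x(t) = lambda s_k(t) + sqrt(1 - lambda^2) eps(t)` with a network latent
signal `s_k`, so the expected within-network pairwise correlation is exactly
`lambda^2`; a delta-method closed form for the expected thresholded wDC
(`expected_mean_wdc`) agrees with simulation to ~1% and is used to reason
about effect sizes. Defaults mirror the study conditions: 20 participants
per group; 205 timepoints; an mFD group difference (nonautistic
0.10 +- 0.05 mm, autistic 0.15 +- 0.08 mm, Gamma-distributed traces); three
missing autistic sessions reproducing the unbalanced arms (18 placebo / 19
drug); sensorimotor loadings reduced under autistic placebo (0.42) and
restored by the drug (0.55) with frontoparietal mildly elevated (0.62) and
nudged down (0.58), the qualitative pattern under study, while the
nonautistic group is constant (0.55).

Two generator choices matter for realism of the *map z-scoring* step.
Out-of-network gray matter is parcelled into 24-voxel regions, each with its
own latent signal and a loading drawn from U(0.30, 0.60): real gray matter
has broad positive connectivity everywhere, and without this the two network
blocks dominate the map variance and standardization makes the two network
means artificially anti-correlated (a drug effect in one network would
induce an equal and opposite spurious effect in the other). Likewise the
default network blocks occupy only ~6% of gray matter each, mirroring the
modest brain fraction of the real masks. The residual coupling through the
global standardization is small but nonzero — it is a property of the
method, not of the generator.

What the generator does *not* emulate: BOLD spectral structure (no 0.01–0.1
Hz band-limiting; series are temporally white), hemodynamics, physiological
noise, spatial smoothness within parcels beyond the shared latent signal,
motion artifacts in the images themselves, or participant-stable
connectivity traits (sessions are independent given the spec, so the
random-intercept variance in image-level cohorts is essentially zero).
Passing tests therefore demonstrate correctness and calibration of the
pipeline's computations and inference under a faithful statistical
surrogate, not performance on real BOLD data.

## Problem sizes used by the checks

The test suite runs the null-calibration study at 8 participants/group with
1000 permutations and 500 Monte-Carlo replicates on mask-mean outcomes, and
the effect-recovery study at 10 participants/group on 12^3 image grids
(1000-voxel gray matter) with 205 timepoints, 100 replicates, 1000
permutations — sizes chosen so the full suite runs in minutes on one CPU
while keeping the binomial error bars tight enough to be informative. The
effect size for the recovery study (base loading 0.45, autistic-drug
sensorimotor 0.50) was calibrated once by simulation to sit near 100% power
and then frozen as a regression condition. `scripts/acceptance.py` runs the
study-scale defaults (20/group, 77 sessions, 5000 permutations).

## Known limitations

- The pipeline consumes preprocessed BOLD volumes on a common grid;
  registration, normalization, nuisance regression and filtering are out of
  scope, as is any voxelwise (mass-univariate) inference — only mask means
  are analysed.
- Unrestricted outcome permutation is the default for fidelity to the
  described procedure even though it is not the exchangeability-optimal
  scheme for repeated measures; the within-participant alternative is one
  flag away.
- The two network masks from the prior large-scale study are external
  artifacts and are not bundled; their published voxel counts (4446
  frontoparietal, 2803 sensorimotor) are carried as reference metadata only,
  and the generator fabricates geometrically simple stand-ins.
- Reported degrees of freedom use the residual convention and will not match
  Satterthwaite-style values printed elsewhere.
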