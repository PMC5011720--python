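# Methods

## Scope and model

`lobetract` implements the analysis chain of a structure–function twin
study of a long association tract: (i) virtual dissection and lobar
segmentation of a tractogram with per-segment FA/MD statistics, (ii)
Attention Network Test (ANT) scoring, (iii) univariate and bivariate ACE
twin modelling, and (iv) a phenotypic association stage (path model and
stepwise regression). A synthetic-data module generates inputs with the
statistical structure each stage assumes, so every operation is testable
against known ground truth.

## Twin ACE models

For a standardized trait on a twin pair, the model-implied covariance is
Var = a² + c² + e² with within-pair covariance a² + c² (MZ) and ½a² + c²
(DZ). `UnivariateACE` maximizes the exact per-pair bivariate-normal
log-likelihood; `BivariateACE` the per-pair 4-variate likelihood with each
component's cross-trait 2×2 block parameterised as (σ₁, σ₂, r) — an exact
reparameterisation of the 2×2 Cholesky factor that keeps every block
positive semidefinite while exposing the component correlations r_g, r_c,
r_e as direct parameters.

Assumptions: multivariate normal phenotypes, equal environments across
zygosities, no dominance/epistasis (no ADE model), no sex-limitation or age
moderation, complete pairs only. By default each trait is z-scored over all
twins and a common mean is still estimated jointly (`estimate_mean`);
raw-scale fitting is a constructor flag. No covariate adjustment happens
implicitly; `residualize_traits` is the explicit pre-fit hook for age/sex
regression when wanted.

Numerical choices:

- Likelihoods are evaluated from per-zygosity sufficient statistics (sample
  mean and scatter), so one evaluation is O(d³) with d ∈ {2, 4} and fitting
  cost is independent of pair count. Non-PD covariances get a large finite
  penalty so quasi-Newton gradients stay usable.
- Optimization: multi-start L-BFGS-B (4–8 dispersed anchors plus seeded
  uniform starts), bounds keep within-trait paths non-negative (boundary
  solutions such as a² = 0 or e² = 1 are reachable exactly) while
  cross-trait correlations are free in sign; ftol 1e-12, gtol 1e-10.
- Model comparison: χ² = 2·ΔlogLik with df = Δk for nested pairs
  (non-nested requests raise, AIC only), AIC = 2k − 2·logLik; the selected
  model is the lowest-AIC model not significantly worse than full ACE at
  α = 0.05.
- Profile CIs for variance shares fix the share s of one component,
  reallocate the remaining 1 − s over the other free components (inner
  optimization over total σ, a simplex split, and the mean), and solve
  2·ΔlogLik = χ²₁(0.95) by Brent bisection to 1e-4; bounds are clipped to
  [0, 1] and reported at the boundary when the deviance never crosses the
  critical value (e.g. a lower bound of 0 for a component estimated at 0).
  At the share boundary the E path is floored at 1e-5·σ to keep the pair
  covariance non-singular; the induced share perturbation is ~1e-10.
  Bivariate r_g/r_c/r_e CIs are ordinary fixed-parameter profiles (Brent to
  1e-3); an r_ph CI is available by percentile bootstrap of pairs within
  zygosity (default 200 refits).
- Identifiability: when a component's variance is zero for a trait, that
  component's cross-trait correlation is undefined and reported as NaN; its
  contribution to r_ph is still exactly 0. Fitting the full ACE Cholesky to
  data generated without C can pin r_g at a bound for the same reason — the
  AE-reduced bivariate model is provided for cohorts whose univariate best
  models contain no C.

The decomposition r_ph = r_g√(a²₁a²₂) + r_c√(c²₁c²₂) + r_e√(e²₁e²₂) holds
exactly for the fitted model (closure is asserted to 1e-10 in tests) and is
also exposed as the standalone `decompose_rph` for desk calculations from
published component estimates. Published decomposition tables computed from
univariate shares need not reproduce a study's own bivariate-fit
decompositions, which use the bivariate model's component estimates.

## Tract stage

Streamline points live in world mm; voxel lookup goes through the inverse
affine with round-half-away-from-zero and 0-based indices (nibabel
normalises TRK's corner-of-voxel convention to RAS-mm on read). Two-ROI
"AND" selection keeps streamlines with ≥1 point in both masks; "NOT"
removes streamlines touching an exclusion mask; both are idempotent and are
tested against a brute-force per-point oracle. Bend filtering truncates a
streamline at the first inter-segment turning angle above the threshold
(default 30°, the conventional tracking bend limit); truncation rather than
discarding is the default, with `drop=True` as the alternative, and
streamlines reduced below 2 points are dropped.

Labels are sampled nearest-neighbor (as appropriate for categorical
volumes); FA/MD are sampled trilinearly by default (nearest available)
because scalar fields are smooth — on a linear ramp the two differ by less
than one voxel's field variation. Segment means are point-weighted by
default (each retained point counts once); a streamline-weighted mean is an
option since either convention is defensible. Segments with fewer than 10
points are flagged low-confidence, not dropped. Points whose interpolation
support leaves the grid are skipped and counted.

Reliability uses the two-way absolute-agreement single-measure ICC(A,1)
(McGraw–Wong), matching the repeat-extraction use case where a systematic
offset between extractions should count against reliability; ICC(C,1) is a
flag. CIs use the standard F construction; an all-equal target matrix is a
degeneracy error. The implementation is cross-checked against pingouin in
the tests.

## ANT stage

QC removes, in order of attribution: incorrect trials; RTs strictly below
200 ms or strictly above 1500 ms (trials at exactly the bound are kept,
since the exclusion rule is phrased strictly); trials whose immediately
preceding trial in the same block was incorrect (post-error slowing), using
original correctness and adjacency, so QC is idempotent and order-checked.
Post-error removal does not carry across the block break. Subjects with raw
accuracy strictly below 80% are excluded before scoring.

Ratio scores divide each condition RT difference by the subject's overall
mean retained RT (the conventional ratio-score denominator); a
per-component baseline denominator (no-cue, center-cue, congruent mean
respectively) is available, and every ScoreSet records which convention was
used. Scores are exactly invariant to uniform multiplicative RT rescaling.

## Association stage

VIF_j = 1/(1 − R²_j) per predictor with flagging above 10. Stepwise
regression is forward selection at p_enter = 0.05 with backward removal at
p_remove = 0.10 (the common defaults of mainstream statistics packages),
over statsmodels OLS; with both thresholds at 1 it reproduces the full OLS
fit. Durbin–Watson is reported for the final residuals. The path model is a
manifest-variable multiple regression on z-scored variables — with a single
indicator per construct a latent-variable PLS structural model collapses to
exactly this — whose standardized coefficients are tested by nonparametric
case resampling (default 5000 draws, mandatory seed): t = β̂/SE_boot with a
two-tailed p from t(n − k − 1). Degenerate resamples are redrawn and
counted. Twin pair clustering is ignored by default, matching the classical
analysis; pair-level resampling is the documented alternative.
Bonferroni-corrected α = base/repetitions.

## Synthetic data

`gen_twin_cohort` assembles the full 2-twin × 2-trait covariance explicitly
(A correlates 1.0/0.5 within MZ/DZ pairs, C 1.0 in both, E twin-specific;
cross-trait latent correlations rg, rc, re) and samples jointly, raising a
named error if the assembled matrix is not PSD. Default pair counts are the
classical small twin design (14 MZ / 16 DZ); simulations request larger
cohorts explicitly.

`gen_ant_session` produces 6 blocks × 36 trials with the 3 cue × 2 flanker
cells balanced within block and shuffled by seed. Default cell means are
additive (cue and flanker offsets around 600 ms) chosen so a noiseless
session yields ratio scores of the magnitude reported for healthy
adolescent twin cohorts (alerting 0.060, orienting 0.090, EC 0.167);
per-condition means are not published for such cohorts, so these are
plausible ANT values, not a calibration. RT noise is multiplicative
log-normal with matched mean and SD (default SD 100 ms; Gaussian behind a
flag); the default error rate of 3% reproduces the ~97% accuracies typical
of healthy performers. RTs are capped at the 2000 ms response deadline.

`gen_tract_phantom` tiles the first grid axis with five axis-aligned label
slabs (labels 1–5, background 0 outside the grid) and draws smooth
sinusoidal-arc streamlines spanning all slabs in order, so per-segment
ground truth is unambiguous. FA/MD are constant per slab plus optional
Gaussian noise. What the phantom does not emulate: realistic brain
geometry, crossing fibers, partial-volume or scanner artifacts, or
diffusion signal formation — passing phantom tests demonstrates the
correctness of the selection/labeling/statistics code, not robustness to
real-data confounds. Likewise the twin generator draws exactly normal
phenotypes, so passing recovery tests says nothing about robustness to
non-normality.

## Problem sizes used in the checks

Parameter-recovery and CI-coverage checks use 100 replicates of 2000 MZ +
2000 DZ pairs per generating a² ∈ {0.2, 0.4, 0.6} (with c² = 0.2 so the
fitted ACE model is the generating model); bivariate recovery averages 5
replicates at the same size under the generating AE family. Enumeration
oracles run on 6-pair datasets over a 0.01 share grid. Calibration of
stepwise false entry and bootstrap null p-values uses 200 replicates at
n = 60 subjects. These sizes make the whole suite run in a few minutes on
one CPU while keeping Monte Carlo error well inside the asserted bands.

## Known limitations

- No dominance (ADE), sex-limitation, age-moderation, or missing-data FIML;
  complete pairs only.
- The bivariate r_ph CI is bootstrap-based rather than profile-based.
- Stepwise selection inherits the usual post-selection inference caveats;
  the reported CIs of the final model are conditional on selection.
- ROI drawing is out of scope: selection consumes pre-drawn mask volumes,
  and atlas registration is assumed done (the label volume must share the
  tractogram's grid).
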