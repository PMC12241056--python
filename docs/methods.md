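# Methods

## Model

The Scaled Subprofile Model treats the natural log of a participants ×
tracts metric matrix as an additive decomposition

    ln X_ij = mu + r_i + c_j + sum_c s_ic v_cj + eps_ij ,

where `r_i` is a per-subject offset (a global multiplicative scaling of the
raw metric), `c_j` the group mean regional profile, `v_c` regional
covariance patterns with subject expressions `s_c`, and `eps` residual
noise. Full double-centering (subtract row means and column means, add the
grand mean) eliminates `mu`, `r_i` and `c_j` exactly — order-invariantly, so
it equals the classical sequence of subject-mean removal followed by
group-profile removal — leaving the "subject residual profile" matrix whose
SVD yields the patterns. Eigenvalues are reported as score variances,
singular value² / (n−1). A double-centered n × p matrix has rank at most
min(n−1, p−1); components below a relative singular-value tolerance of
max(n, p)·eps are dropped, and an all-zero matrix yields an empty (not an
error) decomposition. Component signs are fixed by making each loading
vector's largest-magnitude entry positive; the fitness-facing sign of the
combined pattern is fixed later.

Fitness relation: candidate models are the *nested leading* component sets
1..k (never arbitrary subsets), scored by the Gaussian-likelihood
`BIC(k) = n ln(RSS_k/n) + (k+1) ln n` with the intercept counted and ties
broken toward smaller k; `k_max` defaults to min(15, rank). The selected
components are combined with their OLS coefficients, `w = Σ b_c v_c`; the
per-participant expression is z-scored (ddof=1) and, together with `w` and
`b`, negated when it correlates negatively with VO₂max, so higher expression
always means higher fitness. For the resulting simple regression the
standardized β equals the Pearson correlation and
`adjusted R² = 1 − (1−β²)(n−1)/(n−2)`; both raw and adjusted R² are
reported, and figures display the adjusted value.

## Bootstrap reliability

Participants are the resampling unit (the only exchangeable one). Each of
the (default) 10,000 replicates re-runs log → double-center → PCA → combine
with k **frozen** at the full-sample selection: the interval quantifies the
reliability of the observed pattern's tract weights, and re-selecting k per
replicate would mix model-selection variance into the loading CIs. PCA sign
indeterminacy is resolved by negating any replicate whose loading vector
correlates negatively with the full-sample point estimate; a full Procrustes
alignment of component subspaces is a known alternative and deliberately not
used (one pattern vector is being tracked, not a subspace). CIs are
equal-tail percentile intervals (2.5th/97.5th at the default level); they
need not bracket the point estimate and are compared on the unit-norm
loading scale — the scale on which patterns are plotted — so that replicate
fit magnitude does not leak into them (`scale="raw"` is available).
Replicates whose decomposition has rank < k (or a resampled VO₂max with zero
variance) are discarded and counted; more than 1% degenerate replicates
triggers a warning, all-degenerate is an error. The per-replicate
recomputation uses an eigendecomposition of the p × p cross-product matrix
and the closed-form OLS on exactly orthogonal score columns; this is
algebraically identical to the SVD route (tested against it) and roughly an
order of magnitude faster at n=167, p=42.

## Quality control

A cell is an extreme value when it lies beyond 3 IQR of that tract's
cross-participant distribution for that metric (quartiles by the
linear-interpolation definition; flags can differ at the margin under other
quantile rules — the definition is therefore fixed and stated). A
participant is excluded when two or more of the four metrics are extreme on
the same tract, or one metric is extreme on two or more tracts. Quartiles
are computed per tract per metric across participants by default; an
`axis="tracts"` option computes them within participant across tracts.
Missing cells after QC are a hard error — the analysis assumes complete
data after exclusions, and no imputation is attempted.

## Follow-up regressions

Univariate models regress each tract's log metric on VO₂max (a config flag
switches to the raw scale), unadjusted; Benjamini–Hochberg adjustment is
applied across the tested family, which defaults to the tracts found
reliable by the bootstrap (falling back to all tracts when none are). The
block-wise models accumulate TIV | age, sex | vascular risk level, APOE ε4 |
log WMH volume (alternative predictor sets, e.g. individual risk factors,
are accepted for sensitivity analyses). Standardized coefficients z-score
binary predictors exactly like continuous ones; unstandardized B, SE, p,
adjusted R² and the model F are reported per block, and
`β = B·SD(x)/SD(y)` holds identically. Complete-case analysis uses the
largest block's predictor set so R²-change comparisons share one sample.
Rank-deficient designs are rejected naming the collinear columns; a perfect
fit is flagged rather than reported as a spuriously infinite F with p = 0
from the F distribution's machinery.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes in a
healthy older-adult cohort: n = 167 participants (ages uniform 50–88), 42
bundles with realistic labels and per-metric baseline profiles (AD
1.05–1.50 ×10⁻³ mm²/s, RD 4.0–7.0 ×10⁻⁴, MD 6.5–9.5 ×10⁻⁴, FA 0.30–0.60),
VO₂max rescaled to mean 24.43, SD 5.40 ml/kg/min, and covariates with
cohort-realistic prevalences (female 78/167; cardiac arrest 5/167,
hypertension 55/167, hyperlipidemia 73/167, diabetes 8/167, smoking 66/167,
APOE ε4 49/167). The high-vascular-risk indicator is *derived* (≥2 risk
factors), not drawn: under independent factors its implied prevalence is
≈0.35, matching the target 60/167 without forcing. TIV ~ N(1.4×10⁶,
1.3×10⁵) mm³ and WMH ~ logNormal(0.9, 1.0) ml are chosen as realistic
values rather than published moments.

On the log scale each metric is baseline + subject factor `g_i ~ N(0,
subject_scale_sd)` + `signal_amplitude · (Σ_c s_ic v_cj + noise_sd ε_ij)`.
Key conventions, with defaults and why:

- **Expression scores** `s_1 ~ N(0,1)` — the planted signal SD is 1, so
  `noise_sd` (default 0.5) is expressed in expression-SD units. Later
  components decay geometrically (`component_sd_decay`, default 0.85):
  exactly degenerate expression variances would leave only the signal
  *subspace* identifiable, making "the first k components" ill-posed under
  within-subspace rotation.
- **`signal_amplitude`** (default 0.05, i.e. 5% metric variation per
  expression SD) converts the dimensionless block into log-metric units.
  It is invisible to every downstream statistic (PCA directions,
  correlations, BIC, standardized β are scale-invariant) and exists so raw
  values have realistic dispersion for the IQR-based QC: at amplitude ~1
  the raw scale is so heavy-tailed that clean data genuinely contains
  3-IQR extremes.
- **Planted loadings** default to random zero-sum unit vectors:
  double-centering annihilates the tract-mean component of any pattern, so
  a nonzero-mean planted vector would be unrecoverable by construction.
  Nuisance components are Gram–Schmidt-orthonormalised against the planted
  vector and the all-ones direction.
- **VO₂max** is `signal_strength · z(u) + √(1−signal_strength²) · N(0,1)`,
  affinely rescaled to the target mean/SD, where `u` is the
  `component_weights` combination of the *standardized* expressions
  (default equal weights — each signal component contributes equally).
  With one component this reduces to mixing against z(s_1), giving the
  configured correlation in expectation.
- **Covariate effects** (defaults: age −0.5, log WMH −0.25, vascular risk
  −0.15, APOE 0) enter s_1 additively on population-standardized
  covariates, with the residual variance chosen so s_1 keeps unit variance;
  effects are therefore exact standardized coefficients at the population
  level.
- **Subject factor** `subject_scale_sd` defaults to 0.1 (a 10% global
  scaling), included precisely because the log + double-centering step
  exists to remove it; tests assert the removal is exact.
- An optional exchangeable residual correlation is exposed (default 0 — the
  residual dependence structure beyond the patterns is not characterized);
  note that its exchangeable component is a row effect and is therefore
  also removed by double-centering.

What the generator does *not* emulate: spatial structure within tracts, raw
diffusion images or streamlines, metric-specific pattern differences (all
four metrics share the planted pattern and expressions, with independent
noise and subject factors), realistic residual correlation between
neighbouring bundles, and covariate interdependence (age and vascular risk
are drawn independently). Passing tests therefore demonstrate correctness
of the machinery and calibration under the assumed model, not performance
on real cohorts.

A consequence worth knowing: with the default subject factor (0.1)
dominating the per-tract amplitude (0.05), per-tract *univariate*
regressions on synthetic data are nearly powerless (per-tract correlations
~0.05) while the multivariate pattern reaches β ≈ 0.55–0.6 — the global
scaling buries single-tract effects that double-centering removes. The
univariate stage is validated for calibration (FDR control under the null,
agreement with a reference OLS implementation), not for power.

## Study designs behind the headline checks

- Pattern recovery: n=167, 42 tracts, one planted component,
  signal_strength 0.7, noise_sd 0.5 (half the expression SD); recovery
  criterion |cosine| ≥ 0.9 across seeds.
- BIC selection: the four-component study runs at noise_sd 0.25 so each
  component's increment sits above the PCA estimation floor and the study
  measures selection behaviour rather than attenuation; the one-component
  study keeps noise_sd 0.5.
- Bootstrap coverage: population loadings from one n=50,000 run of the same
  truth; 200 independent n=167 cohorts with 1,000 inner iterations each,
  coverage pooled over tracts.
- FDR control: 500 null cohorts (signal_strength 0), 42 tracts.
- Covariate recovery: exact betas on the true expression at n=2000; sign
  recovery through the fitted pattern at n=167 (estimation noise attenuates
  fitted-expression betas by roughly 1/√(1+noise_sd²), so absolute recovery
  is only asserted on the true expression).

Problem sizes were chosen so the full suite completes in a few minutes on a
single core while leaving the Monte-Carlo margins comfortably away from
their thresholds.

## Numerical choices and edge cases

- Quantiles: numpy's linear interpolation; documented because IQR flags are
  definition-sensitive at the margin.
- Rank tolerance: singular values below max(n, p)·eps·s_max are zero.
- z-scoring uses ddof=1 throughout (expression scores, standardized β).
- Constant VO₂max is rejected (nothing to model); a pattern whose combined
  expression has zero variance is rejected as degenerate; TIV (near-)
  collinear with expression (|r| > 0.999) yields a flagged, warned result
  rather than silent nonsense.
- Orientation ties (correlation exactly 0) keep the positive sign.
- All randomness flows through numpy Generators from explicit seeds; the
  pipeline derives per-metric stage seeds from the root seed via
  SeedSequence spawn keys, and identical configuration yields byte-identical
  report files (the manifest additionally carries a timestamp and SHA-256
  checksums).

## Known limitations

- One pattern per metric; no cross-metric joint decomposition.
- Forward application of a frozen pattern to new participants is exposed
  (`CenteringOffsets.apply_to_new`) but not validated against any external
  reference.
- Percentile CIs by default; bias-corrected and accelerated intervals
  (`ci_method="bca"`, jackknife acceleration) are available behind a flag
  but are not the validated default — the coverage study uses percentile
  intervals.
- No permutation test for whole-pattern significance; no mediation,
  interaction or longitudinal models.
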