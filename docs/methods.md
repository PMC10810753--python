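# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `twinlook`.

## Twin model

### Structure and likelihood

Phenotypes measured on both members of MZ and DZ twin pairs are modelled
as multivariate normal. Each variance component X ∈ {A, C, D, E} is
parameterized by an unconstrained lower-triangular path matrix L_X
(k × k for k traits), so X = L_X L_Xᵀ is positive semi-definite for every
parameter value — the Cholesky parameterization. The pair covariance is

    Σ_within   = A + C + D + E
    Σ_cross,MZ = A + C + D
    Σ_cross,DZ = ½A + C + ¼D

reflecting full/half sharing of additive-genetic effects, full/quarter
sharing of dominance effects, full sharing of the common environment, and
independence of the non-shared environment. C and D cannot be freed in the
same model (not jointly identified from MZ/DZ data); E is mandatory so the
likelihood is proper. Age (scaled to zero mean, unit s.d.) and sex
(0 = female, 1 = male) enter the mean model only, with effects equated
across twins and zygosity groups.

The objective is full-information maximum likelihood: each pair
contributes −2 log N(y_i; μ_i, Σ_i) over its observed entries. An absent
co-twin simply drops their rows of μ and rows/columns of Σ, which equals
analytic marginalization of the multivariate normal (verified against a
brute-force density oracle in the test suite). Pairs are grouped by
pattern (complete MZ, complete DZ, singles) so each evaluation performs
three Cholesky factorizations and vectorized quadratic forms, keeping
fits at 8,000 pairs below a second.

### Optimization

Quasi-Newton search (L-BFGS-B, numerical gradients) from a moment-based
start plus randomized restarts (3 by default). A fit is flagged
non-converged — not raised — when the best restarts disagree by more than
1e-4 in −2LL or the optimum sits on the penalty used for non-positive-
definite covariances. Sign indeterminacy of the Cholesky factors is
resolved after fitting by flipping column signs so diagonal paths are
non-negative; standardized quantities are invariant to this.

### Conventions

* df = (number of observed, non-missing trait values) − (free parameters).
* AIC = −2LL − 2·df (the convention used in twin-modelling reports where
  lower is better and values are typically negative).
* Nested comparison: Δχ² = Δ(−2LL) on Δdf = Δ(parameter count); p from the
  naive χ² upper tail. At variance-component boundaries the asymptotically
  correct reference is a χ² mixture; the naive reference is the standard
  reporting practice in this literature and is used deliberately —
  p-values for boundary components are conservative. Known limitation.
* Model selection: among nested models with p ≥ 0.05, lowest AIC wins;
  ties break to fewest parameters; if none is retained the full model is
  returned.
* Phenotypes are modelled on their raw (proportion / count) scale by
  default; a standardization flag exists for simulation studies.

### Saturated models

The saturated family frees a mean and s.d. per trait per twin-order ×
zygosity cell and a full correlation structure per zygosity, with equality
constraints declared by parameter tying (slots sharing a label share one
free parameter). The fully saturated two-trait model with age and sex on
the means has 2×(4 means + 4 s.d.s + 6 correlations) + 4 = 32 free
parameters. Twin and cross-trait cross-twin (CTCT) correlations are
extracted from the constrained saturated model — means, variances and
phenotypic correlations equated across twin order and zygosity, CTCT
directions equated within zygosity — with per-zygosity twin and CTCT
correlations left free. Correlation matrices are built as D·R·D; parameter
vectors implying a non-positive-definite R are penalized rather than
reparameterized, which is robust because the optimum is interior.

### Confidence intervals

95% intervals are profile-likelihood based: the set of values of the
target quantity (a standardized component share, or a correlation) whose
constrained refit raises −2LL by at most χ²₁(0.95) = 3.841. The
constrained refit for component shares uses SLSQP with an equality
constraint; because the constraint gradient vanishes where a path is
exactly zero, each refit starts from a feasible point constructed by
rescaling the component's paths to the target share, and a refit that
ends more than 1e-4 off the constraint is treated as infeasible. Bounds
for standardized components are clipped to [0, 1]. Whether the original
analyses used profile or transformed-bound intervals is not documented;
profile likelihood was adopted as the more principled default.

## Gaze phenotype extraction

A *look* is a maximal run of at least 3 consecutive samples (~25 ms at
120 Hz) assigned to one AOI, tolerating up to 1 consecutive invalid sample
inside the run (a lightweight stand-in for gap interpolation); a valid
sample outside every AOI always ends the run. Both thresholds are
configurable — published processing pipelines for this paradigm do not
fully specify them, and these are the smallest noise-robust choices.

Trial validity requires all of: valid-sample proportion ≥ 0.25, summed
valid-sample time ≥ 5 s, and at least one AOI look. The duration criterion
is interpreted as *valid* data time because elapsed trial time is fixed by
design. Per-trial measures: first AOI = AOI of the earliest-onset look;
face preference = face look time over total AOI look time across the whole
trial; exploration = distinct AOIs among looks starting within the first
10 s (the window is a configuration constant). Infants need ≥ 4 valid
trials; measures are unweighted means over valid trials. The missing-data
covariate is the mean missing proportion over valid trials.

Any AOI can be designated the target, so analyses contrasting e.g. the
most salient non-social object use the same code path.

Quality residualization: each phenotype is tested (cluster-robust linear
model) on the two gaze-quality covariates jointly; if either association
has p < 0.05 the phenotype is replaced by OLS residuals on both covariates
with the grand mean added back, so comparisons against the chance level
remain meaningful.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which everything downstream is validated.

**Pedigree.** Factor scores per component are standard normal with the
classical cross-twin correlations (A: 1 / 0.5; C: 1; D: 1 / 0.25; E: 0);
traits are linear combinations via the declared path matrices, plus age
and sex effects on the means. Defaults mirror the study dimensions:
155 MZ + 130 DZ same-sex pairs, ~12% incomplete pairs, age ~
Normal(168, 9) days truncated to [145, 203], sex shared within pair.
A declared-standardized spec must imply unit trait variances (checked to
1e-8) and positive E variance per trait.

**Gaze render.** Each trial: a lognormal latency (median 350 ms) with
gaze at screen centre (the gaze-contingent start), then a first look that
is the face with probability p_orient, then a random walk over the five
AOIs with occasional off-AOI excursions. The infant-level rates come from
probit links p = Φ(m + s·z) of the latent traits, with (m, s) solved in
closed form (mean via Φ, second moment via the bivariate normal CDF) to
hit target cohort moments — face orienting mean 0.30, face preference
mean 0.44 / s.d. 0.14, matching the published descriptives. The face's
*dwell duration* (not visit frequency) carries the preference bias: with
uniform visit frequencies over the five AOIs, face dwell d_face =
5·p_face·d̄ makes the expected face share of AOI time equal p_face; the
walk includes a revisit bias (probability 0.70 of returning to the
previous object) which is label-symmetric and therefore preserves the
face time share while producing realistic back-and-forth looking. With
mean dwell 850 ms this reproduces the published exploration descriptives
(mean ~3.6 objects in 10 s; all five objects reached in ~22% of trials).
The orienting latent spread defaults to 0.10 on the probability scale:
the observed 6-trial orienting proportion adds binomial noise of ~0.19
s.d. on top, so the observed spread cannot pin the latent value; 0.10
reproduces the observed total spread while leaving room for familial
signal. Missingness is a bursty two-state process (geometric blink runs,
mean 10 samples) at a per-infant rate ~ Normal(0.28, 0.13) clipped to
[0, 0.61], plus occasional look-away trials (4%) with extreme missingness
that fail the validity filter, reproducing realistic attrition (~5.8
valid trials of 6). A deterministic-dwell mode renders a noise-free
cycle with exact dwell shares for round-trip testing.

What the render does *not* emulate: saccade kinematics, pupil dynamics,
calibration drift, or spatial inaccuracy beyond small fixation jitter.
Passing round-trip tests therefore show the extraction logic is correct
and the generative chain is coherent — not that the pipeline is robust to
eye-tracker artefacts absent from the generator.

**Outcomes.** outcome = β·z(predictor) + covariate effects + noise with
noise variance 1 − β², optionally exchangeable within pairs, so the
outcome is marginally standardized and the clustered-error machinery is
genuinely exercised. |β| ≥ 1 is rejected.

## Association statistics

Linear regressions are estimated as generalized estimating equations with
an independence working correlation: point estimates are ordinary least
squares, standard errors come from the cluster-sandwich estimator over
twin pairs with no small-sample correction (so singleton clusters reduce
exactly to HC0). Continuous variables are scaled to unit variance so
slopes are standardized; binary sex stays 0/1. CIs are β ± 1.96·SE and
p-values use the normal reference. ΔR² compares the squared correlation
between fitted and observed outcome against the covariates-only null
(estimating equations have no canonical likelihood R²; this conventional
choice is recorded in the result object).

Tests against chance select the branch by Shapiro–Wilk at α = 0.05
(unspecified in the source analyses; 0.05 is the conventional default):
a one-sample t-test under normality, otherwise a Wilcoxon signed-rank
test with values at chance dropped before ranking and the statistic
reported as V = sum of positive-difference ranks (the R convention).
The effect size is d = (mean − chance)/s.d. in either branch. Skewness is
the adjusted Fisher–Pearson standardized third moment. FDR control is
Benjamini–Hochberg step-up, reporting each test's rank-assigned threshold
i·q/m as conventionally tabulated.

## Problem sizes

Stochastic validation uses the sizes at which the quantities are
identified with useful precision: 4,000 pairs per zygosity for univariate
and bivariate recovery (sampling s.d. of a standardized A share is then
~0.015), 10,000 pairs for the clustered-slope recovery, 200 replicates
for interval coverage, and study-sized cohorts (155 + 130 pairs) for
end-to-end pipeline behaviour. At study size the bivariate shared/unique
genetic split is weakly identified — its profile intervals are wide — and
model selection between AE and CE can flip across seeds; both behaviours
are properties of the design, not of the implementation.

## Known limitations

* Naive χ² reference at variance-component boundaries (conservative).
* No sex-limitation / moderation (G×E) models, no ordinal liability
  threshold models, no polygenic-score integration.
* The five-object screen layout is a stand-in (ring layout, counterbalanced
  face position); only the AOI contract matters downstream.
* The gaze generative law (walk + dwell bias) is a minimal mechanism that
  makes orienting and preference separately controllable, not a cognitive
  model of infant attention.
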