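# Methods

This note documents the models implemented in `clpnet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Data model and preprocessing

A `PanelDataset` holds two waves of item responses (the canonical network
uses 28 symptoms: 12 ITQ items on a 0–4 scale grouped into six two-item
dimensions — RE, AV, TH, NSC, AD, DR — plus 9 PHQ-9 and 7 GAD-7 items on
0–3 scales), gender and age covariates, and victimization-screening fields.

**Screening.** The analysis sample keeps participants who report
victimization *at least once* — any screening item strictly above the
scale's "never" anchor (0 for the BPBQ victim subscale, 1 for the Delaware
scale; `never_anchor` is a parameter) — and then drops those who failed
embedded control questions.  Counts are reported in that order
(victimized → excluded-invalid → final).

**Imputation.** Missing item responses are replaced by the item's observed
mean across participants (series-mean imputation), computed *after*
screening so invalid responders cannot contaminate the means.  The
alternative readings — person-mean imputation, or imputing before
screening — are coherent but not implemented; item-wise means match the
common statistical-package default.  Imputed values are deliberately not
rounded back to the ordinal grid: responses are treated as numeric
downstream, and leaving them continuous preserves each item's observed
mean exactly (a property the tests pin at 1e-12).

**Reliability and composites.** Cronbach's α uses the standard
k/(k−1)·(1 − Σ item variances / total variance) form with n−1 variances;
composites are plain item sums (no diagnostic cutoffs or caseness
algorithms).

## Construct-level cross-lagged path model

The three composites (CPTSD, depression, anxiety) at both waves, z-scored,
form a recursive path system: each wave-2 construct is regressed on all
three wave-1 constructs (three autoregressive + six cross-lagged paths)
and on gender and age; wave-1 covariances and wave-2 residual covariances
are free.  Constructs are **manifest composites, not latent variables**:
no factor loadings are estimated.  The asymmetry logic the model exists
for — directional prediction between constructs — is fully exercised at
the composite level, at the cost of ignoring measurement error, so
coefficients are attenuated relative to a latent-variable treatment.

Estimation is by maximum likelihood on the sample covariance matrix,
computed as iterated-FGLS seemingly-unrelated regressions (the two
coincide for this model class; with identical regressors in every
equation both reduce to per-equation least squares — a test asserts this
numerically).  Standard errors come from the joint GLS coefficient
covariance, which also feeds the Wald path-difference test.  The
difference is reported as *reverse minus forward*, so a stronger forward
path gives a negative difference.

Fit indices follow the conventional ML definitions: χ² = (n−1)·F_ML
against the saturated model; CFI and TLI against the
independence-of-all-variables baseline; RMSEA = √(max(χ²−df,0)/(df(n−1)))
with RMSEA = 0 and TLI = 1 by convention when df = 0; SRMR is the root
mean square of standardized covariance residuals over the lower triangle
including the diagonal.  The default specification (all nine paths, all
covariate paths, free covariances) is saturated — df = 0, χ² = 0, CFI =
TLI = 1 — which the tests pin as an identity; restricted path sets give
positive df and meaningful indices.  Cutoff labels: CFI/TLI above 0.95
"good", above 0.90 "acceptable"; RMSEA/SRMR at or below 0.08 "acceptable"
(boundary inclusive).

## Symptom-level cross-lagged panel network

All item columns and covariates are z-scored per wave (ddof = 1), so edge
weights are fully standardized regression coefficients — necessary for
expected-influence sums to be comparable across instruments with different
response ranges, and for a single penalty to treat all predictors
symmetrically.  For each wave-2 symptom the package solves

  (1/2n)·‖y − b₀ − Xβ‖² + λ·Σ_{j penalized} |β_j|

by cyclic coordinate descent on the Gram form (O(p²) per sweep regardless
of n), with gender and age unpenalized.  Whether the original workflow
penalized covariates is not documented anywhere we know of; leaving
confounders unpenalized is the conservative choice and is exposed through
`unpenalized_cols`.

**Penalty selection.**  The λ grid is log-spaced over
[λ_max·ratio, λ_max] with 50 points and ratio 0.01, where λ_max is the
KKT bound computed on the residual after the unpenalized-only fit.  Folds
(10 by default) come from one seeded permutation shared across all node
regressions, so the whole network is a deterministic function of
(data, seed).  The default selection rule is the **one-standard-error
rule**: the largest λ whose CV error is within one SE of the minimum.
This was an open design point; we measured both rules under the
generator's study conditions and the minimum-CV rule admitted 15–30%
false-positive edges in null and sparse-truth networks, while the 1se
rule held false edges at 0–1% with unchanged sensitivity (1.0) for
standardized effects of |0.3| at n ≈ 1400.  Since the stated purpose of
cross-validated regularization in this workflow is to suppress
false-positive edges, 1se is the default and `lambda_rule="min"` remains
available.

The self-lag coefficient of each regression is stored as the
autoregressive effect `a_j`; the off-diagonal coefficients form `B`.
Display thresholding (|weight| ≥ 0.05 by default) affects exports only,
never the stored matrix; ties in the strongest-edge ranking break by
(source, target) label order.

**Centrality.**  Expected influence uses *signed* sums (not absolute
strength): Out-EI(i) = Σ_{j≠i} B[i,j], In-EI(j) = Σ_{i≠j} B[i,j], with
autoregressive and covariate coefficients excluded entirely.  The identity
Σ In-EI = Σ Out-EI = Σ B holds by construction and is tested at 1e-12.
Centrality difference tests use percentile bootstrap intervals of the
difference (α = 0.05) over participant resamples; this is the bootnet-style
convention, documented here as our choice rather than inferred from any
particular prior analysis.

## Bootstrap diagnostics

*Edge-weight bootstrap*: resample participants with replacement, re-fit the
full network per replicate (CV included), percentile CIs per edge; a
CI-overlap matrix summarizes how separable edges are.  Replicates that fail
(e.g. a zero-variance column after resampling) are skipped and counted;
more than 5% failures aborts.  *Case-dropping bootstrap*: for each drop
proportion in {0.05, 0.10, …, 0.75}, re-estimate on subsamples without
replacement and correlate subsample centralities with the full-sample ones
(Pearson by default, Spearman by flag).  The CS-coefficient is the largest
proportion p such that at *every* proportion up to p at least 95% of
correlations are ≥ 0.7; the 0.7/0.95 constants and the grid follow the
convention behind the usual "CS > 0.25 moderate / CS > 0.5 very stable"
reading and are all exposed as parameters.  Proportions whose retained
subsample would fall under 10 rows per node are skipped with a warning.

Every replicate draws its RNG from (seed, replicate index), so bootstrap
output is independent of execution order or any parallel partitioning —
the first k replicates of a longer run equal a k-replicate run exactly.

## Synthetic-data generator

The generator emulates a two-wave victimization cohort with roughly a
six-month lag.  Wave-1 latent symptom scores are standard normal with
exchangeable within-wave correlation ρ (default 0.3; no published value
exists for the residual item-level correlation, so it is a free
parameter).  Wave-2 latents follow the first-order cross-lagged system
W₂ = W₁(diag(a)+B) + covariate effects + correlated noise, with the truth
matrix B (zero diagonal) and autoregressions a required to have spectral
radius below 1.  `make_truth` draws a support of exactly
round(density·p(p−1)) cells at ±effect_size (signs 50/50) and *redraws*
(never shrinks) up to 100 times if the draw is unstable, so stated effect
magnitudes are always exact; genuinely unstable configurations are
rejected.  Latents are discretized to each instrument's ordinal range by
equiprobable normal quantile thresholds (wave-2 columns are first scaled
by their analytic marginal SD so the thresholds hit their target
frequencies; a test checks 2-percentage-point calibration at n = 10000).
`discretize=False` emits the continuous latents, used for construct-level
recovery experiments where composites are quasi-continuous.

Defaults emulate the screening funnel of school-based victimization
surveys: 25% screen-negative, 7% control-question failures, 2% MCAR item
missingness at wave 1 only (wave-2-style online administration forces
complete responses), adolescent age distribution 13.2 ± 2.0 years, and
small covariate loadings (0.1) so gender/age adjustment is exercised
without dominating.  A single seeded generator is consumed per call; no
global RNG state.

What the generator does **not** emulate — and hence what green tests do
not establish about real cohorts: skewed (non-equiprobable) symptom
marginals, selective attrition between waves, informative missingness,
measurement non-invariance across waves, and latent-factor structure
beyond the exchangeable correlation.  Recovery results say the estimator
works when its assumptions hold, not that any particular clinical finding
replicates.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately modest problems —
10-node networks at n = 2000 (≈1400 after screening) for recovery and
stability, the 28-node canonical set for null calibration, n = 3000 for
construct-level path recovery, 50–200 bootstrap replicates — sizes at
which each effect of interest is decisively detectable while a full run
stays in the minutes range.  Coordinate descent converges when the largest
coefficient change in a sweep falls below 1e-8 (default; error on
non-convergence at 100k sweeps); the warm-started path reuses solutions
down the λ grid.  λ_max is taken as exactly the first grid point so the
all-zero model is always selectable.  Zero-variance columns are reported
by node label; degenerate centrality vectors (zero variance) contribute a
correlation of 0 to stability curves rather than NaN.

## Known limitations

Composite-score (manifest) path modelling attenuates construct-level
coefficients relative to latent-variable SEM; no FIML (inputs are
pre-imputed); no within-wave partial-correlation networks, bridge or
strength centralities, moderated networks, or multi-group invariance
testing; two waves only; MCAR missingness only.
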