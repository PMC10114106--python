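# Methods

This note records the statistical procedures the package implements, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Data model

A cohort is a rectangle with `ID` (unique), `PHENO`, optional `TIME`, and
typed exposure/covariate columns. Three families are supported: `lm`
(real-valued phenotype), `logistic` (0/1), and `cox` (time-to-event). For
survival runs the schema names only `ID`/`PHENO`/`TIME`, so `PHENO` doubles
as the 0/1 event indicator and `TIME` (strictly positive) is follow-up to
event or censoring.

Categorical columns carry an explicit ordered level set; when no ordering
is declared, levels are taken in first-seen file order and the first level
is the dummy-coding reference. "Unwanted" response codes (survey artefacts
such as `prefer_not_to_answer`) are user-supplied per column, never
hard-coded. Rows are never imputed: every model stage uses the complete
cases of exactly the columns it touches, so the analysis n varies by
exposure and is always reported.

Group splitting into A (selection), B (calibration) and C (held-out
validation) accepts explicit id lists or fractions; fractional splits are a
seeded uniform permutation partition, deterministic given the seed.

## Unpenalized engines

Linear models are ordinary least squares (standard errors from the
unbiased residual variance, t-based Wald p-values); logistic models are
Newton MLEs of the binomial likelihood; Cox models maximize the partial
likelihood with the **Efron** approximation for tied event times and carry
no intercept. These engines sit on statsmodels and lifelines; the
package's own tests check them against brute-force oracles (grid search
over the written-out binomial log-likelihood; 1-D golden-section
maximization of the written-out Efron partial likelihood).

Convergence: relative log-likelihood tolerance 1e-8 with at most 100
Newton steps (lifelines' solver is tightened to precision 1e-9 so the Cox
MLE is reproducible to ~1e-6). Complete separation in logistic fits is
*reported*, not repaired: the fit returns `converged=False` with a
separation diagnostic (triggered by the solver's singular Hessian or by a
coefficient norm above 50 on the standardized scale) and downstream stages
treat it as unusable.

One p-value per exposure: the slope's Wald p for a single-term exposure, a
joint likelihood-ratio test of all dummy terms for a multi-level
categorical. This convention is used uniformly in the scan and in the
stepwise calibration.

## XWAS

For each exposure: take the complete cases of {exposure} ∪ covariates,
regress the phenotype on exposure + covariates in the designated family,
and store the effect size(s) and the exposure p-value. After the loop the
p-values are corrected for multiple testing — Benjamini–Yekutieli by
default (`adjusted_(i) = min(1, p_(i)·m·c(m)/i)` with `c(m)=Σ 1/j`,
step-up monotone), with BH and Bonferroni as alternatives. Exposures whose
fit fails (separation, rank deficiency) are reported flagged and excluded
from the correction, reducing m accordingly — an unconverged Wald p would
be meaningless. The correction therefore runs over converged exposures
only; this is a documented choice.

## Penalized selection

The selection machinery is implemented in the package (not delegated),
because its exact conventions are load-bearing for everything downstream.

**Design.** Exposure terms are dummy-expanded (reference dropped) and
standardized to mean 0 / unit variance on the selection rows; penalties
are scale-sensitive and this puts every exposure on an equal footing.
Constant terms are dropped with a warning. Covariates are forced into
every model: penalty factor 0, left on their raw scale. Coefficients are
reported both on the design scale and back-transformed to the original
scale.

**Elastic net.** Cyclic coordinate descent on
`avg-negative-loglik + λ Σ_j w_j (α|β_j| + (1−α)/2 β_j²)`, exact
univariate updates (so the objective is non-increasing by construction),
active-set sweeps, warm starts down a log-spaced path of 100 λ values from
the analytic all-zero KKT bound `λ_max` down to `λ_max·1e-3`. `λ_max` is
computed at the covariate-only null fit; for α < 0.001 (including ridge)
the bound is anchored at α = 0.001, where the pure-L2 bound would be
infinite. Logistic and Cox families use the standard outer
iteratively-reweighted quadratic approximation with the same inner solver;
the Cox working terms use the Breslow tie approximation (standard for
penalized partial-likelihood paths; the unpenalized recalibration engine
still uses Efron). Cross-validation uses k = 10 seeded folds by default,
dealt round-robin within outcome strata for logistic/cox; `λ_min`
minimizes the mean held-out deviance (squared error / binomial deviance /
partial-likelihood deviance per event), with ties resolved toward the
larger, more parsimonious λ.

**Hierarchical interactions.** Pairwise interaction selection solves an
overlapped group lasso: each exposure has a main-effect group, and each
pair (j,k) has an interaction group whose latent coefficient block
contains *both mains' columns plus their element-wise products*. Because a
nonzero interaction group necessarily contributes to its parents' main
columns, strong hierarchy holds by construction of the convex program
rather than by a constraint. Group weights are √(group size). The
objective is minimized by FISTA with group soft-thresholding and adaptive
restart (tolerance 1e-8 relative objective change), with a power-iteration
Lipschitz bound and warm starts along the path. Only linear and logistic
losses are offered here; survival callers select on the event indicator
with the logistic loss and recalibrate in the Cox family afterwards.
Product columns are products of the standardized mains and are not
re-standardized.

## PXS derivation

**Main effects** (`derive_pxs` / `PXS(...)`): Step 1 runs the
cross-validated elastic net (lasso by default, α = 1) on group A complete
cases and carries forward every exposure with a nonzero coefficient at
λ_min; an empty selection is an error. Step 2 runs backward stepwise
elimination on group B: fit all candidates + covariates jointly, remove
the single worst exposure whose p ≥ 0.05 (ties broken by removing the
later-listed exposure), refit, and stop when all remaining exposures are
independently significant. Covariates are never removed. One variable is
removed per iteration — not all non-significant ones at once — matching
standard backward-elimination semantics. The complete-case rows are fixed
at the initial candidate set so successive fits are nested and their
likelihood-ratio tests comparable (recomputing complete cases after each
removal would change n between iterations; the package trades a few rows
for comparability).

**Interactions** (`derive_pxs_interactions` / `PXS(..., interactions=True)`):
Step 1 runs the hierarchical group lasso on group A; Step 2 refits an
unpenalized model of the designated family containing exactly the selected
main and product terms plus covariates on group B. There is deliberately
no stepwise pruning here — the variant recalibrates only, and its greater
propensity to keep weak terms (and hence to overfit) is a property of the
procedure that the package reproduces rather than repairs. Rank-deficient
recalibrations drop aliased product terms with a warning.

**Scale of the calibrated model.** The group-B refits are performed on the
group-A standardized exposure scale. This keeps one invariant exact: the
model's score weights *are* the final fit's exposure-term coefficients,
and scoring a new individual applies the stored training centers/scales
(and training dummy coding) before taking the weighted sum. Covariates
adjust the calibration fit but never contribute to the score.

**Scoring and assessment.** Group C individuals with a missing value,
unwanted code, or unseen categorical level in any needed term are
unscoreable and counted, never imputed. Assessment fits
`PHENO ~ PXS + covariates` on scored group-C rows (covariate adjustment at
validation is a documented choice) and reports R² / AUC / C-index with a
seeded percentile-bootstrap CI.

## Model comparison and stratification

AUC is the Mann–Whitney form (ties count ½). Harrell's C-index counts a
pair usable when the earlier observed time is an event (an event tied with
a censoring time is usable — the censored individual outlived the event);
two events with tied times are not usable; ties in predicted risk count ½.
`delta_pred` bootstraps the *difference*: each replicate resamples
individuals once and evaluates both models on the same replicate (the
paired design removes between-replicate variance from the difference);
the CI is percentile-based with B = 1000 by default, and replicates on
which a metric is undefined are redrawn (at most 100 times).
`risk_stratify` fits a Cox (or logistic) model on the top-decile indicator
of the score, reporting exp(β) with a 95% Wald interval, plus a 100-bin
percentile table with per-bin event counts and incidence = events/bin-size
(per-bin rather than cumulative incidence; the table's event counts sum to
the cohort total).

## Synthetic cohorts

The generator draws an exchangeable latent Gaussian (single correlation ρ,
the simplest structure that exercises dense inter-exposure correlation):
continuous exposures are the latents; categoricals are equal-probability
quantile slices of theirs (so a categorical's effect is monotone across
levels). True effects are declared on the standardized latent scale.
Covariates are age ~ N(57, 8²) and sex ~ Bernoulli(½), entering the linear
predictor on the standardized scale. Outcomes: `lm` adds N(0,1) noise;
`logistic` draws Bernoulli(expit(η)); `cox` draws event times from an
exponential hazard `λ₀·e^η` (λ₀ = 0.05 by default) with Uniform(0, 10)
censoring, giving event rates in the 25–30% range at the defaults.
Missingness is injected completely at random per exposure (default 2%),
and categorical exposures additionally receive the unwanted code at 2% —
ID/PHENO/TIME and covariates are never touched.

Default conditions (n = 2000 per analysis group, 20 exposures of which 4
carry standardized effects of 0.3, ρ = 0.2) are the regime the recovery
tests and the acceptance script run under; the fixture files in
`fixtures/` are small (n = 250) deterministic draws with a YAML manifest
of their generating specs.

What the generator does *not* emulate: realistic marginal distributions of
real biobank exposures, informative (non-random) missingness, measurement
error, non-proportional hazards, or effects that act through category
boundaries rather than the latent. Passing recovery tests therefore shows
the machinery is correct under its stated assumptions, not that real
cohorts will yield comparable sensitivity.

## Problem sizes and runtime choices

Simulation-based tests use 150–6000 individuals, 4–50 exposures, 10–200
replicates, and 15–100-value λ paths — sizes chosen so the full suite and
the acceptance script each run in minutes on a single core while keeping
every Monte-Carlo margin comfortable. The acceptance script derives all of
its sub-seeds from the single `--seed` argument, so its JSON output is
exactly reproducible.

## Known limitations

- No interactions beyond pairwise; no three-way hierarchy.
- No robust/clustered standard errors, stratified or time-varying Cox, or
  Firth correction for separation.
- No imputation or automated variable-transformation heuristics; inputs
  are analyzed as typed.
- The survival interaction pathway selects on the event indicator
  (logistic surrogate), ignoring follow-up time at the selection stage;
  the Cox recalibration restores the time scale but selection can miss
  exposures whose effect is mainly on timing.
- Bootstrap CIs are percentile (not BCa); coverage is approximate in small
  groups.
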