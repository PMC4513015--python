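# Methods

## The problem

The analysis ("substantive") model of interest relates a fully observed
outcome to covariates, f(Y | X, Z, ψ), where the p covariates X are partially
observed and the q covariates Z are complete.  Multiple imputation by fully
conditional specification (FCS, "chained equations") fills the missing X
entries M times from univariate imputation models and pools the M analyses by
Rubin's rules.  When the substantive model is non-linear — a squared term, an
interaction, a Cox proportional-hazards outcome — the default FCS imputation
models (each covariate linear in the outcome and the other covariates) are
*incompatible* with it: no joint model has both as its conditionals.  An
incompatible imputation model is, in general, mis-specified, and the pooled
estimates of the non-linear coefficients are biased, typically attenuated.

## Substantive-model-compatible FCS

This package imputes each covariate Xj from the density proportional to

    f(Y | X, Z, ψ) · f(Xj | X₋j, Z, φj)

which is by construction the conditional of a joint model whose
outcome-given-covariates component *is* the substantive model.  One chain
iteration visits the covariates in turn (ascending count of missing values, a
deterministic proxy for the "closest to monotone" ordering used by FCS
software; ties broken by column index) and, for each covariate j:

1. draws ψ from its posterior given the current completed data — a proper
   Bayesian draw under the Jeffreys prior f(β, σ²) ∝ 1/σ² for the normal
   family; a multivariate-normal draw at the MLE with the inverse observed
   information for logistic and Poisson families; for the Cox family a
   multivariate-normal draw of β at the partial-likelihood estimate followed
   by the Breslow baseline cumulative hazard evaluated at the drawn β;
2. draws φj from the covariate-model posterior fit to **all** n subjects
   using the current fill (a Gibbs-style update conditioning on Xj's previous
   imputations — this is what distinguishes the algorithm from standard FCS,
   which fits to the Xj-observed subjects only);
3. re-imputes the missing Xj entries by rejection sampling.

Because the Xj update conditions on its own previous imputations, the chain
can need more burn-in than standard FCS; per-iteration means of each
partially observed covariate are recorded (`ImputationResult.trace`) so
convergence can be checked, and the iteration count is a prominent parameter.

The M imputed datasets come from M **independent** chains (each with its own
burn-in), with per-chain seeds spawned deterministically from the master
seed.  Independent chains match the between-imputation independence that
Rubin's variance rule assumes.

## Rejection sampling

The fitted covariate conditional f(Xj | X₋j, Z, φj) is the proposal, so the
target/proposal ratio is f(Y | Xj, X₋j, Z, ψ), which must be bounded above in
Xj.  The per-family acceptance probabilities (ratio divided by its bound):

| family    | acceptance probability                  | bound                   |
|-----------|-----------------------------------------|-------------------------|
| normal    | exp(−(Y − g)² / 2σε²)                   | density at Y = g        |
| discrete  | model probability of the observed Y     | probabilities ≤ 1       |
| cox, D=0  | exp(−H0(W)·e^g)                         | survivor function ≤ 1   |
| cox, D=1  | H0(W)·exp(1 + g − H0(W)·e^g)            | maximised at H0·e^g = 1 |

with g the substantive model's linear predictor at the candidate.  Proposal
and uniform draws consume one seeded stream in a fixed order, so runs are
exactly reproducible given (seed, data, configuration).  Candidates are
drawn in geometrically growing blocks per still-missing value and scanned
for the first acceptance — sequentially equivalent to one-at-a-time
sampling, but with a loop count logarithmic in the attempt cap.

A value that reaches the attempt cap (default 10,000 proposals) falls back,
by default, to the best candidate seen (highest acceptance probability) with
a logged warning; `fallback="strict"` raises instead.  In the simulation
scenarios the fallback fires for roughly 0.01% of draws, so it does not
shape results, but a subject whose outcome is wildly unlikely under every
plausible covariate value will be imputed at the kernel's mode rather than
aborting a long run.  One structural case is an uncensored subject whose
event time precedes every event time in the current completed-data Breslow
fit: H0(W) = 0 makes every candidate's acceptance zero, and the fallback
applies.

## Cox details

The baseline cumulative hazard uses the Breslow convention throughout: tied
events share one risk-set denominator, H0 is a right-continuous step
function with H0(0) = 0, and subjects censored before the first event have
H0(W) = 0.  Uncertainty in H0 is deliberately ignored (β is drawn, H0 is
plugged in) — a known limitation of the approach; the simulation study
nevertheless shows close-to-nominal interval coverage.  The repeated
partial-likelihood fits inside the chain (hundreds per dataset) use an
in-package Newton–Raphson solver over vectorised risk-set sums; the
per-imputation analysis fits in the pooling step go through lifelines.

## Pooling

Pooled estimate = mean of the M per-imputation ML estimates; total variance
= W̄ + (1 + 1/M)·B with W̄ the mean model-based variance and B the sample
variance of the estimates; degrees of freedom by the classical Rubin rule
ν = (M − 1)(1 + W̄/((1 + 1/M)B))².  B = 0 gives infinite df and a normal
interval, which makes pooling M identical fits reproduce the single-fit CI
exactly.  The Barnard–Rubin small-sample adjustment is available behind
`small_sample=True` but off by default, matching the classical rule used in
the simulation references.

## Comparators

*Passive FCS*: each covariate imputed from a linear (logistic if binary)
model on the other covariates, Z, and the outcome — plus outcome-by-covariate
products when the substantive model has an interaction, and, for survival
outcomes, the event indicator and Nelson–Aalen marginal cumulative hazard in
place of the raw outcome.  Parameters are fit to the subjects with the target
observed; derived design terms are recomputed passively (in this package they
are never stored, so passivity is structural).

*JAV* ("just another variable"): each non-linear design term is materialised
as its own column, missing whenever a parent is missing, and every partially
observed column — including derived columns and binary covariates — is
imputed by chained normal-linear models given everything else and the
outcome.  The deterministic relation between a derived column and its parents
is not enforced, and the analysis fit uses the stored columns as-is.  JAV is
only defined here for numeric-outcome models.

The "polynomial combination" comparator is not implemented.

## The simulation harness

The generators emulate three study designs:

- **quadratic**: Y = 4 − 4X + X² + ε with X ~ N(2, 1), a lognormal with mean
  2 and variance 1 (log-scale parameters μ = log(4/√5), σ² = log(5/4)), or
  an equal mixture of N(1.125, 0.234) and N(2.875, 0.234); n = 1000.
- **interaction**: Y = X1 + X2 + X1X2 + ε with five joint covariate designs
  (bivariate normal with correlation 0.5; bivariate lognormal correlated 0.5
  on the log scale; X2 | X1 ~ N((X1 − 2)², 2); X1 ~ Bernoulli(0.5) with
  X2 | X1 ~ N(X1, 1); and the Bernoulli case with a shifted lognormal X2).
- **cox**: hazard 0.002·exp(X1 + X2), X1 ~ Bernoulli(0.5),
  X2 | X1 ~ N(X1, 1), independent exponential censoring at rate 0.002
  (≈ 64% of subjects experience the event).

ε is iid normal with variance σε² solving R² = 0.5.  For the normal-X
quadratic design this is exact: −4X + X² = (X − 2)² − 4, so Var(g) = 2 and
σε² = 2, giving SD(Y) = 2.  Elsewhere σε² = Var(g) is computed by a 10⁷-draw
Monte-Carlo integral with a fixed internal seed, so every run of a scenario
uses identical generating parameters.

Missingness is MCAR (each eligible value observed independently with
probability 0.7) or MAR with observation probability expit(α₀ + α₁Y),
α₁ = −1/SD(Y), and α₀ calibrated once per scenario at the population level
(root-finding over a fixed Monte-Carlo sample of Y) so the marginal
observation probability is 0.7.  In two-covariate designs X1 and X2 are
masked independently with the same mechanism.  Because calibration is
population-level, per-dataset observed fractions vary around 0.7 as they
would in the field.

What the generators do *not* emulate: real missingness is rarely exactly
M(C)AR, covariates are rarely exactly (log)normal, and outcomes carry
measurement error.  Passing tests therefore demonstrate correctness of the
algorithmic machinery and its behaviour under the stated designs — including
two designs where the covariate models are deliberately mis-specified — not
robustness on arbitrary real data.

`run_study` derives per-replicate seeds from (master seed, replicate index),
so any single replicate can be re-run in isolation; replicates where any
requested method fails (e.g. a collinearity error after extreme imputed
values) are excluded pairwise and counted, so methods are always compared on
the same datasets.

## Numerical choices and defaults

- M = 10 imputations, 10 chain iterations, rejection cap 10,000 — the
  conventional FCS operating point; all exposed.
- Covariate models always include an intercept; logistic fits are
  unpenalised, with separation surfaced as an error naming the covariate
  (an optional `ridge` rescues separated fits on request).
- Collinear covariate-model designs raise rather than being silently
  dropped — extreme imputed values under incompatible comparator models are
  a documented failure mode, and hiding them would distort comparisons.
- Bayesian linear draws use a QR factorisation; rank deficiency is detected
  from the R diagonal at relative tolerance 1e-10.
- The Newton Cox solver iterates to a 1e-9 step norm, capped at 50
  iterations; it is validated against lifelines and a brute-force
  partial-likelihood maximisation.
- Missing values in CSV input are empty fields or the literal `NA`; the
  in-memory sentinel is NaN.

## Problem sizes in the test suite

The distributional checks run at full strength (10⁶ kernel draws, 30–50k
accepted rejection-sampler draws, a 5000-subject closed-form conditional
check).  The end-to-end scenario replications in the acceptance tests use
60 replicates for the quadratic designs, 50 for the interaction design and
30 for the Cox design, with pass bands of ±3 binomial Monte-Carlo standard
errors at those counts; `scripts/acceptance.py` re-runs them at 200 (Cox:
100) replicates.

## Known limitations

- Categorical covariates with more than two levels, missing outcomes and
  missing fully-observed covariates are out of scope (the engine assumes
  Y/W/D and Z complete).
- The Cox ψ draw ignores baseline-hazard uncertainty (above).
- Poisson outcomes use the discrete-outcome acceptance bound and the same
  MVN-at-MLE posterior approximation as logistic models, but the logistic
  path is the one exercised by the study designs.
- With heavily mis-specified covariate models the imputations converge to a
  well-defined but wrong distribution; the mixture-X and quadratic-dependence
  designs quantify this deliberately.
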