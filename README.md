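# smcfcs

Substantive-model-compatible fully conditional specification (SMC-FCS)
multiple imputation of partially observed covariates, for analysts whose
regression model of interest contains non-linear covariate effects, an
interaction, or a Cox proportional-hazards outcome.

## Why

Chained-equations multiple imputation fills missing covariate values from
univariate models that are, by default, linear in the outcome and the other
covariates.  If the analysis model f(Y | X, Z, ψ) has a squared term, an
interaction, or a non-linear link, those defaults are **incompatible** with
it — no joint distribution has both as its conditionals — and the pooled
estimates of the non-linear coefficients are biased, typically attenuated
towards zero.

SMC-FCS instead imputes each partially observed covariate Xj from the
density proportional to

    f(Y | X, Z, ψ) · f(Xj | X₋j, Z, φj)

so every imputation model is compatible with the analysis model by
construction.  The density is non-standard, so draws are made by rejection
sampling with the covariate conditional f(Xj | X₋j, Z, φj) as proposal; the
acceptance probability is the outcome density at the candidate divided by
its upper bound in Xj — exp(−(Y − g)²/2σε²) for a normal model, the model
probability of the observed Y for discrete outcomes, and, for a Cox model
with Breslow baseline cumulative hazard H0, exp(−H0(W)e^g) for censored
subjects and H0(W)·exp(1 + g − H0(W)e^g) for events.  Analyses of the M
completed datasets are combined by Rubin's rules: pooled estimate
ψ̂ = M⁻¹Σψ̂ₘ, total variance W̄ + (1 + 1/M)B, t reference with
ν = (M − 1)(1 + W̄/((1 + 1/M)B))² degrees of freedom.

The package also implements the standard comparator imputers — passive FCS
and "just another variable" (JAV) — and a simulation harness that
reproduces the method-comparison study designs head-to-head.  See
`docs/methods.md` for the full model account.

## Worked example

Impute a covariate with a quadratic effect, fit, and pool:

```python
import numpy as np
import smcfcs as sf
from smcfcs.simulation import generate_quadratic, apply_missingness

rng = np.random.default_rng(42)
full = generate_quadratic("normal", 1000, rng)        # y = 4 - 4x + x^2 + eps
data = apply_missingness(full, ("x",), "mcar", rng)   # ~30% of x missing

spec = sf.SubstantiveModelSpec(
    family="normal", outcome="y",
    terms=(sf.linear("x"), sf.power("x", 2)),
)
cov_specs = [sf.CovariateModelSpec("x", family="normal")]

problem = sf.validate_problem(data, spec, cov_specs)
result = sf.impute(problem, spec, cov_specs, m=10, n_iter=10, seed=2024)
pooled = sf.pool_fits(result.datasets, spec)
print(pooled.to_frame().round(3))
```

```
       estimate     se        df  ci_lower  ci_upper
const     3.944  0.162   142.959     3.625     4.264
x        -3.963  0.147   482.640    -4.253    -3.674
x^2       0.973  0.034  2265.378     0.907     1.040
```

All three generating coefficients (4, −4, 1) are recovered within their
pooled 95% intervals, including the quadratic term that linear default
imputation attenuates to ≈0.7 in this scenario.  `result.trace` holds
per-iteration covariate means for convergence checks, and
`sf.SMCFCSImputer` wraps the same machinery as a scikit-learn-style
estimator (`fit(data)` → `datasets_`, `trace_`).

The same pipeline is available from the shell:

```sh
smcfcs impute --data data.csv --config model.yaml --m 10 --iter 10 \
    --seed 7 --out-prefix imp          # writes imp_1.csv ... imp_10.csv
smcfcs pool imp_*.csv --config model.yaml
smcfcs simstudy --scenario quadratic-normal --mechanism mar \
    --methods jav,smcfcs --reps 200 --seed 7 --out study.csv
```

`model.yaml` declares the substantive model family and design terms, the
partially observed covariates with their conditional-model families, and
any fully observed covariates (see `smcfcs.data_model.load_config`).

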