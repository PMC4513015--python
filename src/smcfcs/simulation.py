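"""Simulation studies: data generators, missingness mechanisms and the
method-comparison harness.

Three families of scenarios are generated:

- quadratic:   Y = 4 - 4 X + X^2 + eps, with X normal, lognormal or a
               two-component normal mixture, always with mean 2 and
               variance 1; eps variance chosen so R^2 = 0.5.
- interaction: Y = X1 + X2 + X1 X2 + eps (zero intercept, unit
               coefficients), with five joint distributions for (X1, X2);
               eps variance again targets R^2 = 0.5.
- cox:         hazard h(t | X) = 0.002 exp(X1 + X2), X1 ~ Bernoulli(0.5),
               X2 | X1 ~ N(X1, 1), independent exponential censoring with
               rate 0.002.

Missingness is MCAR (each eligible value observed independently with
probability 0.7) or MAR with observation probability expit(a0 + a1 Y),
a1 = -1 / SD(Y) and a0 calibrated at the population level so the marginal
observation probability is 0.7.  Population quantities (the residual
variance solving R^2 = 0.5, SD(Y), a0) are computed analytically where a
closed form is simple (normal-X quadratic: sigma_eps^2 = 2) and otherwise by
a 10^7-draw Monte Carlo integration with a fixed internal seed, so every run
of a scenario uses identical generating parameters.

``run_study`` runs the full generate / mask / impute / fit / pool loop for a
set of methods and reports the empirical mean, SD and 95%-interval coverage
of the estimates with Monte-Carlo standard errors.  Replicates in which any
requested method fails are excluded pairwise (and counted), so methods are
always compared on the same datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .comparators import (
    JAVImputer,
    PassiveFCSImputer,
    fit_with_stored_terms,
)
from .data_model import (
    CovariateModelSpec,
    SubstantiveModelSpec,
    interaction,
    linear,
    power,
    validate_problem,
)
from .engine import impute
from .pooling import fit_substantive, pool, pool_fits

__all__ = [
    "ScenarioConfig",
    "StudyResult",
    "generate_quadratic",
    "generate_interaction",
    "generate_cox",
    "apply_missingness",
    "scenario_population",
    "make_scenario",
    "run_study",
]

QUADRATIC_BETA = (4.0, -4.0, 1.0)
INTERACTION_BETA = (0.0, 1.0, 1.0, 1.0)
COX_BETA = (1.0, 1.0)
BASE_HAZARD = 0.002
OBS_PROB = 0.7
R_SQUARED = 0.5

# lognormal with mean 2 and variance 1 on the raw scale
LN_SIGMA2 = np.log(1.25)
LN_MU = np.log(4.0 / np.sqrt(5.0))
# normal mixture with mean 2, variance ~1
MIX_MEANS = (1.125, 2.875)
MIX_VAR = 0.234

_MOMENT_SEED = 20150214  # internal seed for population Monte-Carlo integrals
_MOMENT_DRAWS = 10_000_000

QUADRATIC_SCENARIOS = ("quadratic-normal", "quadratic-lognormal", "quadratic-mixture")
INTERACTION_SCENARIOS = (
    "interaction-bvn",
    "interaction-lognormal",
    "interaction-quadratic-dependence",
    "interaction-binary-normal",
    "interaction-binary-lognormal",
)
COX_SCENARIOS = ("cox-binary-normal",)


@dataclass
class ScenarioConfig:
    """One simulation cell: scenario, missingness mechanism and sizes."""

    scenario: str
    mechanism: str = "mcar"
    n: int = 1000
    reps: int = 1000
    m: int = 10
    n_iter: int = 10
    obs_prob: float = OBS_PROB
    seed: int | None = None

    def __post_init__(self):
        all_scenarios = QUADRATIC_SCENARIOS + INTERACTION_SCENARIOS + COX_SCENARIOS
        if self.scenario not in all_scenarios:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0 < self.obs_prob < 1:
            raise ValueError("observation probability must lie in (0, 1)")
        if self.n < 10:
            raise ValueError("n must be at least 10")


@dataclass
class StudyResult:
    """Empirical summaries per method and parameter, with MC errors."""

    table: pd.DataFrame
    n_reps_used: int
    n_failed: dict = field(default_factory=dict)

    def cell(self, method: str, parameter: str) -> pd.Series:
        t = self.table
        row = t[(t["method"] == method) & (t["parameter"] == parameter)]
        return row.iloc[0]


# ---------------------------------------------------------------------------
# Covariate draws
# ---------------------------------------------------------------------------

def _draw_x_quadratic(dist: str, n: int, rng) -> np.ndarray:
    if dist == "normal":
        return rng.normal(2.0, 1.0, n)
    if dist == "lognormal":
        return np.exp(rng.normal(LN_MU, np.sqrt(LN_SIGMA2), n))
    if dist == "mixture":
        comp = rng.random(n) < 0.5
        sd = np.sqrt(MIX_VAR)
        return np.where(comp, rng.normal(MIX_MEANS[0], sd, n), rng.normal(MIX_MEANS[1], sd, n))
    raise ValueError(f"unknown covariate distribution {dist!r}")


def _draw_x_interaction(kind: str, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    if kind == "bvn":
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        x = rng.multivariate_normal([2.0, 2.0], cov, size=n, method="cholesky")
        return x[:, 0], x[:, 1]
    if kind == "lognormal":
        cov = LN_SIGMA2 * np.array([[1.0, 0.5], [0.5, 1.0]])
        v = rng.multivariate_normal([LN_MU, LN_MU], cov, size=n, method="cholesky")
        return np.exp(v[:, 0]), np.exp(v[:, 1])
    if kind == "quadratic-dependence":
        x1 = rng.normal(2.0, 1.0, n)
        x2 = rng.normal((x1 - 2.0) ** 2, np.sqrt(2.0))
        return x1, x2
    if kind == "binary-normal":
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.normal(x1, 1.0)
        return x1, x2
    if kind == "binary-lognormal":
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = x1 + np.exp(rng.normal(LN_MU, np.sqrt(LN_SIGMA2), n))
        return x1, x2
    raise ValueError(f"unknown interaction scenario {kind!r}")


# ---------------------------------------------------------------------------
# Population calibration (residual variance for R^2 = 0.5, SD(Y), MAR a0)
# ---------------------------------------------------------------------------

def _linpred_sample(scenario: str, rng, size: int) -> np.ndarray:
    if scenario in QUADRATIC_SCENARIOS:
        b0, b1, b2 = QUADRATIC_BETA
        x = _draw_x_quadratic(scenario.split("-", 1)[1], size, rng)
        return b0 + b1 * x + b2 * x ** 2
    kind = scenario.split("-", 1)[1]
    b0, b1, b2, b3 = INTERACTION_BETA
    x1, x2 = _draw_x_interaction(kind, size, rng)
    return b0 + b1 * x1 + b2 * x2 + b3 * x1 * x2


@lru_cache(maxsize=None)
def scenario_population(scenario: str) -> dict:
    """Population constants for a scenario: residual variance giving
    R^2 = 0.5, SD(Y), and the MAR intercept a0 with a1 = -1/SD(Y).

    Analytic for the normal-X quadratic scenario (Var(-4X + X^2) = 2 for
    X ~ N(2, 1)); otherwise a fixed-seed Monte-Carlo integral.
    """
    if scenario in COX_SCENARIOS:
        return {}
    rng = np.random.default_rng(_MOMENT_SEED)
    g = _linpred_sample(scenario, rng, _MOMENT_DRAWS)
    if scenario == "quadratic-normal":
        sigma2 = 2.0
    else:
        sigma2 = float(np.var(g)) * (1.0 - R_SQUARED) / R_SQUARED
    sd_y = float(np.sqrt(np.var(g) + sigma2))
    # MAR calibration: E[expit(a0 - Y / SD(Y))] = obs_prob over the Y
    # population (a fixed 10^6 subsample keeps root finding cheap)
    y = g[:1_000_000] + rng.normal(0.0, np.sqrt(sigma2), 1_000_000)
    a1 = -1.0 / sd_y

    def marginal(a0):
        return float(np.mean(expit(a0 + a1 * y))) - OBS_PROB

    a0 = brentq(marginal, -20.0, 20.0, xtol=1e-10)
    return {"sigma2_eps": sigma2, "sd_y": sd_y, "alpha0": float(a0), "alpha1": a1}


# ---------------------------------------------------------------------------
# Dataset generators
# ---------------------------------------------------------------------------

def generate_quadratic(dist: str, n: int, rng) -> pd.DataFrame:
    """Quadratic scenario dataset with columns (y, x)."""
    pop = scenario_population(f"quadratic-{dist}")
    b0, b1, b2 = QUADRATIC_BETA
    x = _draw_x_quadratic(dist, n, rng)
    y = b0 + b1 * x + b2 * x ** 2 + rng.normal(0.0, np.sqrt(pop["sigma2_eps"]), n)
    return pd.DataFrame({"y": y, "x": x})


def generate_interaction(kind: str, n: int, rng) -> pd.DataFrame:
    """Interaction scenario dataset with columns (y, x1, x2)."""
    pop = scenario_population(f"interaction-{kind}")
    b0, b1, b2, b3 = INTERACTION_BETA
    x1, x2 = _draw_x_interaction(kind, n, rng)
    y = b0 + b1 * x1 + b2 * x2 + b3 * x1 * x2 + rng.normal(0.0, np.sqrt(pop["sigma2_eps"]), n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


def generate_cox(n: int, rng) -> pd.DataFrame:
    """Cox scenario dataset with columns (w, d, x1, x2).

    Event times are exponential with subject rate 0.002 exp(x1 + x2);
    censoring times exponential with rate 0.002; w = min(T, C),
    d = 1(T < C).
    """
    b1, b2 = COX_BETA
    x1 = (rng.random(n) < 0.5).astype(float)
    x2 = rng.normal(x1, 1.0)
    rate = BASE_HAZARD * np.exp(b1 * x1 + b2 * x2)
    t = rng.exponential(1.0 / rate)
    c = rng.exponential(1.0 / BASE_HAZARD, n)
    w = np.minimum(t, c)
    d = (t < c).astype(float)
    return pd.DataFrame({"w": w, "d": d, "x1": x1, "x2": x2})


def apply_missingness(data: pd.DataFrame, x_cols, mechanism: str, rng,
                      scenario: str | None = None,
                      obs_prob: float = OBS_PROB) -> pd.DataFrame:
    """Mask covariate values MCAR or MAR (independently per covariate).

    MCAR: each value observed with probability ``obs_prob``.  MAR: observed
    with probability expit(a0 + a1 Y), a1 = -1/SD(Y) and a0 the population
    calibration for this scenario.
    """
    out = data.copy()
    n = len(out)
    if mechanism == "mcar":
        p_obs = np.full(n, obs_prob)
    elif mechanism == "mar":
        if scenario is None:
            raise ValueError("MAR masking requires the scenario name")
        pop = scenario_population(scenario)
        p_obs = expit(pop["alpha0"] + pop["alpha1"] * out["y"].to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    for col in x_cols:
        observed = rng.random(n) < p_obs
        vals = out[col].to_numpy(dtype=float, copy=True)
        vals[~observed] = np.nan
        out[col] = vals
    return out


# ---------------------------------------------------------------------------
# Scenario -> model specifications
# ---------------------------------------------------------------------------

def make_scenario(scenario: str):
    """Substantive spec, covariate specs, masked columns and true parameter
    values for a scenario."""
    if scenario in QUADRATIC_SCENARIOS:
        spec = SubstantiveModelSpec(
            family="normal", outcome="y", terms=(linear("x"), power("x", 2))
        )
        cov_specs = [CovariateModelSpec("x", "normal")]
        truth = dict(zip(spec.param_names, QUADRATIC_BETA))
        return spec, cov_specs, ("x",), truth
    if scenario in INTERACTION_SCENARIOS:
        spec = SubstantiveModelSpec(
            family="normal", outcome="y",
            terms=(linear("x1"), linear("x2"), interaction("x1", "x2")),
        )
        binary_x1 = scenario in ("interaction-binary-normal", "interaction-binary-lognormal")
        cov_specs = [
            CovariateModelSpec("x1", "logistic" if binary_x1 else "normal"),
            CovariateModelSpec("x2", "normal"),
        ]
        truth = dict(zip(spec.param_names, INTERACTION_BETA))
        return spec, cov_specs, ("x1", "x2"), truth
    if scenario in COX_SCENARIOS:
        spec = SubstantiveModelSpec(
            family="cox", time="w", event="d", terms=(linear("x1"), linear("x2"))
        )
        cov_specs = [
            CovariateModelSpec("x1", "logistic"),
            CovariateModelSpec("x2", "normal"),
        ]
        truth = dict(zip(spec.param_names, COX_BETA))
        return spec, cov_specs, ("x1", "x2"), truth
    raise ValueError(f"unknown scenario {scenario!r}")


def _generate(scenario: str, n: int, rng) -> pd.DataFrame:
    if scenario in QUADRATIC_SCENARIOS:
        return generate_quadratic(scenario.split("-", 1)[1], n, rng)
    if scenario in INTERACTION_SCENARIOS:
        return generate_interaction(scenario.split("-", 1)[1], n, rng)
    return generate_cox(n, rng)


# ---------------------------------------------------------------------------
# Study harness
# ---------------------------------------------------------------------------

METHODS = ("complete-case", "passive-fcs", "jav", "smcfcs")


def _run_method(method, masked, spec, cov_specs, config, rep_seed):
    if method == "complete-case":
        cc = masked.dropna()
        est, var, names = fit_substantive(cc, spec)
        se = np.sqrt(var)
        if spec.family == "normal":
            dfree = len(cc) - len(names)
            crit = stats.t.ppf(0.975, dfree)
        else:
            crit = stats.norm.ppf(0.975)
        return names, est, est - crit * se, est + crit * se
    if method == "smcfcs":
        problem = validate_problem(masked, spec, cov_specs)
        result = impute(problem, spec, cov_specs, m=config.m,
                        n_iter=config.n_iter, seed=rep_seed)
        pooled = pool_fits(result.datasets, spec)
        return pooled.names, pooled.estimate, pooled.ci_lower, pooled.ci_upper
    if method == "passive-fcs":
        y_int = spec.family == "normal" and any(
            t.kind == "interaction" for t in spec.terms
        )
        imp = PassiveFCSImputer(
            substantive=spec, covariates=tuple(cov_specs), m=config.m,
            n_iter=config.n_iter, y_interactions=y_int, random_state=rep_seed,
        ).fit(masked)
        pooled = pool_fits(imp.datasets_, spec)
        return pooled.names, pooled.estimate, pooled.ci_lower, pooled.ci_upper
    if method == "jav":
        imp = JAVImputer(
            substantive=spec, covariates=tuple(cov_specs), m=config.m,
            n_iter=config.n_iter, random_state=rep_seed,
        ).fit(masked)
        ests, variances = [], []
        names = None
        for d in imp.datasets_:
            e, v, names = fit_with_stored_terms(d, spec)
            ests.append(e)
            variances.append(v)
        pooled = pool(np.array(ests), np.array(variances), names=names)
        return pooled.names, pooled.estimate, pooled.ci_lower, pooled.ci_upper
    raise ValueError(f"unknown method {method!r}")


def run_study(config: ScenarioConfig, methods=("smcfcs",)) -> StudyResult:
    """Run the full simulation for one scenario cell.

    Per replicate: generate the dataset, apply the missingness mechanism,
    run every requested method, fit and pool, and record estimates and
    whether each nominal 95% interval covers the generating value.
    Replicates where any method errors are dropped for all methods.
    """
    for mth in methods:
        if mth not in METHODS:
            raise ValueError(f"unknown method {mth!r}")
    spec, cov_specs, x_cols, truth = make_scenario(config.scenario)
    records = {mth: [] for mth in methods}
    n_failed = {mth: 0 for mth in methods}
    used = 0
    for rep in range(config.reps):
        ss = np.random.SeedSequence(entropy=[0 if config.seed is None else config.seed, rep])
        gen_rng = np.random.default_rng(ss.spawn(1)[0])
        data = _generate(config.scenario, config.n, gen_rng)
        masked = apply_missingness(
            data, x_cols, config.mechanism, gen_rng,
            scenario=config.scenario, obs_prob=config.obs_prob,
        )
        rep_out = {}
        failed = None
        for k, mth in enumerate(methods):
            method_seed = int(ss.generate_state(len(methods) + 1, dtype=np.uint32)[k + 1] >> 1)
            try:
                rep_out[mth] = _run_method(mth, masked, spec, cov_specs, config, method_seed)
            except Exception:
                failed = mth
                break
        if failed is not None:
            n_failed[failed] += 1
            continue
        used += 1
        for mth, out in rep_out.items():
            records[mth].append(out)

    rows = []
    for mth in methods:
        outs = records[mth]
        names = outs[0][0]
        est = np.array([o[1] for o in outs])
        lo = np.array([o[2] for o in outs])
        hi = np.array([o[3] for o in outs])
        for i, name in enumerate(names):
            true_val = truth[name]
            cover = np.mean((lo[:, i] <= true_val) & (true_val <= hi[:, i]))
            mean = est[:, i].mean()
            sd = est[:, i].std(ddof=1)
            reps = len(outs)
            rows.append(
                {
                    "scenario": config.scenario,
                    "mechanism": config.mechanism,
                    "method": mth,
                    "parameter": name,
                    "truth": true_val,
                    "mean": mean,
                    "sd": sd,
                    "coverage": cover,
                    "mc_se_mean": sd / np.sqrt(reps),
                    "mc_se_coverage": np.sqrt(cover * (1.0 - cover) / reps),
                    "n_reps": reps,
                }
            )
    return StudyResult(table=pd.DataFrame(rows), n_reps_used=used, n_failed=n_failed)
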