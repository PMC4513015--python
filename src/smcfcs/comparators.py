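"""Benchmark imputation methods: standard (passive) FCS and JAV.

Standard FCS imputes each covariate from a generalised linear model on the
other covariates and the outcome, fit to the subjects with that covariate
observed; derived design terms (squares, interactions) are then recomputed
passively from the imputed values.  For survival outcomes the imputation
models condition on the event indicator and the Nelson-Aalen estimate of the
marginal cumulative hazard instead of the raw outcome, the standard
recommendation for Cox substantive models.  For substantive models with an
interaction between two partially observed covariates, the imputation model
for one covariate can additionally include the product of the outcome with
the other covariate.

JAV ("just another variable", or transform-then-impute) instead materialises
each derived term as a separate column whose missingness follows its parent
covariates, and imputes all columns - including the derived ones, and binary
covariates - with chained normal-linear models conditioning on everything
else and the outcome.  The deterministic relation between a derived column
and its parents is *not* enforced, which is exactly what makes JAV consistent
under MCAR for linear substantive models but biased under MAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .covariate_models import draw_linear_phi, draw_logistic_phi, sample_proposal
from .data_model import (
    CovariateModelSpec,
    ImputationProblem,
    SubstantiveModelSpec,
    validate_problem,
    visit_order,
)
from .engine import ImputationResult, initialize_fill
from .substantive_models import StepFunction

__all__ = [
    "nelson_aalen",
    "passive_fcs_impute",
    "jav_impute",
    "PassiveFCSImputer",
    "JAVImputer",
    "fit_with_stored_terms",
]


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen estimator of the marginal cumulative hazard:
    H(t) = sum_{t_k <= t} d_k / n_k with n_k the size of the risk set."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    order = np.argsort(times, kind="stable")
    t_s, d_s = times[order], events[order]
    at_risk = np.arange(len(t_s), 0, -1)
    ev_times, first_idx, counts = np.unique(t_s[d_s], return_index=True, return_counts=True)
    if ev_times.size == 0:
        return StepFunction(np.empty(0), np.empty(0))
    pos = np.searchsorted(t_s, ev_times, side="left")
    jumps = counts / at_risk[pos]
    return StepFunction(ev_times, np.cumsum(jumps))


def _outcome_features(data: pd.DataFrame, spec: SubstantiveModelSpec) -> dict[str, np.ndarray]:
    """Fully observed outcome covariates entering the imputation models."""
    if spec.family == "cox":
        w = data[spec.time].to_numpy(dtype=float)
        d = data[spec.event].to_numpy(dtype=float)
        na = nelson_aalen(w, d)
        return {"_event": d, "_cumhaz": np.asarray(na(w), dtype=float)}
    return {"_y": data[spec.outcome].to_numpy(dtype=float)}


def _fcs_sweep(cur, problem, order, models, rng, fit_rows_per_col):
    """One chained-equations sweep: for each covariate, fit its imputation
    model to the rows where it is observed and redraw the missing rows."""
    for j in order:
        col = problem.x_cols[j] if j < problem.p else None
        name, family, predictors, obs_mask = models[j]
        pred = np.column_stack(
            [np.ones(problem.n)] + [p(cur) for p in predictors]
        )
        target = cur[name].to_numpy(dtype=float)
        fit_rows = fit_rows_per_col[j]
        if family == "normal":
            phi = draw_linear_phi(target[fit_rows], pred[fit_rows], rng)
        else:
            phi = draw_logistic_phi(target[fit_rows], pred[fit_rows], rng, name=name)
        miss = ~obs_mask
        if miss.any():
            target[miss] = sample_proposal(phi, pred[miss], rng)
            cur[name] = target
    return cur


class PassiveFCSImputer(BaseEstimator):
    """Standard FCS with passive recomputation of derived terms.

    Each covariate Xj is imputed from a linear (or logistic, if binary)
    model on the other covariates, the fully observed covariates and the
    outcome features: Y itself for non-survival families, or (D, Nelson-Aalen
    cumulative hazard) for the cox family.  With ``y_interactions=True`` the
    products of Y with the other partially observed covariates are added,
    mirroring common practice when the substantive model has an interaction.
    Parameter draws are proper Bayesian for linear models and
    MVN-at-the-MLE for logistic ones.
    """

    method_name = "passive-fcs"

    def __init__(self, substantive=None, covariates=(), fully_observed=(),
                 m=10, n_iter=10, y_interactions=False, random_state=None):
        self.substantive = substantive
        self.covariates = covariates
        self.fully_observed = fully_observed
        self.m = m
        self.n_iter = n_iter
        self.y_interactions = y_interactions
        self.random_state = random_state

    def _models(self, problem, features):
        models = []
        feat_names = list(features)
        for j, cs in enumerate(self.covariates):
            preds = []
            for other in problem.x_cols:
                if other != cs.name:
                    preds.append(lambda cur, c=other: cur[c].to_numpy(dtype=float))
            for z in problem.z_cols:
                preds.append(lambda cur, c=z: cur[c].to_numpy(dtype=float))
            for f in feat_names:
                preds.append(lambda cur, a=features[f]: a)
            if self.y_interactions and "_y" in features:
                for other in problem.x_cols:
                    if other != cs.name:
                        preds.append(
                            lambda cur, c=other, yv=features["_y"]:
                            yv * cur[c].to_numpy(dtype=float)
                        )
            models.append((cs.name, cs.family, preds, problem.R[:, j]))
        return models

    def fit(self, data: pd.DataFrame, y=None):
        problem = validate_problem(
            data, self.substantive, list(self.covariates), self.fully_observed
        )
        features = _outcome_features(data, self.substantive)
        models = self._models(problem, features)
        order = visit_order(problem.R)
        fit_rows = [np.flatnonzero(problem.R[:, j]) for j in range(problem.p)]
        children = np.random.SeedSequence(self.random_state).spawn(self.m)
        datasets, traces = [], []
        for chain_seed in children:
            rng = np.random.default_rng(chain_seed)
            cur = initialize_fill(problem, rng)
            trace = np.empty((self.n_iter, problem.p))
            for t in range(self.n_iter):
                cur = _fcs_sweep(cur, problem, order, models, rng, fit_rows)
                trace[t] = [cur[c].mean() for c in problem.x_cols]
            datasets.append(cur)
            traces.append(trace)
        self.problem_ = problem
        self.datasets_ = datasets
        self.trace_ = np.stack(traces)
        self.result_ = ImputationResult(
            datasets=datasets, trace=self.trace_, attempts_total=0, n_fallback=0,
            method=self.method_name, m=self.m, n_iter=self.n_iter,
            seed=self.random_state,
        )
        return self


@dataclass(frozen=True)
class DerivedColumn:
    """A derived design column materialised as its own variable for JAV."""

    name: str
    parents: tuple[str, ...]

    def compute(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


def _derived_from_terms(spec: SubstantiveModelSpec):
    """The non-linear terms of the substantive model, as (name, parents,
    compute) triples to materialise for JAV."""
    out = []
    for term in spec.terms:
        if term.kind == "linear":
            continue
        out.append((term.name, term.variables(), term.values))
    return out


class JAVImputer(BaseEstimator):
    """"Just another variable" (transform-then-impute) imputation.

    Derived terms of the substantive model become separate columns, missing
    whenever any parent is missing, and every partially observed column
    (original or derived, continuous or binary) is imputed by a chained
    normal-linear model on all other variables and the outcome.  Only
    defined for substantive models with a numeric outcome Y.
    """

    method_name = "jav"

    def __init__(self, substantive=None, covariates=(), fully_observed=(),
                 m=10, n_iter=10, random_state=None):
        self.substantive = substantive
        self.covariates = covariates
        self.fully_observed = fully_observed
        self.m = m
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        spec = self.substantive
        if spec.family == "cox":
            raise ValueError("JAV is defined here for numeric-outcome models only")
        problem = validate_problem(
            data, spec, list(self.covariates), self.fully_observed
        )
        derived = _derived_from_terms(spec)
        work = data.copy()
        all_cov_specs = [CovariateModelSpec(cs.name, "normal") for cs in self.covariates]
        for name, parents, compute in derived:
            vals = compute(work).astype(float)
            miss = np.zeros(len(work), dtype=bool)
            for pcol in parents:
                miss |= work[pcol].isna().to_numpy()
            vals = np.where(miss, np.nan, vals)
            work[name] = vals
            all_cov_specs.append(CovariateModelSpec(name, "normal"))
        jav_problem = ImputationProblem(
            data=work,
            x_cols=tuple(cs.name for cs in all_cov_specs),
            z_cols=tuple(self.fully_observed),
        )
        yv = work[spec.outcome].to_numpy(dtype=float)
        models = []
        for j, cs in enumerate(all_cov_specs):
            preds = [
                (lambda cur, c=other: cur[c].to_numpy(dtype=float))
                for other in jav_problem.x_cols if other != cs.name
            ]
            preds += [
                (lambda cur, c=z: cur[c].to_numpy(dtype=float))
                for z in jav_problem.z_cols
            ]
            preds.append(lambda cur, a=yv: a)
            models.append((cs.name, "normal", preds, jav_problem.R[:, j]))
        order = visit_order(jav_problem.R)
        fit_rows = [np.flatnonzero(jav_problem.R[:, j]) for j in range(jav_problem.p)]
        children = np.random.SeedSequence(self.random_state).spawn(self.m)
        datasets, traces = [], []
        for chain_seed in children:
            rng = np.random.default_rng(chain_seed)
            cur = initialize_fill(jav_problem, rng)
            trace = np.empty((self.n_iter, jav_problem.p))
            for t in range(self.n_iter):
                cur = _fcs_sweep(cur, jav_problem, order, models, rng, fit_rows)
                trace[t] = [cur[c].mean() for c in jav_problem.x_cols]
            datasets.append(cur)
            traces.append(trace)
        self.problem_ = jav_problem
        self.datasets_ = datasets
        self.trace_ = np.stack(traces)
        self.result_ = ImputationResult(
            datasets=datasets, trace=self.trace_, attempts_total=0, n_fallback=0,
            method=self.method_name, m=self.m, n_iter=self.n_iter,
            seed=self.random_state,
        )
        return self


def fit_with_stored_terms(data: pd.DataFrame, spec: SubstantiveModelSpec):
    """Fit the substantive model using materialised term columns (JAV analysis
    fit): the stored derived columns are used as-is, never recomputed."""
    cols = [np.asarray(data[t.name], dtype=float) for t in spec.terms]
    D = np.column_stack([np.ones(len(data))] + cols) if spec.has_intercept else np.column_stack(cols)
    if spec.family != "normal":
        raise ValueError("stored-term fits are defined for the normal family")
    res = sm.OLS(np.asarray(data[spec.outcome], dtype=float), D).fit()
    return np.asarray(res.params), np.asarray(res.bse) ** 2, spec.param_names


def passive_fcs_impute(data, spec, cov_specs, fully_observed=(), m=10, n_iter=10,
                       seed=None, y_interactions=False) -> ImputationResult:
    """Functional wrapper over :class:`PassiveFCSImputer`."""
    imp = PassiveFCSImputer(
        substantive=spec, covariates=tuple(cov_specs), fully_observed=tuple(fully_observed),
        m=m, n_iter=n_iter, y_interactions=y_interactions, random_state=seed,
    ).fit(data)
    return imp.result_


def jav_impute(data, spec, cov_specs, fully_observed=(), m=10, n_iter=10,
               seed=None) -> ImputationResult:
    """Functional wrapper over :class:`JAVImputer`."""
    imp = JAVImputer(
        substantive=spec, covariates=tuple(cov_specs), fully_observed=tuple(fully_observed),
        m=m, n_iter=n_iter, random_state=seed,
    ).fit(data)
    return imp.result_
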