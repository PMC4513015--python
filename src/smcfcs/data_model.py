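"""Problem definition, missingness bookkeeping and model specifications.

The package works on a rectangular dataset holding one outcome (a numeric
vector, or a time/event pair for survival), ``p`` partially observed
covariates ``X`` and ``q`` fully observed covariates ``Z``.  Missingness is
tracked by an observation-indicator matrix ``R`` (1 = observed), derived from
the not-a-number entries of ``X``.

The substantive (analysis) model is described by a closed vocabulary of design
terms — :func:`linear`, :func:`power`, :func:`interaction` — so the linear
predictor g(X, Z, beta) can be re-evaluated for arbitrary candidate covariate
values inside the rejection sampler.  Derived terms (squares, interactions)
are always recomputed from the current covariate values; they are never stored
as independently imputed columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpecError",
    "Term",
    "linear",
    "power",
    "interaction",
    "SubstantiveModelSpec",
    "CovariateModelSpec",
    "PsiDraw",
    "PhiDraw",
    "ImputationProblem",
    "validate_problem",
    "visit_order",
    "read_dataset",
    "load_config",
]

FAMILIES = ("normal", "logistic", "poisson", "cox")
COVARIATE_FAMILIES = ("normal", "logistic")


class SpecError(ValueError):
    """Raised when a problem or model specification is inconsistent."""


# ---------------------------------------------------------------------------
# Design terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One column of the substantive model's design matrix.

    kind
        ``"linear"``, ``"power"`` or ``"interaction"``.
    """

    kind: str
    var: str
    k: int = 1
    var2: str | None = None

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.var
        if self.kind == "power":
            return f"{self.var}^{self.k}"
        return f"{self.var}:{self.var2}"

    def variables(self) -> tuple[str, ...]:
        if self.kind == "interaction":
            return (self.var, self.var2)
        return (self.var,)

    def values(self, data: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        x = np.asarray(data[self.var], dtype=float)
        if self.kind == "linear":
            return x
        if self.kind == "power":
            return x ** self.k
        if self.kind == "interaction":
            return x * np.asarray(data[self.var2], dtype=float)
        raise SpecError(f"unknown term kind {self.kind!r}")


def linear(var: str) -> Term:
    """Main effect of ``var``."""
    return Term("linear", var)


def power(var: str, k: int) -> Term:
    """``var`` raised to the integer power ``k`` (e.g. a squared term)."""
    if k < 1:
        raise SpecError("power term requires k >= 1")
    return Term("power", var, k=k)


def interaction(var1: str, var2: str) -> Term:
    """Product term ``var1 * var2``."""
    return Term("interaction", var1, var2=var2)


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstantiveModelSpec:
    """The analysis model f(Y | X, Z, psi).

    Parameters
    ----------
    family
        ``"normal"`` (linear regression), ``"logistic"``, ``"poisson"`` or
        ``"cox"`` (proportional hazards).
    terms
        Ordered design terms defining the linear predictor.  An intercept is
        included implicitly for every family except ``cox``.
    outcome
        Column name of Y (non-survival families).
    time, event
        Column names of the follow-up time W = min(T, C) and the event
        indicator D = 1(T < C) (cox family).
    """

    family: str
    terms: tuple[Term, ...]
    outcome: str | None = None
    time: str | None = None
    event: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.family == "cox":
            if self.time is None or self.event is None:
                raise SpecError("cox family requires time and event columns")
        elif self.outcome is None:
            raise SpecError(f"{self.family} family requires an outcome column")

    @property
    def has_intercept(self) -> bool:
        return self.family != "cox"

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def param_names(self) -> tuple[str, ...]:
        base = ("const",) if self.has_intercept else ()
        return base + self.term_names

    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for v in t.variables():
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def design_matrix(self, data: Mapping[str, np.ndarray] | pd.DataFrame,
                      intercept: bool | None = None) -> np.ndarray:
        """Evaluate the term columns (optionally prepending the intercept)."""
        cols = [t.values(data) for t in self.terms]
        n = len(cols[0])
        if intercept is None:
            intercept = self.has_intercept
        if intercept:
            cols.insert(0, np.ones(n))
        return np.column_stack(cols)

    def linear_predictor(self, data, beta: np.ndarray) -> np.ndarray:
        """g(X, Z, beta), including the intercept where the family has one."""
        return self.design_matrix(data) @ np.asarray(beta, dtype=float)


@dataclass(frozen=True)
class CovariateModelSpec:
    """Conditional model f(Xj | X_-j, Z, phi_j) for one partially observed
    covariate.

    All other partially observed covariates and all fully observed covariates
    enter linearly, plus an intercept.  ``family`` is ``"normal"`` (linear
    regression) or ``"logistic"`` (binary covariates only).
    """

    name: str
    family: str = "normal"

    def __post_init__(self):
        if self.family not in COVARIATE_FAMILIES:
            raise SpecError(f"unknown covariate family {self.family!r}")


@dataclass
class PsiDraw:
    """One draw of the substantive model parameter psi.

    beta is the coefficient vector (intercept first where applicable);
    sigma2_eps the residual variance (normal family); H0 the baseline
    cumulative hazard step function (cox family), nondecreasing with
    H0(0) = 0.
    """

    beta: np.ndarray
    sigma2_eps: float | None = None
    H0: object | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma2_eps is not None and not self.sigma2_eps > 0:
            raise SpecError("sigma2_eps must be positive")


@dataclass
class PhiDraw:
    """One draw of a covariate model parameter phi_j."""

    coef: np.ndarray
    sigma2: float | None = None
    family: str = "normal"

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.sigma2 is not None and not self.sigma2 > 0:
            raise SpecError("residual variance must be positive")


# ---------------------------------------------------------------------------
# Problem container
# ---------------------------------------------------------------------------

@dataclass
class ImputationProblem:
    """A dataset together with its covariate roles and missingness pattern.

    Attributes
    ----------
    data
        The full dataset (outcome, X and Z columns).
    x_cols
        Names of the p partially observed covariates (imputation targets).
    z_cols
        Names of the q fully observed covariates.
    R
        n x p boolean observation indicators; ``R[i, j]`` is False exactly
        when ``data[x_cols[j]][i]`` is missing.
    """

    data: pd.DataFrame
    x_cols: tuple[str, ...]
    z_cols: tuple[str, ...] = ()
    R: np.ndarray = field(default=None)

    def __post_init__(self):
        self.x_cols = tuple(self.x_cols)
        self.z_cols = tuple(self.z_cols)
        if self.R is None:
            self.R = ~self.data[list(self.x_cols)].isna().to_numpy()
        self.R = np.asarray(self.R, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.x_cols)

    def n_missing(self) -> np.ndarray:
        return (~self.R).sum(axis=0)


def validate_problem(
    data: pd.DataFrame,
    spec: SubstantiveModelSpec,
    cov_specs: Sequence[CovariateModelSpec],
    z_cols: Sequence[str] = (),
) -> ImputationProblem:
    """Check shapes and roles, derive R, and return the validated problem.

    Raises :class:`SpecError` when the outcome or a fully observed covariate
    contains missing values, when a covariate has zero observed values, when
    a term references an unknown variable, or when the covariate model list
    does not match the partially observed covariates.
    """
    x_cols = tuple(cs.name for cs in cov_specs)
    if len(set(x_cols)) != len(x_cols):
        raise SpecError("duplicate covariate model targets")
    if not x_cols:
        raise SpecError("at least one partially observed covariate required")
    if len(data) < 1:
        raise SpecError("empty dataset")

    outcome_cols = (spec.time, spec.event) if spec.family == "cox" else (spec.outcome,)
    for col in outcome_cols + tuple(z_cols):
        if col not in data.columns:
            raise SpecError(f"column {col!r} not in dataset")
        if data[col].isna().any():
            raise SpecError(
                f"fully observed variables required: {col!r} contains missing values"
            )
    if spec.family == "cox":
        d = data[spec.event].to_numpy()
        if not np.isin(d, (0, 1)).all():
            raise SpecError("event indicator must be 0/1")
        if (data[spec.time].to_numpy() < 0).any():
            raise SpecError("survival times must be nonnegative")

    known = set(x_cols) | set(z_cols)
    for t in spec.terms:
        for v in t.variables():
            if v not in known:
                raise SpecError(f"design term references unknown variable {v!r}")
    for col in x_cols:
        if col not in data.columns:
            raise SpecError(f"covariate {col!r} not in dataset")

    problem = ImputationProblem(data=data, x_cols=x_cols, z_cols=tuple(z_cols))
    if (problem.R.sum(axis=0) == 0).any():
        bad = [c for c, k in zip(x_cols, problem.R.sum(axis=0)) if k == 0]
        raise SpecError(f"covariate(s) with zero observed values: {bad}")

    for cs in cov_specs:
        if cs.family == "logistic":
            vals = data[cs.name].dropna().unique()
            if not np.isin(vals, (0, 1)).all():
                raise SpecError(
                    f"logistic covariate model for non-binary target {cs.name!r}"
                )
    return problem


def visit_order(R: np.ndarray) -> np.ndarray:
    """Covariate update order: ascending count of missing values.

    A deterministic proxy for the "closest to monotone" ordering used by FCS
    software; ties are broken by column index (stable sort).
    """
    R = np.asarray(R, dtype=bool)
    missing = (~R).sum(axis=0)
    return np.argsort(missing, kind="stable")


# ---------------------------------------------------------------------------
# External interfaces: CSV dataset + YAML/JSON model config
# ---------------------------------------------------------------------------

def read_dataset(path) -> pd.DataFrame:
    """Read a delimited-text dataset; empty fields and ``NA`` are missing."""
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)


def _parse_term(entry) -> Term:
    if isinstance(entry, str):
        return linear(entry)
    kind = entry.get("type", "linear")
    if kind == "linear":
        return linear(entry["var"])
    if kind == "power":
        return power(entry["var"], int(entry["k"]))
    if kind == "interaction":
        return interaction(entry["var1"], entry["var2"])
    raise SpecError(f"unknown term type {kind!r}")


def load_config(path) -> tuple[SubstantiveModelSpec, list[CovariateModelSpec], tuple[str, ...]]:
    """Load a model configuration (YAML, which subsumes JSON).

    Expected layout::

        substantive:
          family: normal            # normal | logistic | poisson | cox
          outcome: y                # or time: w / event: d for cox
          terms:
            - x                     # shorthand for a linear term
            - {type: power, var: x, k: 2}
            - {type: interaction, var1: x1, var2: x2}
        covariates:
          - {name: x, family: normal}
        fully_observed: [z1, z2]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sub = cfg["substantive"]
    spec = SubstantiveModelSpec(
        family=sub["family"],
        terms=tuple(_parse_term(t) for t in sub["terms"]),
        outcome=sub.get("outcome"),
        time=sub.get("time"),
        event=sub.get("event"),
    )
    cov_specs = [
        CovariateModelSpec(name=c["name"], family=c.get("family", "normal"))
        for c in cfg.get("covariates", [])
    ]
    z_cols = tuple(cfg.get("fully_observed", ()) or ())
    return spec, cov_specs, z_cols
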