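"""Per-imputation model fits and Rubin's-rules pooling.

The substantive model is fitted by maximum likelihood to each completed
dataset; the M estimates and their model-based variances are then combined:
pooled estimate = mean of the per-imputation estimates, total variance =
within-imputation mean + (1 + 1/M) x between-imputation sample variance, and
degrees of freedom by the classical Rubin rule
nu = (M - 1)(1 + W / ((1 + 1/M) B))^2.  When the between variance is zero the
degrees of freedom are infinite and the interval is normal-based.  The
small-sample Barnard-Rubin adjustment is available behind a flag (off by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .data_model import SubstantiveModelSpec

__all__ = ["PooledResult", "pool", "fit_substantive", "pool_fits"]


@dataclass
class PooledResult:
    """Rubin's-rules summary for the substantive model parameters."""

    estimate: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total_variance: np.ndarray
    df: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    m: int
    names: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total_variance)

    def to_frame(self) -> pd.DataFrame:
        names = self.names or tuple(f"b{i}" for i in range(self.estimate.size))
        return pd.DataFrame(
            {
                "estimate": self.estimate,
                "se": self.se,
                "df": self.df,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=list(names),
        )


def pool(
    estimates,
    variances,
    level: float = 0.95,
    names: Sequence[str] = (),
    small_sample: bool = False,
    df_complete: float | None = None,
) -> PooledResult:
    """Combine M per-imputation estimates and variances by Rubin's rules.

    ``estimates`` and ``variances`` are (M, k) arrays (or (M,) for scalar
    parameters).  ``small_sample=True`` applies the Barnard-Rubin adjusted
    degrees of freedom, which requires ``df_complete`` (the complete-data
    residual degrees of freedom).
    """
    q = np.atleast_2d(np.asarray(estimates, dtype=float))
    u = np.atleast_2d(np.asarray(variances, dtype=float))
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have matching shapes")
    m = q.shape[0]
    if m < 2:
        raise ValueError("pooling requires M >= 2 imputations")

    qbar = q.mean(axis=0)
    wbar = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    total = wbar + (1.0 + 1.0 / m) * b

    with np.errstate(divide="ignore"):
        r = (1.0 + 1.0 / m) * b / wbar
        df = np.where(b > 0, (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, 1.0)) ** 2, np.inf)
    if small_sample:
        if df_complete is None:
            raise ValueError("small_sample pooling requires df_complete")
        lam = (1.0 + 1.0 / m) * b / total
        df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
        df = np.where(np.isinf(df), df_obs, 1.0 / (1.0 / df + 1.0 / df_obs))

    alpha = 1.0 - level
    crit = np.where(
        np.isinf(df), stats.norm.ppf(1.0 - alpha / 2.0), stats.t.ppf(1.0 - alpha / 2.0, np.where(np.isinf(df), 1.0, df))
    )
    half = crit * np.sqrt(total)
    return PooledResult(
        estimate=qbar,
        within=wbar,
        between=b,
        total_variance=total,
        df=df,
        ci_lower=qbar - half,
        ci_upper=qbar + half,
        level=level,
        m=m,
        names=tuple(names),
    )


def fit_substantive(data: pd.DataFrame, spec: SubstantiveModelSpec):
    """Maximum-likelihood fit of the substantive model to complete data.

    Returns ``(estimates, variances, names)`` with model-based variances
    (squared standard errors).  Derived design terms are recomputed from the
    current covariate values.
    """
    D = spec.design_matrix(data)
    names = spec.param_names
    if spec.family == "normal":
        res = sm.OLS(np.asarray(data[spec.outcome], dtype=float), D).fit()
        return np.asarray(res.params), np.asarray(res.bse) ** 2, names
    if spec.family in ("logistic", "poisson"):
        fam = sm.families.Binomial() if spec.family == "logistic" else sm.families.Poisson()
        res = sm.GLM(np.asarray(data[spec.outcome], dtype=float), D, family=fam).fit(maxiter=100)
        if not res.converged:
            raise RuntimeError(f"{spec.family} substantive model did not converge")
        return np.asarray(res.params), np.asarray(res.bse) ** 2, names
    if spec.family == "cox":
        df = pd.DataFrame(D, columns=list(names))
        df["_time"] = np.asarray(data[spec.time], dtype=float)
        df["_event"] = np.asarray(data[spec.event], dtype=float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        est = cph.params_.reindex(list(names)).to_numpy()
        var = (cph.standard_errors_.reindex(list(names)).to_numpy()) ** 2
        return est, var, names
    raise ValueError(f"unknown family {spec.family!r}")


def pool_fits(datasets, spec: SubstantiveModelSpec, level: float = 0.95,
              small_sample: bool = False) -> PooledResult:
    """Fit the substantive model to each imputed dataset and pool."""
    ests, variances, names = [], [], None
    for i, d in enumerate(datasets):
        try:
            e, v, names = fit_substantive(d, spec)
        except Exception as exc:
            raise RuntimeError(f"substantive fit failed for imputation {i + 1}: {exc}") from exc
        ests.append(e)
        variances.append(v)
    df_complete = None
    if small_sample:
        df_complete = len(datasets[0]) - len(names)
    return pool(np.array(ests), np.array(variances), level=level, names=names,
                small_sample=small_sample, df_complete=df_complete)
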