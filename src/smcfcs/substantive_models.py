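"""Substantive-model posteriors and rejection-sampling acceptance kernels.

For each supported family this module draws psi from its (approximate)
posterior given completed data and evaluates the acceptance probability
f(Y | Xj*, X_-j, Z, psi) / c(Y, X_-j, Z, psi), where c is an upper bound in
Xj, so that accepted proposals from the covariate conditional are draws from
the density proportional to f(Y | X, Z, psi) f(Xj | X_-j, Z, phi_j):

- normal:   exp(-(Y - g)^2 / (2 sigma_eps^2))            (bound 1/sqrt(2 pi sigma^2))
- discrete: the model probability of the observed Y      (bound 1)
- cox, censored:  exp(-H0(W) e^g)                        (bound: survivor <= 1)
- cox, event:     H0(W) exp(1 + g - H0(W) e^g)           (maximised, at 1,
                  exactly when H0(W) e^g = 1)

The Cox posterior draws beta from a normal approximation at the partial
likelihood estimate and plugs in the Breslow baseline cumulative hazard
evaluated at the drawn beta; uncertainty in H0 is deliberately ignored (a
known limitation of the approach, which simulation nonetheless shows yields
close-to-nominal interval coverage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import poisson as poisson_dist

from .covariate_models import SeparationError, bayes_linear_draw
from .data_model import PsiDraw, SubstantiveModelSpec

__all__ = [
    "StepFunction",
    "breslow_cumhaz",
    "cox_partial_fit",
    "draw_psi",
    "AcceptanceKernel",
    "acceptance_probability",
]


class StepFunction:
    """Right-continuous nondecreasing step function on [0, inf) with value 0
    before the first jump (so H0(0) = 0 when all jump times are positive)."""

    def __init__(self, times, values):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.zeros(t.shape)
            return out if out.ndim else 0.0
        idx = np.searchsorted(self.times, t, side="right")
        out = np.where(idx > 0, self.values[np.maximum(idx - 1, 0)], 0.0)
        return out if out.ndim else float(out)


def breslow_cumhaz(times, events, linpred) -> StepFunction:
    """Breslow estimator of the baseline cumulative hazard.

    H0(t) = sum_{event times t_k <= t} d_k / sum_{i: W_i >= t_k} exp(g_i),
    with tied events at t_k sharing the single risk-set denominator d_k.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    g = np.asarray(linpred, dtype=float)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    d_sorted = events[order].astype(bool)
    eg_sorted = np.exp(g[order])
    # risk set at t = subjects with W >= t: suffix sums of exp(g)
    suffix = np.cumsum(eg_sorted[::-1])[::-1]
    event_times, first_idx, counts = np.unique(
        t_sorted[d_sorted], return_index=True, return_counts=True
    )
    if event_times.size == 0:
        return StepFunction(np.empty(0), np.empty(0))
    # denominator for each unique event time: suffix sum at the first subject
    # with W >= that time
    pos = np.searchsorted(t_sorted, event_times, side="left")
    denom = suffix[pos]
    jumps = counts / denom
    return StepFunction(event_times, np.cumsum(jumps))


def cox_partial_fit(times, events, X, tol: float = 1e-9, max_iter: int = 50):
    """Newton-Raphson maximiser of the Cox partial likelihood (Breslow ties).

    Returns ``(beta_hat, cov)`` with ``cov`` the inverse observed information.
    Written for the many small repeated fits inside the chained sampler,
    where a vectorised ndarray solver is needed; validated against lifelines.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if d.sum() == 0:
        raise ValueError("Cox model requires at least one event")
    order = np.argsort(times, kind="stable")
    t_s, d_s, X_s = times[order], d[order], X[order]
    ev_times, ev_start, ev_counts = np.unique(
        t_s[d_s], return_index=True, return_counts=True
    )
    risk_pos = np.searchsorted(t_s, ev_times, side="left")
    # sum of X over events at each unique event time
    X_events = X_s[d_s]
    ev_groups = np.repeat(np.arange(ev_times.size), ev_counts)
    sum_x_events = np.zeros((ev_times.size, k))
    np.add.at(sum_x_events, ev_groups, X_events)

    beta = np.zeros(k)
    for _ in range(max_iter):
        eg = np.exp(X_s @ beta)
        s0 = np.cumsum(eg[::-1])[::-1]
        s1 = np.cumsum((X_s * eg[:, None])[::-1], axis=0)[::-1]
        xx = X_s[:, :, None] * X_s[:, None, :] * eg[:, None, None]
        s2 = np.cumsum(xx[::-1], axis=0)[::-1]
        S0 = s0[risk_pos]
        S1 = s1[risk_pos]
        S2 = s2[risk_pos]
        xbar = S1 / S0[:, None]
        U = (sum_x_events - ev_counts[:, None] * xbar).sum(axis=0)
        I = (
            ev_counts[:, None, None]
            * (S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
        ).sum(axis=0)
        step = np.linalg.solve(I, U)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    else:
        raise RuntimeError("Cox partial likelihood fit did not converge")
    eg = np.exp(X_s @ beta)
    s0 = np.cumsum(eg[::-1])[::-1]
    s1 = np.cumsum((X_s * eg[:, None])[::-1], axis=0)[::-1]
    xx = X_s[:, :, None] * X_s[:, None, :] * eg[:, None, None]
    s2 = np.cumsum(xx[::-1], axis=0)[::-1]
    S0, S1, S2 = s0[risk_pos], s1[risk_pos], s2[risk_pos]
    xbar = S1 / S0[:, None]
    I = (
        ev_counts[:, None, None]
        * (S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
    ).sum(axis=0)
    return beta, np.linalg.inv(I)


def draw_psi(data, spec: SubstantiveModelSpec, rng) -> PsiDraw:
    """Draw psi from its (approximate) posterior given completed data.

    normal: proper Bayesian draw under the Jeffreys prior; logistic/poisson:
    multivariate normal at the MLE with inverse observed information; cox:
    multivariate normal at the partial-likelihood estimate, then the Breslow
    baseline cumulative hazard evaluated at the drawn beta.
    """
    D = spec.design_matrix(data)
    if spec.family == "normal":
        y = np.asarray(data[spec.outcome], dtype=float)
        beta, sigma2 = bayes_linear_draw(y, D, rng)
        return PsiDraw(beta=beta, sigma2_eps=sigma2)
    if spec.family in ("logistic", "poisson"):
        y = np.asarray(data[spec.outcome], dtype=float)
        fam = sm.families.Binomial() if spec.family == "logistic" else sm.families.Poisson()
        res = sm.GLM(y, D, family=fam).fit(maxiter=100)
        if not res.converged:
            raise SeparationError(f"{spec.family} substantive model did not converge")
        beta = rng.multivariate_normal(
            np.asarray(res.params), np.asarray(res.cov_params()), method="cholesky"
        )
        return PsiDraw(beta=beta)
    # cox
    w = np.asarray(data[spec.time], dtype=float)
    d = np.asarray(data[spec.event], dtype=float)
    bhat, cov = cox_partial_fit(w, d, D)
    beta = rng.multivariate_normal(bhat, cov, method="cholesky")
    H0 = breslow_cumhaz(w, d, D @ beta)
    return PsiDraw(beta=beta, H0=H0)


@dataclass
class AcceptanceKernel:
    """Per-subject rejection-sampling acceptance probabilities.

    Holds the outcome records of the subjects being imputed and the current
    psi draw; :meth:`probability` maps candidate linear-predictor values g to
    acceptance probabilities in [0, 1].
    """

    family: str
    psi: PsiDraw
    y: np.ndarray | None = None       # outcome (non-survival families)
    time: np.ndarray | None = None    # W (cox)
    event: np.ndarray | None = None   # D (cox)

    def __post_init__(self):
        if self.family == "cox":
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=bool)
            self._H0W = np.asarray(self.psi.H0(self.time), dtype=float)
        else:
            self.y = np.asarray(self.y, dtype=float)

    def probability(self, g, idx=None) -> np.ndarray:
        """Acceptance probability for candidates with linear predictor ``g``.

        ``idx`` selects a subset of the stored subjects (defaults to all,
        matched elementwise to ``g``).
        """
        g = np.asarray(g, dtype=float)
        if self.family == "normal":
            y = self.y if idx is None else self.y[idx]
            return np.exp(-((y - g) ** 2) / (2.0 * self.psi.sigma2_eps))
        if self.family == "logistic":
            y = self.y if idx is None else self.y[idx]
            p = expit(g)
            return np.where(y == 1, p, 1.0 - p)
        if self.family == "poisson":
            y = self.y if idx is None else self.y[idx]
            return poisson_dist.pmf(y, np.exp(g))
        # cox
        h0w = self._H0W if idx is None else self._H0W[idx]
        d = self.event if idx is None else self.event[idx]
        lam = h0w * np.exp(g)
        prob = np.where(d, h0w * np.exp(1.0 + g - lam), np.exp(-lam))
        # an uncensored subject whose time precedes every current event time
        # has H0(W) = 0: no candidate can be accepted (handled by fallback)
        return np.clip(prob, 0.0, 1.0)


def acceptance_probability(kernel: AcceptanceKernel, g) -> np.ndarray:
    """Functional wrapper around :meth:`AcceptanceKernel.probability`."""
    return kernel.probability(g)
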