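"""Conditional covariate models f(Xj | X_-j, Z, phi_j).

Each partially observed covariate gets a normal-linear or logistic conditional
model fit to the currently completed data.  Parameter draws are proper
Bayesian for the linear case (Jeffreys prior f(beta, sigma^2) proportional to
1/sigma^2, i.e. sigma^2 from its scaled inverse-chi-square posterior, then
beta from the conditional multivariate normal) and a normal approximation
centred at the maximum-likelihood estimate with the inverse observed
information as covariance for the logistic case.  The fitted conditional is
also the proposal density of the rejection sampler.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data_model import PhiDraw

__all__ = [
    "CollinearityError",
    "SeparationError",
    "bayes_linear_draw",
    "draw_linear_phi",
    "draw_logistic_phi",
    "sample_proposal",
]


class CollinearityError(RuntimeError):
    """Design matrix is rank deficient ("collinear predictors")."""


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


def bayes_linear_draw(y, X, rng) -> tuple[np.ndarray, float]:
    """One posterior draw of (beta, sigma^2) for a normal linear model under
    the noninformative prior f(beta, sigma^2) ∝ 1/sigma^2.

    sigma^2 ~ RSS / chi^2_{n-k}; beta | sigma^2 ~ N(beta_hat, sigma^2 (X'X)^-1).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise CollinearityError("fewer observations than parameters")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise CollinearityError("collinear predictors")
    bhat = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ bhat
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / rng.chisquare(df) if rss > 0 else 0.0
    if sigma2 > 0:
        # beta = bhat + sigma * R^-1 z  since (X'X)^-1 = R^-1 R^-T
        z = rng.standard_normal(k)
        beta = bhat + np.sqrt(sigma2) * np.linalg.solve(R, z)
    else:
        beta = bhat
        sigma2 = np.finfo(float).tiny  # degenerate: keep positivity contract
    return beta, sigma2


def draw_linear_phi(y, X, rng) -> PhiDraw:
    """Draw phi_j for a normal-linear covariate model fit to (y, X).

    ``X`` must already include the intercept column.
    """
    coef, sigma2 = bayes_linear_draw(y, X, rng)
    return PhiDraw(coef=coef, sigma2=sigma2, family="normal")


def draw_logistic_phi(y, X, rng, ridge: float = 0.0, name: str = "") -> PhiDraw:
    """Draw phi_j for a logistic covariate model.

    The draw is multivariate normal centred at the MLE with covariance equal
    to the inverse observed information.  Separation or non-convergence
    raises :class:`SeparationError`; ``ridge`` > 0 adds a small L2 penalty as
    an opt-in rescue for separated fits.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.min() == y.max():
        raise SeparationError(f"covariate {name or 'target'!r} has a single class")
    try:
        if ridge > 0:
            res = sm.Logit(y, X).fit_regularized(
                alpha=ridge, L1_wt=0.0, disp=0, maxiter=200
            )
            mle = np.asarray(res.params, dtype=float)
            cov = np.linalg.inv(_logistic_information(mle, X) + ridge * np.eye(X.shape[1]))
        else:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", False):
                raise SeparationError(
                    f"logistic model for covariate {name or 'target'!r} did not converge"
                )
            mle = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"separation in logistic model for covariate {name or 'target'!r}"
        ) from exc
    if np.abs(mle).max() > 30:
        raise SeparationError(
            f"separation suspected in logistic model for covariate {name or 'target'!r}"
        )
    coef = rng.multivariate_normal(mle, cov, method="cholesky")
    return PhiDraw(coef=coef, family="logistic")


def _logistic_information(beta, X):
    p = expit(X @ beta)
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def sample_proposal(phi: PhiDraw, design: np.ndarray, rng) -> np.ndarray:
    """Sample candidate covariate values from the fitted conditional.

    ``design`` is the predictor matrix (intercept included) for the subjects
    being imputed; returns one candidate per row.  Normal-linear: N(eta,
    sigma^2); logistic: Bernoulli(expit(eta)).
    """
    eta = np.asarray(design, dtype=float) @ phi.coef
    if phi.family == "normal":
        return eta + np.sqrt(phi.sigma2) * rng.standard_normal(eta.shape)
    return (rng.random(eta.shape) < expit(eta)).astype(float)
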