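"""Substantive-model posterior draws, the Breslow estimator and the
rejection-sampling acceptance kernels.

Oracles: brute-force risk-set loops for the Breslow estimator, lifelines for
the Cox partial-likelihood fit, grid search for the event-kernel maximiser,
and randomized draws for the upper-bound property of every kernel.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smcfcs.data_model import PsiDraw, SubstantiveModelSpec, linear
from smcfcs.substantive_models import (
    AcceptanceKernel,
    StepFunction,
    acceptance_probability,
    breslow_cumhaz,
    cox_partial_fit,
    draw_psi,
)


def brute_force_breslow(times, events, g, t_eval):
    """Oracle: double loop over event times and risk sets."""
    total = 0.0
    for tk in sorted(set(times[events.astype(bool)])):
        if tk > t_eval:
            continue
        d_k = np.sum((times == tk) & events.astype(bool))
        denom = np.sum(np.exp(g[times >= tk]))
        total += d_k / denom
    return total


@pytest.fixture
def survival_fixture(rng):
    n = 10
    times = np.round(rng.exponential(5.0, n), 1)
    times[3] = times[7]  # force a tie
    events = (rng.random(n) < 0.7).astype(float)
    events[[3, 7]] = 1.0
    g = rng.normal(0, 0.5, n)
    return times, events, g


class TestBreslow:
    def test_no_events_identically_zero(self):
        H = breslow_cumhaz(np.array([1.0, 2.0]), np.array([0, 0]), np.zeros(2))
        assert H(0.0) == 0.0 and H(100.0) == 0.0

    def test_single_earliest_event_jumps_one_over_n(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 0, 0, 0, 0])
        H = breslow_cumhaz(times, events, np.zeros(5))
        assert H(0.5) == 0.0
        assert H(1.0) == pytest.approx(1 / 5)
        assert H(10.0) == pytest.approx(1 / 5)

    def test_matches_brute_force_with_ties(self, survival_fixture):
        times, events, g = survival_fixture
        H = breslow_cumhaz(times, events, g)
        for t_eval in np.concatenate([times, [0.0, times.max() + 1]]):
            assert H(t_eval) == pytest.approx(
                brute_force_breslow(times, events, g, t_eval)
            )

    def test_h0_at_zero_is_zero_and_nondecreasing(self, survival_fixture):
        times, events, g = survival_fixture
        H = breslow_cumhaz(times, events, g)
        grid = np.linspace(0, times.max() + 1, 200)
        vals = H(grid)
        assert H(0.0) == 0.0
        assert (np.diff(vals) >= 0).all()


class TestCoxFit:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.8 * x1 - 0.5 * x2)))
        c = rng.exponential(10.0, n)
        w = np.minimum(t, c)
        d = (t < c).astype(float)
        beta, cov = cox_partial_fit(w, d, np.column_stack([x1, x2]))
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"x1": x1, "x2": x2, "w": w, "d": d}),
                duration_col="w", event_col="d")
        np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=2e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(cov)), cph.standard_errors_.to_numpy(), rtol=0.02
        )

    def test_zero_events_raises(self):
        with pytest.raises(ValueError, match="at least one event"):
            cox_partial_fit(np.array([1.0, 2.0]), np.array([0, 0]),
                            np.zeros((2, 1)))


class TestDrawPsi:
    def test_noiseless_normal_recovers_coefficients(self, rng, quadratic_spec):
        x = rng.normal(2, 1, 80)
        data = pd.DataFrame({"x": x, "y": 4 - 4 * x + x**2})
        psi = draw_psi(data, quadratic_spec, rng)
        np.testing.assert_allclose(psi.beta, [4.0, -4.0, 1.0], atol=1e-6)

    def test_reproducible_given_seed(self, quadratic_spec):
        r = np.random.default_rng(3)
        x = r.normal(2, 1, 60)
        data = pd.DataFrame({"x": x, "y": 4 - 4 * x + x**2 + r.normal(size=60)})
        p1 = draw_psi(data, quadratic_spec, np.random.default_rng(11))
        p2 = draw_psi(data, quadratic_spec, np.random.default_rng(11))
        np.testing.assert_array_equal(p1.beta, p2.beta)
        assert p1.sigma2_eps == p2.sigma2_eps

    def test_cox_draw_mean_matches_partial_likelihood_mle(self, rng):
        spec = SubstantiveModelSpec(family="cox", time="w", event="d",
                                    terms=(linear("x"),))
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        c = rng.exponential(30.0, n)
        data = pd.DataFrame({"x": x, "w": np.minimum(t, c),
                             "d": (t < c).astype(float)})
        bhat, cov = cox_partial_fit(
            data["w"].to_numpy(), data["d"].to_numpy(), x[:, None]
        )  # oracle centre
        draws = np.array([draw_psi(data, spec, rng).beta[0] for _ in range(2000)])
        se = np.sqrt(cov[0, 0])
        assert abs(draws.mean() - bhat[0]) < 3 * se / np.sqrt(2000) * 1.5 + 1e-3
        assert abs(draws.std() - se) / se < 0.1

    def test_cox_zero_events_errors(self):
        spec = SubstantiveModelSpec(family="cox", time="w", event="d",
                                    terms=(linear("x"),))
        data = pd.DataFrame({"x": [0.1, 0.2], "w": [1.0, 2.0], "d": [0.0, 0.0]})
        with pytest.raises(ValueError):
            draw_psi(data, spec, np.random.default_rng(0))


class TestAcceptanceKernels:
    def test_normal_outcome_equal_to_mean_accepts_surely(self):
        psi = PsiDraw(beta=np.array([0.0]), sigma2_eps=1.0)
        k = AcceptanceKernel("normal", psi, y=np.array([2.5]))
        assert acceptance_probability(k, np.array([2.5]))[0] == pytest.approx(1.0)

    def test_normal_half_probability_identity(self):
        # (Y - g)^2 = 2 sigma^2 ln 2  =>  acceptance exactly 1/2
        s2 = 0.7
        psi = PsiDraw(beta=np.array([0.0]), sigma2_eps=s2)
        y = np.array([0.0])
        g = np.array([np.sqrt(2 * s2 * np.log(2))])
        k = AcceptanceKernel("normal", psi, y=y)
        assert k.probability(g)[0] == pytest.approx(0.5)

    def test_cox_censored_before_first_event_accepts_surely(self):
        H0 = StepFunction(np.array([5.0]), np.array([0.3]))
        psi = PsiDraw(beta=np.array([1.0]), H0=H0)
        k = AcceptanceKernel("cox", psi, time=np.array([1.0]), event=np.array([0.0]))
        assert k.probability(np.array([3.0]))[0] == pytest.approx(1.0)

    def test_cox_event_kernel_maximised_at_unit_cumulative_intensity(self):
        # H0(W) e^g = 1 is the maximiser of the event kernel and attains 1
        H0 = StepFunction(np.array([1.0]), np.array([0.25]))
        psi = PsiDraw(beta=np.array([1.0]), H0=H0)
        k = AcceptanceKernel("cox", psi, time=np.array([2.0]), event=np.array([1.0]))
        g_star = -np.log(0.25)
        assert k.probability(np.array([g_star]))[0] == pytest.approx(1.0)
        grid = np.linspace(g_star - 6, g_star + 6, 5001)
        probs = k.probability(grid, idx=np.zeros(grid.size, dtype=int))
        assert probs.max() == pytest.approx(1.0, abs=1e-6)
        assert abs(grid[probs.argmax()] - g_star) < 0.01

    def test_cox_event_with_zero_baseline_hazard_rejects_surely(self):
        H0 = StepFunction(np.array([5.0]), np.array([0.3]))
        psi = PsiDraw(beta=np.array([1.0]), H0=H0)
        k = AcceptanceKernel("cox", psi, time=np.array([1.0]), event=np.array([1.0]))
        assert k.probability(np.array([0.0]))[0] == 0.0

    def test_logistic_kernel_is_model_probability(self):
        psi = PsiDraw(beta=np.array([0.0]))
        k = AcceptanceKernel("logistic", psi, y=np.array([1.0, 0.0]))
        g = np.array([0.0, 2.0])
        from scipy.special import expit

        np.testing.assert_allclose(k.probability(g), [0.5, 1 - expit(2.0)])

    def test_kernels_bounded_by_one_randomised(self, rng):
        """All acceptance kernels stay in [0, 1] over 10^6 randomized
        (family, psi, candidate) draws — the upper-bound property that makes
        rejection sampling valid."""
        n = 250_000
        # normal
        psi = PsiDraw(beta=np.array([0.0]), sigma2_eps=float(rng.uniform(0.05, 5)))
        k = AcceptanceKernel("normal", psi, y=rng.normal(0, 10, n))
        p = k.probability(rng.normal(0, 10, n))
        assert ((p >= 0) & (p <= 1)).all()
        # logistic
        k = AcceptanceKernel("logistic", PsiDraw(beta=np.array([0.0])),
                             y=(rng.random(n) < 0.5).astype(float))
        p = k.probability(rng.normal(0, 10, n))
        assert ((p >= 0) & (p <= 1)).all()
        # poisson
        k = AcceptanceKernel("poisson", PsiDraw(beta=np.array([0.0])),
                             y=rng.poisson(3.0, n).astype(float))
        p = k.probability(rng.normal(0, 2, n))
        assert ((p >= 0) & (p <= 1)).all()
        # cox (events and censorings, random baseline hazard)
        H0 = StepFunction(np.sort(rng.uniform(0, 10, 20)),
                          np.sort(rng.exponential(0.5, 20)).cumsum())
        psi = PsiDraw(beta=np.array([1.0]), H0=H0)
        k = AcceptanceKernel("cox", psi, time=rng.uniform(0, 12, n),
                             event=(rng.random(n) < 0.5).astype(float))
        p = k.probability(rng.normal(0, 3, n))
        assert ((p >= 0) & (p <= 1)).all()

    @given(
        y=st.floats(-50, 50),
        g=st.floats(-50, 50),
        s2=st.floats(0.01, 25),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normal_kernel_bounded_property(self, y, g, s2):
        psi = PsiDraw(beta=np.array([0.0]), sigma2_eps=s2)
        k = AcceptanceKernel("normal", psi, y=np.array([y]))
        p = k.probability(np.array([g]))[0]
        assert 0.0 <= p <= 1.0
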