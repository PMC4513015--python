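"""The SMC-FCS chained sampler.

The headline oracle: with a substantive model linear in a single normal
covariate and a normal covariate model, imputation from the compatible joint
model is imputation from a bivariate normal, so the imputed values must
follow the closed-form conditional f(X | Y) (complete-the-squares oracle).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smcfcs.data_model import (
    CovariateModelSpec,
    SubstantiveModelSpec,
    linear,
    validate_problem,
)
from smcfcs.engine import SMCFCSImputer, impute, initialize_fill, run_chain

from conftest import make_missing_frame


class TestInitializeFill:
    def test_single_observed_value_fills_everywhere(self, quadratic_spec,
                                                    quadratic_cov_specs):
        df = make_missing_frame(n=8, seed=0, frac=0.0)
        df.loc[1:, "x"] = np.nan
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        filled = initialize_fill(prob, np.random.default_rng(0))
        assert (filled["x"] == df.loc[0, "x"]).all()

    def test_no_missing_is_identity(self, quadratic_spec, quadratic_cov_specs):
        df = make_missing_frame(n=8, seed=1, frac=0.0)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        filled = initialize_fill(prob, np.random.default_rng(0))
        pd.testing.assert_frame_equal(filled, df)

    def test_fill_resamples_observed_marginal(self, quadratic_spec,
                                              quadratic_cov_specs):
        df = make_missing_frame(n=6, seed=2, frac=0.0)
        df.loc[[4, 5], "x"] = np.nan
        observed = df["x"].dropna().to_numpy()
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        rng = np.random.default_rng(5)
        fills = np.array(
            [initialize_fill(prob, rng).loc[[4, 5], "x"].to_numpy()
             for _ in range(1000)]
        ).ravel()
        # every fill is one of the observed values, frequencies ~ uniform
        assert np.isin(fills, observed).all()
        freqs = np.array([(fills == v).mean() for v in observed])
        assert np.abs(freqs - 1 / observed.size).max() < 4 * np.sqrt(
            (1 / observed.size) * (1 - 1 / observed.size) / fills.size
        )


class TestRunChain:
    def test_no_missing_values_passthrough(self, quadratic_spec,
                                           quadratic_cov_specs):
        df = make_missing_frame(n=50, seed=3, frac=0.0)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        out, trace, att, nfb = run_chain(
            prob, quadratic_spec, quadratic_cov_specs, 3,
            np.random.default_rng(0),
        )
        pd.testing.assert_frame_equal(out, df)
        assert att == 0 and nfb == 0

    def test_fixed_seed_reproducible(self, quadratic_spec, quadratic_cov_specs):
        df = make_missing_frame(n=60, seed=4, frac=0.3)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        out1, *_ = run_chain(prob, quadratic_spec, quadratic_cov_specs, 4,
                             np.random.default_rng(123))
        out2, *_ = run_chain(prob, quadratic_spec, quadratic_cov_specs, 4,
                             np.random.default_rng(123))
        pd.testing.assert_frame_equal(out1, out2)

    def test_observed_entries_never_change(self, quadratic_spec,
                                           quadratic_cov_specs):
        df = make_missing_frame(n=80, seed=5, frac=0.4)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        out, *_ = run_chain(prob, quadratic_spec, quadratic_cov_specs, 3,
                            np.random.default_rng(9))
        obs = prob.R[:, 0]
        np.testing.assert_array_equal(
            out["x"].to_numpy()[obs], df["x"].to_numpy()[obs]
        )
        assert not out["x"].isna().any()

    def test_error_annotated_with_iteration_and_covariate(self):
        # constant covariate + intercept in the covariate model of a second
        # target produces collinearity; the error must name the covariate
        r = np.random.default_rng(0)
        n = 30
        x1 = r.normal(size=n)
        x2 = np.ones(n)  # constant: collinear with the intercept
        y = x1 + r.normal(size=n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        df.loc[:5, "x1"] = np.nan
        df.loc[6:8, "x2"] = np.nan
        spec = SubstantiveModelSpec(family="normal", outcome="y",
                                    terms=(linear("x1"), linear("x2")))
        cov = [CovariateModelSpec("x1"), CovariateModelSpec("x2")]
        prob = validate_problem(df, spec, cov)
        with pytest.raises(Exception, match=r"iteration 1, covariate"):
            run_chain(prob, spec, cov, 2, np.random.default_rng(0))


class TestImpute:
    def test_m_datasets_differ_only_in_imputed_entries(self, quadratic_spec,
                                                       quadratic_cov_specs):
        df = make_missing_frame(n=60, seed=6, frac=0.3)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        res = impute(prob, quadratic_spec, quadratic_cov_specs, m=2, n_iter=2,
                     seed=1)
        a, b = res.datasets
        obs = prob.R[:, 0]
        np.testing.assert_array_equal(a["x"].to_numpy()[obs],
                                      b["x"].to_numpy()[obs])
        assert (a["x"].to_numpy()[~obs] != b["x"].to_numpy()[~obs]).any()
        pd.testing.assert_series_equal(a["y"], b["y"])

    def test_defaults_are_ten_imputations_ten_iterations(self, quadratic_spec,
                                                         quadratic_cov_specs):
        df = make_missing_frame(n=40, seed=7, frac=0.2)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        res = impute(prob, quadratic_spec, quadratic_cov_specs, seed=2)
        assert res.M == 10
        assert res.trace.shape == (10, 10, 1)

    def test_m_below_two_rejected(self, quadratic_spec, quadratic_cov_specs):
        df = make_missing_frame(n=40, seed=8, frac=0.2)
        prob = validate_problem(df, quadratic_spec, quadratic_cov_specs)
        with pytest.raises(ValueError, match="m must be"):
            impute(prob, quadratic_spec, quadratic_cov_specs, m=1)

    def test_estimator_wrapper_exposes_fitted_attributes(self, quadratic_spec,
                                                         quadratic_cov_specs):
        df = make_missing_frame(n=40, seed=9, frac=0.2)
        est = SMCFCSImputer(substantive=quadratic_spec,
                            covariates=tuple(quadratic_cov_specs),
                            m=2, n_iter=2, random_state=3)
        est.fit(df)
        assert len(est.datasets_) == 2
        assert est.trace_.shape == (2, 2, 1)
        params = est.get_params()
        assert params["m"] == 2 and params["random_state"] == 3


class TestBivariateNormalOracle:
    def test_imputations_match_closed_form_conditional(self):
        """p = 1, substantive model linear in X, normal covariate model:
        the imputed X must follow the bivariate-normal conditional
        X | Y ~ N(mu_x + rho (sx/sy)(y - mu_y), sx^2 (1 - rho^2)).

        The probability-integral transform of the imputed values under the
        true conditional is compared with the uniform by KS distance."""
        r = np.random.default_rng(2024)
        n = 5000
        mu_x, sx = 2.0, 1.0
        b0, b1, s_eps = 1.0, 1.5, 1.0
        x = r.normal(mu_x, sx, n)
        y = b0 + b1 * x + r.normal(0, s_eps, n)
        miss = r.random(n) < 0.5
        xm = x.copy()
        xm[miss] = np.nan
        df = pd.DataFrame({"y": y, "x": xm})
        spec = SubstantiveModelSpec(family="normal", outcome="y",
                                    terms=(linear("x"),))
        cov = [CovariateModelSpec("x")]
        prob = validate_problem(df, spec, cov)
        res = impute(prob, spec, cov, m=2, n_iter=10, seed=77)

        var_y = b1**2 * sx**2 + s_eps**2
        mu_y = b0 + b1 * mu_x
        rho = b1 * sx / np.sqrt(var_y)
        cond_mean = mu_x + rho * (sx / np.sqrt(var_y)) * (y - mu_y)
        cond_sd = sx * np.sqrt(1 - rho**2)

        pit = []
        for d in res.datasets:
            xi = d["x"].to_numpy()[miss]
            pit.append(stats.norm.cdf((xi - cond_mean[miss]) / cond_sd))
        pit = np.concatenate(pit)
        ks = stats.kstest(pit, "uniform")
        assert ks.statistic < 0.02

    def test_trace_means_stabilise(self):
        """Lag-1 differences of per-iteration covariate means shrink as the
        chain converges on the quadratic scenario."""
        from smcfcs.simulation import apply_missingness, generate_quadratic

        r = np.random.default_rng(8)
        d = generate_quadratic("normal", 1000, r)
        m = apply_missingness(d, ("x",), "mcar", r)
        from smcfcs.data_model import power

        spec = SubstantiveModelSpec(family="normal", outcome="y",
                                    terms=(linear("x"), power("x", 2)))
        cov = [CovariateModelSpec("x")]
        prob = validate_problem(m, spec, cov)
        res = impute(prob, spec, cov, m=4, n_iter=12, seed=5)
        # average |lag-1 difference| over chains: late < early
        diffs = np.abs(np.diff(res.trace[:, :, 0], axis=1))
        early = diffs[:, :3].mean()
        late = diffs[:, -3:].mean()
        assert late < early * 2.0  # no divergence
        # and the late-iteration means hover near the complete-data mean
        assert abs(res.trace[:, -1, 0].mean() - d["x"].mean()) < 0.15
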