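import numpy as np
import pytest
from scipy import stats

from cyclesem.bayes import (BayesianARRegression, Draws, TwoLevelRegression,
                            derived_per_draw, summarize)


class TestSummarize:
    def test_median_of_integer_ladder(self):
        d = Draws({"x": np.arange(1.0, 101.0).reshape(2, 50)})
        out = summarize(d).iloc[0]
        assert out["median"] == pytest.approx(50.5)
        assert out["n_draws"] == 100

    def test_symmetric_draws_not_flagged_nonzero(self):
        rng = np.random.default_rng(0)
        d = Draws({"x": rng.standard_normal((2, 2000))})
        assert not summarize(d).iloc[0]["nonzero"]

    def test_normal_quantiles_closed_form(self):
        rng = np.random.default_rng(1)
        d = Draws({"x": rng.normal(0.4, 0.1, size=(2, 50000))})
        out = summarize(d).iloc[0]
        lo, hi = stats.norm.ppf([0.025, 0.975], loc=0.4, scale=0.1)
        assert out["median"] == pytest.approx(0.4, abs=0.002)
        assert out["ci_lower"] == pytest.approx(lo, abs=0.003)
        assert out["ci_upper"] == pytest.approx(hi, abs=0.003)
        assert out["nonzero"]


class TestDerivedPerDraw:
    def test_degenerate_product(self):
        d = Draws({"a": np.full((2, 10), 2.0), "b": np.full((2, 10), 3.0)})
        out = derived_per_draw(d, lambda p: p["a"] * p["b"], name="ab")
        assert np.all(out == 6.0)
        assert "ab" in d

    def test_string_expression(self):
        d = Draws({"a": np.full((2, 5), 4.0), "b": np.full((2, 5), -0.5)})
        out = derived_per_draw(d, "a * b + 1.0")
        assert np.all(out == -1.0)

    def test_independent_normals_product_median_near_zero(self):
        rng = np.random.default_rng(2)
        d = Draws({"a": rng.standard_normal((2, 20000)),
                   "b": rng.standard_normal((2, 20000))})
        out = derived_per_draw(d, "a * b")
        assert np.median(out) == pytest.approx(0.0, abs=0.02)

    def test_median_of_product_not_product_of_medians(self):
        """With spread around 4.34 and -0.003, the per-draw product median
        lands near -0.013 but need not equal the product of the medians."""
        rng = np.random.default_rng(3)
        d = Draws({"a": rng.normal(4.34, 1.3, size=(2, 40000)),
                   "b": rng.normal(-0.003, 0.0008, size=(2, 40000))})
        out = derived_per_draw(d, "a * b")
        assert np.median(out) == pytest.approx(-0.013, abs=0.001)

    def test_unknown_parameter_errors(self):
        d = Draws({"a": np.ones((2, 4))})
        with pytest.raises(KeyError):
            derived_per_draw(d, lambda p: p["nope"])
        with pytest.raises(NameError):
            derived_per_draw(d, "a * nope")


class TestARRegression:
    def test_flat_prior_posterior_matches_ols(self):
        rng = np.random.default_rng(10)
        n = 500
        X = rng.standard_normal((n, 2))
        y = 1.0 - 2.0 * X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(n) * 0.7
        m = BayesianARRegression(ar_order=0, chains=2, draws=800, random_state=1).fit(X, y)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        mc_tol = 3 * 0.7 / np.sqrt(n)  # a few posterior-SD units
        assert np.all(np.abs(m.coef_ - ols) < mc_tol)
        assert m.converged_

    def test_ar2_coefficients_recovered_on_long_series(self):
        rng = np.random.default_rng(11)
        n = 2000
        u = rng.standard_normal(n) * 0.5
        eps = np.zeros(n)
        for t in range(2, n):
            eps[t] = 0.4 * eps[t - 1] + 0.3 * eps[t - 2] + u[t]
        m = BayesianARRegression(ar_order=2, chains=2, draws=800,
                                 random_state=2).fit(np.empty((n, 0)), 1.0 + eps)
        s = m.summary_.set_index("parameter")["median"]
        assert s["phi[1]"] == pytest.approx(0.4, abs=0.05)
        assert s["phi[2]"] == pytest.approx(0.3, abs=0.05)
        assert s["sigma2"] == pytest.approx(0.25, abs=0.03)
        assert m.stationary_frac_ > 0.99

    def test_constant_response_concentrates_at_constant(self):
        y = np.full(60, 3.25) + np.random.default_rng(3).normal(0, 1e-6, 60)
        m = BayesianARRegression(ar_order=0, chains=2, draws=300,
                                 random_state=3).fit(np.empty((60, 0)), y)
        out = m.summary_.set_index("parameter")
        assert out.loc["intercept", "median"] == pytest.approx(3.25, abs=1e-4)

    def test_non_contiguous_lag_set(self):
        rng = np.random.default_rng(12)
        n = 1500
        u = rng.standard_normal(n)
        eps = np.zeros(n)
        for t in range(2, n):
            eps[t] = 0.45 * eps[t - 2] + u[t]
        m = BayesianARRegression(ar_lags=(2,), chains=2, draws=600,
                                 random_state=4).fit(np.empty((n, 0)), eps)
        assert m.summary_.set_index("parameter").loc["phi[2]", "median"] == \
            pytest.approx(0.45, abs=0.05)
        assert m.param_names_ == ["intercept", "phi[2]", "sigma2"]

    def test_missing_responses_are_imputed_not_dropped(self):
        rng = np.random.default_rng(13)
        n = 300
        X = rng.standard_normal((n, 1))
        y = 2.0 + 1.5 * X[:, 0] + rng.standard_normal(n) * 0.5
        y[[7, 100, 101, 250]] = np.nan
        m = BayesianARRegression(ar_order=1, chains=2, draws=500,
                                 random_state=5).fit(X, y)
        s = m.summary_.set_index("parameter")["median"]
        assert s["beta[0]"] == pytest.approx(1.5, abs=0.12)

    def test_missing_covariates_rejected(self):
        X = np.ones((30, 1))
        X[3] = np.nan
        with pytest.raises(ValueError, match="missing covariates"):
            BayesianARRegression().fit(X, np.zeros(30))

    def test_seeded_runs_bit_reproducible(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((80, 1))
        y = X[:, 0] + rng.standard_normal(80)
        a = BayesianARRegression(ar_order=1, chains=2, draws=200, random_state=9).fit(X, y)
        b = BayesianARRegression(ar_order=1, chains=2, draws=200, random_state=9).fit(X, y)
        for nm in a.draws_.names:
            np.testing.assert_array_equal(a.draws_[nm], b.draws_[nm])

    def test_interval_calibration_near_nominal(self):
        """Planted-truth 95% intervals cover at roughly the nominal rate."""
        rng = np.random.default_rng(15)
        n, reps, covered = 60, 40, 0
        for rep in range(reps):
            X = rng.standard_normal((n, 1))
            y = 0.5 + 0.8 * X[:, 0] + rng.standard_normal(n)
            m = BayesianARRegression(ar_order=0, chains=2, draws=300,
                                     random_state=200 + rep).fit(X, y)
            s = m.summary_.set_index("parameter").loc["beta[0]"]
            covered += int(s["ci_lower"] <= 0.8 <= s["ci_upper"])
        assert 0.85 <= covered / reps <= 1.0


class TestTwoLevelRegression:
    def test_within_slope_recovered(self):
        rng = np.random.default_rng(20)
        J, nj = 80, 50
        mu = rng.normal(0, 1.0, J)
        alpha = rng.normal(5.0, 0.8, J)
        codes = np.repeat(np.arange(J), nj)
        x = mu[codes] + rng.standard_normal(J * nj)
        y = alpha[codes] + 0.7 * (x - mu[codes]) + rng.standard_normal(J * nj) * 0.6
        m = TwoLevelRegression(chains=2, draws=500, random_state=1).fit(
            x[:, None], y, codes)
        s = m.summary_.set_index("parameter")
        assert s.loc["w[x0]", "median"] == pytest.approx(0.7, abs=0.05)

    def test_null_between_slope_covered(self):
        """Cluster covariates with no real effect get intervals covering 0
        in most replicates."""
        rng = np.random.default_rng(21)
        J, nj, reps, covered = 40, 20, 12, 0
        for rep in range(reps):
            z = rng.standard_normal(J)
            alpha = rng.normal(0, 0.5, J)  # no dependence on z
            codes = np.repeat(np.arange(J), nj)
            x = rng.standard_normal(J * nj)
            y = alpha[codes] + 0.3 * x + rng.standard_normal(J * nj) * 0.8
            m = TwoLevelRegression(chains=2, draws=300, random_state=300 + rep).fit(
                x[:, None], y, codes, Z=z[:, None])
            s = m.summary_.set_index("parameter").loc["b[z0]"]
            covered += int(s["ci_lower"] <= 0 <= s["ci_upper"])
        assert covered >= 10

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            TwoLevelRegression().fit(np.zeros((5, 1)), np.zeros(5), np.zeros(5, dtype=int))

    def test_degenerate_within_variance_shrinks(self):
        """Identical nests within every year drive the within residual
        variance to its lower boundary."""
        rng = np.random.default_rng(22)
        J, nj = 30, 8
        alpha = rng.normal(0, 1, J)
        codes = np.repeat(np.arange(J), nj)
        x = np.zeros(J * nj)
        y = alpha[codes]  # no within variation at all
        m = TwoLevelRegression(chains=2, draws=300, random_state=2).fit(
            x[:, None] + rng.standard_normal((J * nj, 1)) * 1e-9, y, codes)
        s = m.summary_.set_index("parameter")
        assert s.loc["sigma2_within", "median"] < 1e-4
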