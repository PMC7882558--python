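import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclesem.simulate import GeneratorConfig, gen_monthly_climate
from cyclesem.windows import (ClimateWindowScanner, WindowSpec, aggregate_window,
                              enumerate_windows, fit_window_model)


@pytest.mark.parametrize("max_lag,expected", [(12, 91), (0, 1), (1, 3)])
def test_enumerate_window_counts(max_lag, expected):
    assert len(enumerate_windows(max_lag)) == expected


@given(st.integers(min_value=0, max_value=30))
@settings(max_examples=30, deadline=None)
def test_enumeration_matches_triangular_formula(max_lag):
    wins = enumerate_windows(max_lag)
    assert len(wins) == (max_lag + 1) * (max_lag + 2) // 2
    assert len(set(wins)) == len(wins)
    assert all(0 <= c <= o <= max_lag for o, c in wins)


def test_enumerate_negative_lag_errors():
    with pytest.raises(ValueError):
        enumerate_windows(-1)


def _climate(values_by_month, years, site="s"):
    rows = []
    for y in years:
        for m, v in values_by_month.items():
            rows.append({"site": site, "year": y, "month": m,
                         "temp": v, "precip": v})
    return pd.DataFrame(rows)


class TestAggregateWindow:
    def test_single_month_window_is_the_value(self):
        clim = _climate({12: 3.5}, [1999])
        spec = WindowSpec(site="s", variable="temp", open_lag=6, close_lag=6)
        # lag 6 from June of 2000 = December 1999
        out = aggregate_window(clim, spec, np.array([2000]))
        assert out.iloc[0] == pytest.approx(3.5)

    def test_december_january_mean(self):
        clim = pd.concat([_climate({12: 2.0}, [1999]), _climate({1: 4.0}, [2000])])
        spec = WindowSpec(site="s", variable="temp", open_lag=6, close_lag=5)
        assert aggregate_window(clim, spec, np.array([2000])).iloc[0] == pytest.approx(3.0)

    def test_constant_series_invariance(self):
        clim = _climate({m: 7.0 for m in range(1, 13)}, range(1998, 2001))
        for open_lag, close_lag in [(0, 0), (5, 2), (12, 0)]:
            spec = WindowSpec(site="s", variable="temp",
                              open_lag=open_lag, close_lag=close_lag)
            assert aggregate_window(clim, spec, np.array([2000])).iloc[0] == pytest.approx(7.0)

    def test_missing_month_gives_missing_aggregate(self):
        clim = _climate({12: 2.0}, [1999])  # January 2000 absent
        spec = WindowSpec(site="s", variable="temp", open_lag=6, close_lag=5)
        assert np.isnan(aggregate_window(clim, spec, np.array([2000])).iloc[0])

    def test_sum_aggregate(self):
        clim = pd.concat([_climate({12: 10.0}, [1999]), _climate({1: 30.0}, [2000])])
        spec = WindowSpec(site="s", variable="precip", open_lag=6, close_lag=5,
                          aggregate="sum")
        assert aggregate_window(clim, spec, np.array([2000])).iloc[0] == pytest.approx(40.0)


class TestFitWindowModel:
    def test_identity_relationship(self):
        x = pd.Series(np.arange(20.0), index=range(2000, 2020))
        res = fit_window_model(x, x)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_fit_is_strongly_preferred(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=20), index=range(2000, 2020))
        y = 2.0 + 0.8 * x + rng.normal(0, 1e-6, size=20)
        res = fit_window_model(y, x)
        assert res["slope"] == pytest.approx(0.8, abs=1e-4)
        assert res["delta_aicc"] < -100

    def test_uninformative_aggregate_rarely_beats_null(self):
        rng = np.random.default_rng(1)
        good = 0
        for _ in range(50):
            y = pd.Series(rng.normal(size=40), index=range(40))
            x = pd.Series(rng.normal(size=40), index=range(40))
            if fit_window_model(y, x)["delta_aicc"] >= -2.0:
                good += 1
        assert good >= 42  # a useless predictor beats the null only rarely

    def test_zero_variance_sentinel(self):
        y = pd.Series(np.random.default_rng(2).normal(size=10), index=range(10))
        x = pd.Series(np.ones(10), index=range(10))
        res = fit_window_model(y, x)
        assert res["delta_aicc"] == np.inf and res["degenerate"]

    def test_too_few_years_errors(self):
        y = pd.Series([1.0, 2, 3, 4], index=range(4))
        with pytest.raises(ValueError):
            fit_window_model(y, y)


class TestScanner:
    def test_result_count_two_variables(self):
        cfg = GeneratorConfig(n_years=30)
        clim = gen_monthly_climate(cfg, np.random.default_rng(0))
        clim = clim[clim["site"] == "mediterranean"]
        years = np.arange(cfg.start_year, cfg.start_year + 30)
        resp = pd.Series(np.random.default_rng(1).normal(size=30), index=years)
        sc = ClimateWindowScanner(max_lag=12).fit(clim, resp)
        assert len(sc.results_) == 182  # 2 variables x 91 windows
        assert np.all(np.diff(sc.results_["delta_aicc"]) >= 0)

    def test_scan_is_deterministic(self):
        cfg = GeneratorConfig(n_years=25)
        clim = gen_monthly_climate(cfg, np.random.default_rng(3))
        clim = clim[clim["site"] == "europe"]
        years = np.arange(cfg.start_year, cfg.start_year + 25)
        resp = pd.Series(np.random.default_rng(4).normal(size=25), index=years)
        a = ClimateWindowScanner(max_lag=6, variables=("temp",)).fit(clim, resp).results_
        b = ClimateWindowScanner(max_lag=6, variables=("temp",)).fit(clim, resp).results_
        pd.testing.assert_frame_equal(a, b)

    def test_planted_window_recovered(self):
        """The December-January planted signal tops the ranking in >= 80% of
        replicates at signal/noise 1."""
        cfg = GeneratorConfig()
        spec = WindowSpec(site="mediterranean", variable="temp", open_lag=6, close_lag=5)
        years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(9000 + rep)
            clim = gen_monthly_climate(cfg, rng)
            clim = clim[clim["site"] == "mediterranean"]
            agg = aggregate_window(clim, spec, years)
            resp = pd.Series(agg.values + rng.normal(0, agg.std(), len(years)),
                             index=agg.index)
            top = ClimateWindowScanner(variables=("temp",)).fit(clim, resp).best_.iloc[0]
            hits += int(top["open_lag"] == 6 and top["close_lag"] == 5)
        assert hits >= 0.8 * reps

    def test_true_window_beats_disjoint_window(self):
        """Delta-AICc of the generating window is stochastically below that of
        a disjoint window."""
        cfg = GeneratorConfig()
        spec = WindowSpec(site="mediterranean", variable="temp", open_lag=6, close_lag=5)
        years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            clim = gen_monthly_climate(cfg, rng)
            clim = clim[clim["site"] == "mediterranean"]
            agg = aggregate_window(clim, spec, years)
            resp = pd.Series(agg.values + rng.normal(0, agg.std(), len(years)),
                             index=agg.index)
            res = ClimateWindowScanner(variables=("temp",)).fit(clim, resp).results_
            res = res.set_index(["open_lag", "close_lag"])
            wins += int(res.loc[(6, 5), "delta_aicc"] < res.loc[(12, 11), "delta_aicc"])
        assert wins >= 9


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(site="s", variable="temp", open_lag=2, close_lag=3)
    w = WindowSpec(site="s", variable="temp", open_lag=6, close_lag=5)
    assert w.length == 2
    assert w.months(2000) == [(2000, 1), (1999, 12)]
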