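import numpy as np
import pandas as pd
import pytest

from cyclesem.bayes import Draws
from cyclesem.rdsem import (GROWTH_PREDICTORS, RDSEM, build_rdsem,
                            fledgling_lag2_effects)
from cyclesem.simulate import GeneratorConfig, gen_full_dataset


def _raw_series(n_years=77, seed=0):
    """An annual series without pre-built lag columns (as from field data)."""
    rng = np.random.default_rng(seed)
    years = np.arange(1941, 1941 + n_years)
    return pd.DataFrame({
        "year": years,
        "density_index": rng.uniform(30, 70, n_years),
        "growth_rate": rng.normal(0, 0.08, n_years),
        "mean_fledglings": rng.normal(4.4, 0.8, n_years),
        "med_winter_temp": rng.normal(0, 1.5, n_years),
        "eur_spring_precip": rng.normal(0, 8, n_years),
        "afr_autumn_precip": rng.normal(0, 20, n_years),
    })


class TestBuildRDSEM:
    def test_raw_series_loses_two_lag_years(self):
        spec = build_rdsem(_raw_series(77))
        assert spec.n_usable == 75

    def test_generator_series_keeps_all_years(self, default_dataset):
        """The simulator emits lagged covariates from its burn-in, so all 77
        emitted growth observations are usable."""
        spec = build_rdsem(default_dataset["series"])
        assert spec.n_usable == 77

    def test_design_column_order(self, default_dataset):
        spec = build_rdsem(default_dataset["series"])
        assert list(spec.table[GROWTH_PREDICTORS].columns) == GROWTH_PREDICTORS

    def test_gap_year_rows_flagged_missing_not_dropped(self):
        s = _raw_series(40)
        s = s[s["year"] != 1960].reset_index(drop=True)
        spec = build_rdsem(s)
        tab = spec.table.set_index("year")
        assert 1960 in tab.index  # gap row exists
        assert not spec.complete_mask[tab.index.get_loc(1960)]
        assert not spec.complete_mask[tab.index.get_loc(1961)]  # lag-1 missing

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            build_rdsem(_raw_series(8))


class TestFitRDSEM:
    def test_noise_free_limit_recovers_slopes(self):
        """With tiny residual variance and no AR terms, the structural slopes
        come back near-exactly."""
        rng = np.random.default_rng(7)
        n = 60
        s = _raw_series(n, seed=7)
        X = s[GROWTH_PREDICTORS[3:]].to_numpy()
        s["density_index"] = rng.uniform(30, 70, n)
        dens_l1 = np.r_[np.nan, s["density_index"].to_numpy()[:-1]]
        fled_l1 = np.r_[np.nan, s["mean_fledglings"].to_numpy()[:-1]]
        fled_l2 = np.r_[np.nan, np.nan, s["mean_fledglings"].to_numpy()[:-2]]
        s["growth_rate"] = (0.1 - 0.003 * dens_l1 + 0.03 * fled_l1 - 0.005 * fled_l2
                            - 0.025 * X[:, 0] - 0.0016 * X[:, 1] - 0.0007 * X[:, 2]
                            + rng.normal(0, 1e-5, n))
        fit = RDSEM(ar_candidates=(), prune=False, chains=2, draws=400,
                    random_state=1).fit(build_rdsem(s))
        med = fit.summary_.set_index("parameter")["median"]
        assert med["growth_on_density_lag1"] == pytest.approx(-0.003, abs=1e-4)
        assert med["growth_on_med_winter_temp"] == pytest.approx(-0.025, abs=1e-3)
        assert med["growth_on_fledglings_lag1"] == pytest.approx(0.03, abs=1e-3)

    def test_summary_contains_every_reported_parameter(self, fitted_rdsem):
        names = set(fitted_rdsem.summary_["parameter"])
        expected = {"growth_intercept", "growth_resid_var", "density_intercept",
                    "density_on_fledglings_lag1", "density_resid_var",
                    "fledglings_lag1_mean", "fledglings_lag1_var",
                    "fledglings_lag2_mean", "fledglings_lag2_var"} \
            | {f"growth_on_{nm}" for nm in GROWTH_PREDICTORS}
        assert expected <= names
        table = fitted_rdsem.summary_table()
        assert set(table["block"]) >= {"Annual population growth rate",
                                       "Population density index", "Means",
                                       "Intercepts", "Variances",
                                       "Residual variances"}

    def test_summary_orders_ci_and_median(self, fitted_rdsem):
        s = fitted_rdsem.summary_
        assert np.all(s["ci_lower"] <= s["median"])
        assert np.all(s["median"] <= s["ci_upper"])


class TestPruning:
    @staticmethod
    def _series_with_growth_ar(phi, lags, n=250, seed=0):
        rng = np.random.default_rng(seed)
        s = _raw_series(n, seed=seed)
        eps = np.zeros(n)
        for t in range(max(lags, default=0), n):
            eps[t] = sum(p * eps[t - l] for p, l in zip(phi, lags)) + rng.normal(0, 0.07)
        s["growth_rate"] = 0.01 + eps
        return s

    def test_white_noise_usually_drops_all_ar_terms(self):
        """Under white-noise growth residuals every AR term is pruned in most
        replicates (each spurious retention is a ~5% event per term)."""
        all_dropped = 0
        for rep in range(5):
            s = self._series_with_growth_ar([], [], n=250, seed=1 + rep)
            fit = RDSEM(chains=2, draws=400, random_state=2 + rep).fit(build_rdsem(s))
            all_dropped += int(fit.growth_lags_ == [])
            assert len(fit.drop_log_) >= 3
        assert all_dropped >= 3

    def test_strong_ar1_retained(self):
        s = self._series_with_growth_ar([0.9], [1], n=250, seed=3)
        fit = RDSEM(chains=2, draws=400, random_state=4).fit(build_rdsem(s))
        assert 1 in fit.growth_lags_

    def test_pure_ar2_usually_selected(self):
        """With only a second-order term planted, pruning should keep exactly
        growth AR(2) in most replicates."""
        exact = 0
        for rep in range(5):
            s = self._series_with_growth_ar([0.45], [2], n=250, seed=10 + rep)
            fit = RDSEM(chains=2, draws=400, random_state=20 + rep).fit(build_rdsem(s))
            exact += int(fit.growth_lags_ == [2])
        assert exact >= 3

    def test_structural_paths_never_pruned(self, fitted_rdsem):
        for entry in fitted_rdsem.drop_log_:
            assert "lag" in entry and entry["equation"] in ("growth", "density")
        assert {f"growth_on_{nm}" for nm in GROWTH_PREDICTORS} <= \
            set(fitted_rdsem.summary_["parameter"])


class TestFledglingLag2Effects:
    def test_degenerate_product(self):
        fit = RDSEM()
        shape = (2, 50)
        fit.draws_ = Draws({
            "growth_on_fledglings_lag2": np.full(shape, -0.004),
            "density_on_fledglings_lag1": np.full(shape, 4.34),
            "growth_on_density_lag1": np.full(shape, -0.003),
        })
        eff = fledgling_lag2_effects(fit).set_index("effect")
        assert eff.loc["indirect", "median"] == pytest.approx(-0.01302)
        assert eff.loc["total", "median"] == pytest.approx(-0.004 + -0.01302)

    def test_zero_density_path_kills_indirect(self):
        fit = RDSEM()
        shape = (2, 50)
        fit.draws_ = Draws({
            "growth_on_fledglings_lag2": np.full(shape, -0.004),
            "density_on_fledglings_lag1": np.full(shape, 4.34),
            "growth_on_density_lag1": np.zeros(shape),
        })
        eff = fledgling_lag2_effects(fit).set_index("effect")
        assert eff.loc["indirect", "median"] == 0.0

    def test_total_is_direct_plus_indirect_per_draw(self, fitted_rdsem):
        d = fitted_rdsem.draws_
        direct = d["growth_on_fledglings_lag2"]
        indirect = d["density_on_fledglings_lag1"] * d["growth_on_density_lag1"]
        eff = fitted_rdsem.effects_.set_index("effect")
        assert eff.loc["total", "median"] == pytest.approx(
            float(np.median(direct + indirect)))


def test_standardized_fit_matches_natural_scale(default_dataset):
    spec = build_rdsem(default_dataset["series"])
    raw = RDSEM(prune=False, ar_candidates=(1,), chains=2, draws=400,
                random_state=5).fit(spec)
    std = RDSEM(prune=False, ar_candidates=(1,), standardize_climate=True,
                chains=2, draws=400, random_state=5).fit(spec)
    a = raw.summary_.set_index("parameter")["median"]
    b = std.summary_.set_index("parameter")["median"]
    for key in ("growth_on_med_winter_temp", "growth_on_eur_spring_precip"):
        assert b[key] == pytest.approx(a[key], rel=0.25, abs=5e-4)
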