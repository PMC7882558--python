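"""Residual dynamic structural equation model for annual population growth.

Two endogenous annual variables are modelled jointly, with autoregressive
residuals separating serial correlation from the structural paths:

* growth rate  R_t ~ density_{t-1} + fledglings_{t-1} + fledglings_{t-2}
               + Mediterranean winter temperature_t
               + European spring precipitation_t
               + African autumn precipitation_{t-1},   AR residuals
* density index N_{t-1} ~ fledglings_{t-2},            AR residuals

The exogenous annual fledgling means enter with free means and variances.
Because the two residual processes are independent and all mediators are
observed, the joint posterior factorises over the equation blocks; each
block is sampled with the conjugate Gibbs machinery in
:mod:`cyclesem.bayes`. Candidate AR terms (lags 1..3 on both endogenous
residuals by default) are pruned iteratively: whichever retained AR term has
the most posterior mass across zero is dropped and the model refit, until
every retained AR credibility interval excludes zero. Structural paths are
never pruned.

The mean fledgling number two years back acts on growth both directly and
via the previous year's density; its indirect effect is the per-draw product
of the fledglings -> density and density -> growth paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bayes import BayesianARRegression, Draws, summarize

GROWTH_PREDICTORS = [
    "density_lag1",
    "fledglings_lag1",
    "fledglings_lag2",
    "med_winter_temp",
    "eur_spring_precip",
    "afr_autumn_precip",
]

#: Display labels for the block-layout summary CSV.
_LABELS = {
    "growth_on_density_lag1": "Population density index (t-1)",
    "growth_on_fledglings_lag1": "Number of fledglings (t-1)",
    "growth_on_fledglings_lag2": "Number of fledglings (t-2)",
    "growth_on_med_winter_temp": "Mediterranean winter temperature",
    "growth_on_eur_spring_precip": "European spring precipitation",
    "growth_on_afr_autumn_precip": "African autumn precipitation (t-1)",
    "density_on_fledglings_lag1": "Number of fledglings (t-2)",
}


class RDSEMSpec:
    """Aligned design tables for the two structural equations.

    Built from an annual series; rows are growth years t, with lagged
    covariates constructed from the same series (or taken directly from
    pre-built ``*_lag*`` columns when present, as in the synthetic tables).
    Rows with missing covariates keep an explicit missing flag.
    """

    def __init__(self, table: pd.DataFrame):
        required = ["year", "growth_rate", *GROWTH_PREDICTORS]
        missing_cols = set(required) - set(table.columns)
        if missing_cols:
            raise ValueError(f"spec table missing columns {sorted(missing_cols)}")
        self.table = table.reset_index(drop=True)
        X = table[GROWTH_PREDICTORS].to_numpy(dtype=float)
        self.complete_mask = np.all(np.isfinite(X), axis=1)
        n_usable = int((self.complete_mask & np.isfinite(table["growth_rate"])).sum())
        if n_usable < 10:
            raise ValueError(f"only {n_usable} usable growth observations; need >= 10")
        self.n_usable = n_usable

    @property
    def growth_design(self) -> np.ndarray:
        return self.table[GROWTH_PREDICTORS].to_numpy(dtype=float)

    @property
    def growth_response(self) -> np.ndarray:
        return self.table["growth_rate"].to_numpy(dtype=float)

    @property
    def density_design(self) -> np.ndarray:
        return self.table[["fledglings_lag2"]].to_numpy(dtype=float)

    @property
    def density_response(self) -> np.ndarray:
        return self.table["density_lag1"].to_numpy(dtype=float)


def build_rdsem(series: pd.DataFrame, climate: pd.DataFrame | None = None) -> RDSEMSpec:
    """Assemble the aligned model table from an annual series.

    `series` needs year, growth_rate, density_index and mean_fledglings; the
    three selected climate-window aggregates come either from pre-existing
    columns or from `climate` (year, med_winter_temp, eur_spring_precip,
    afr_autumn_precip). Lagged columns are built here; the first usable year
    is set by the two-year fledgling lag.
    """
    df = series.sort_values("year").reset_index(drop=True).copy()
    if climate is not None:
        df = df.merge(climate, on="year", how="left", suffixes=("", "_clim"))
    # full year grid so shifts are true calendar lags
    years = np.arange(df["year"].min(), df["year"].max() + 1)
    df = df.set_index("year").reindex(years).rename_axis("year").reset_index()
    if "density_lag1" not in df.columns:
        df["density_lag1"] = df["density_index"].shift(1)
    if "fledglings_lag1" not in df.columns:
        df["fledglings_lag1"] = df["mean_fledglings"].shift(1)
    if "fledglings_lag2" not in df.columns:
        df["fledglings_lag2"] = df["mean_fledglings"].shift(2)
    return RDSEMSpec(df)


class RDSEM(BaseEstimator):
    """Fit the growth-rate path model with AR-residual pruning.

    Parameters
    ----------
    ar_candidates : tuple of int
        Candidate residual lags fitted initially on both endogenous
        residuals.
    prune : bool
        Iteratively drop AR terms whose 95% CI overlaps zero.
    standardize_climate : bool
        Fit with z-scored climate covariates for numerical stability and
        back-transform the summaries to natural units.
    chains, draws, random_state : MCMC controls (half of each chain is
        warm-up; seeded runs are reproducible).

    Attributes
    ----------
    summary_ : tidy table of every reported parameter (median, 95% CI, PSR).
    effects_ : direct / indirect / total effect summaries for the two-year
        fledgling lag.
    drop_log_ : list of dicts recording each pruned AR term and why.
    growth_lags_, density_lags_ : retained AR lags.
    converged_ : bool.
    """

    def __init__(self, ar_candidates=(1, 2, 3), prune: bool = True,
                 standardize_climate: bool = False, chains: int = 2,
                 draws: int = 1000, coef_prior_var: float = 1e6,
                 var_prior_a: float = 0.001, var_prior_b: float = 0.001,
                 rhat_threshold: float = 1.05, random_state=None):
        self.ar_candidates = ar_candidates
        self.prune = prune
        self.standardize_climate = standardize_climate
        self.chains = chains
        self.draws = draws
        self.coef_prior_var = coef_prior_var
        self.var_prior_a = var_prior_a
        self.var_prior_b = var_prior_b
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    @staticmethod
    def _mask_incomplete(X, y):
        """Rows with missing covariates drop out of the likelihood: their
        response becomes latent (imputed each sweep) and the covariates are
        mean-filled, which only re-parameterises the latent residual — the
        AR chain over the remaining years stays intact."""
        X = np.array(X, dtype=float)
        y = np.array(y, dtype=float)
        bad = ~np.all(np.isfinite(X), axis=1)
        if bad.any():
            y[bad] = np.nan
            col_means = np.nanmean(X, axis=0)
            for j in range(X.shape[1]):
                col = X[:, j]
                col[~np.isfinite(col)] = col_means[j]
        return X, y

    def _fit_equations(self, spec, growth_lags, density_lags, seed):
        kw = dict(chains=self.chains, draws=self.draws,
                  coef_prior_var=self.coef_prior_var,
                  var_prior_a=self.var_prior_a, var_prior_b=self.var_prior_b,
                  rhat_threshold=self.rhat_threshold)
        Xg = spec.growth_design
        scales = np.ones(Xg.shape[1])
        if self.standardize_climate:
            climate_cols = [3, 4, 5]
            Xg = Xg.copy()
            for c in climate_cols:
                scales[c] = np.nanstd(Xg[:, c])
                Xg[:, c] = (Xg[:, c] - np.nanmean(Xg[:, c])) / scales[c]
        Xg, yg = self._mask_incomplete(Xg, spec.growth_response)
        growth = BayesianARRegression(ar_lags=growth_lags, random_state=seed, **kw)
        growth.fit(Xg, yg, param_names=[f"on_{nm}" for nm in GROWTH_PREDICTORS])
        if self.standardize_climate:
            for c, nm in enumerate(GROWTH_PREDICTORS):
                if scales[c] != 1.0:
                    growth.draws_._arrays[f"on_{nm}"] /= scales[c]
        Xd, yd = self._mask_incomplete(spec.density_design, spec.density_response)
        density = BayesianARRegression(ar_lags=density_lags, random_state=seed + 1, **kw)
        density.fit(Xd, yd, param_names=["on_fledglings_lag1"])
        return growth, density

    @staticmethod
    def _exogenous_moments(x, rng, n_draws, chains):
        """Normal-InverseGamma conjugate draws for an exogenous mean/variance
        (diffuse Normal(0, 1e6) x IG(0.001, 0.001) prior, small Gibbs)."""
        x = x[np.isfinite(x)]
        n = len(x)
        mu, s2 = float(np.mean(x)), float(np.var(x))
        mus = np.empty((chains, n_draws))
        s2s = np.empty((chains, n_draws))
        for c in range(chains):
            m, v = mu, s2
            for it in range(2 * n_draws):
                prec = n / v + 1e-6
                m = rng.normal((np.sum(x) / v) / prec, np.sqrt(1.0 / prec))
                dev = x - m
                v = 1.0 / rng.gamma(0.001 + 0.5 * n, 1.0 / (0.001 + 0.5 * dev @ dev))
                if it >= n_draws:
                    mus[c, it - n_draws] = m
                    s2s[c, it - n_draws] = v
        return mus, s2s

    def fit(self, spec_or_series, climate: pd.DataFrame | None = None):
        spec = spec_or_series if isinstance(spec_or_series, RDSEMSpec) \
            else build_rdsem(spec_or_series, climate)
        seed = self.random_state if self.random_state is not None else 0
        growth_lags = list(self.ar_candidates)
        density_lags = list(self.ar_candidates)
        drop_log = []

        while True:
            growth, density = self._fit_equations(spec, growth_lags, density_lags, seed)
            if not self.prune:
                break
            worst = None  # (overlap fraction, equation, lag)
            for eq_name, model, lags in (("growth", growth, growth_lags),
                                         ("density", density, density_lags)):
                for lag in lags:
                    d = model.draws_.flat(f"phi[{lag}]")
                    lo, hi = np.percentile(d, [2.5, 97.5])
                    if lo <= 0 <= hi:
                        overlap = min(np.mean(d > 0), np.mean(d < 0))
                        if worst is None or overlap > worst[0]:
                            worst = (overlap, eq_name, lag,
                                     {"median": float(np.median(d)),
                                      "ci_lower": float(lo), "ci_upper": float(hi)})
            if worst is None:
                break
            overlap, eq_name, lag, summ = worst
            drop_log.append({"equation": eq_name, "lag": lag,
                             "reason": "95% CI overlaps zero", **summ,
                             "tail_mass": float(overlap)})
            (growth_lags if eq_name == "growth" else density_lags).remove(lag)

        self.spec_ = spec
        self.growth_model_ = growth
        self.density_model_ = density
        self.growth_lags_ = list(growth_lags)
        self.density_lags_ = list(density_lags)
        self.drop_log_ = drop_log

        rng = np.random.default_rng(np.random.SeedSequence((seed, 977)))
        arrays = {}
        g, d = growth.draws_, density.draws_
        arrays["growth_intercept"] = g["intercept"]
        for nm in GROWTH_PREDICTORS:
            arrays["growth_on_" + nm] = g[f"on_{nm}"]
        for lag in growth_lags:
            arrays[f"growth_ar{lag}"] = g[f"phi[{lag}]"]
        arrays["growth_resid_var"] = g["sigma2"]
        arrays["density_intercept"] = d["intercept"]
        arrays["density_on_fledglings_lag1"] = d["on_fledglings_lag1"]
        for lag in density_lags:
            arrays[f"density_ar{lag}"] = d[f"phi[{lag}]"]
        arrays["density_resid_var"] = d["sigma2"]
        for col, label in (("fledglings_lag1", "fledglings_lag1"),
                           ("fledglings_lag2", "fledglings_lag2")):
            mus, s2s = self._exogenous_moments(
                spec.table[col].to_numpy(dtype=float), rng, self.draws, self.chains)
            arrays[f"{label}_mean"] = mus
            arrays[f"{label}_var"] = s2s
        self.draws_ = Draws(arrays)
        self.summary_ = summarize(self.draws_)
        self.effects_ = fledgling_lag2_effects(self)
        psr = self.summary_["psr"].to_numpy()
        self.converged_ = bool(np.all(psr[np.isfinite(psr)] < self.rhat_threshold)
                               and growth.converged_ and density.converged_)
        return self

    # ------------------------------------------------------------------
    def summary_table(self) -> pd.DataFrame:
        """Reported-table layout: block / parameter / median / 95% CI."""
        s = self.summary_.set_index("parameter")
        rows = []

        def add(block, key, label=None):
            if key in s.index:
                r = s.loc[key]
                rows.append({"block": block, "parameter": label or _LABELS.get(key, key),
                             "median": r["median"], "ci_lower": r["ci_lower"],
                             "ci_upper": r["ci_upper"], "nonzero": r["nonzero"]})

        for key in ("growth_on_density_lag1", "growth_on_fledglings_lag1",
                    "growth_on_fledglings_lag2", "growth_on_med_winter_temp",
                    "growth_on_eur_spring_precip", "growth_on_afr_autumn_precip"):
            add("Annual population growth rate", key)
        for lag in self.growth_lags_:
            add("Annual population growth rate", f"growth_ar{lag}", f"AR({lag})")
        add("Population density index", "density_on_fledglings_lag1")
        for lag in self.density_lags_:
            add("Population density index", f"density_ar{lag}", f"AR({lag})")
        add("Means", "fledglings_lag1_mean", "Number of fledglings (t-1)")
        add("Means", "fledglings_lag2_mean", "Number of fledglings (t-2)")
        add("Intercepts", "growth_intercept", "Annual population growth rate")
        add("Intercepts", "density_intercept", "Population density index (t-1)")
        add("Variances", "fledglings_lag1_var", "Number of fledglings (t-1)")
        add("Variances", "fledglings_lag2_var", "Number of fledglings (t-2)")
        add("Residual variances", "growth_resid_var", "Annual population growth rate")
        add("Residual variances", "density_resid_var", "Population density index (t-1)")
        return pd.DataFrame(rows)


def fledgling_lag2_effects(fit: RDSEM) -> pd.DataFrame:
    """Direct, indirect (via density) and total effect of fledglings_{t-2}.

    All three are computed per posterior draw: the indirect effect is the
    draw-wise product of the fledglings -> density and density -> growth
    paths, the total the draw-wise sum of direct and indirect. Medians of
    products deliberately differ from products of medians.
    """
    d = fit.draws_
    direct = d["growth_on_fledglings_lag2"]
    indirect = d["density_on_fledglings_lag1"] * d["growth_on_density_lag1"]
    total = direct + indirect
    tmp = Draws({"direct": direct, "indirect": indirect, "total": total})
    out = summarize(tmp)
    return out.rename(columns={"parameter": "effect"})
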