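"""Forward simulator for every input the pipeline consumes.

The generator mirrors the structure of the two fitted models exactly, with
default truth values set to the fitted posterior medians, so a generate ->
fit round trip is a parameter-recovery experiment against those values.

Three blocks are simulated:

* monthly climate at up to ten sites along the annual cycle (seasonal
  sinusoid + site offset + independent annual anomalies), with designated
  "true" windows whose aggregates drive the structural equations;
* the annual population block — a density-index equation driven by the
  previous year's mean fledgling number with AR(2) residuals, and a
  growth-rate equation driven by density, fledgling history and three
  climate-window aggregates with AR(2) residuals;
* the nest-level block — per-year latent means for hatching date, clutch
  size, fledgling number and nestling-period weather drawn from the
  between-year model, then within-year nest draws from the within model
  (hatch -> clutch -> fledglings, weather moderation via a
  temperature x precipitation interaction on the centered scale).

``realism_mode="gaussian"`` (default) matches the fitted Gaussian
likelihoods exactly; ``"clamped"`` rounds fledglings to integers in
[0, clutch] and reflects the density index into (0, 100], which introduces
a small, documented bias relative to the fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Truth values: posterior medians of the two fitted models.

RDSEM_TRUTH = {
    "growth_intercept": 0.093,
    "growth_on_density_lag1": -0.003,
    "growth_on_fledglings_lag1": 0.028,
    "growth_on_fledglings_lag2": -0.004,
    "growth_on_med_winter_temp": -0.025,
    "growth_on_eur_spring_precip": -0.00161,
    "growth_on_afr_autumn_precip": -0.00066,
    "growth_ar2": 0.415,
    "density_intercept": 40.673,
    "density_on_fledglings_lag1": 4.34,
    "density_ar1": 0.565,
    "density_ar2": 0.257,
    "fledglings_mean": 4.36,
    "fledglings_var": 0.71,
    "growth_resid_var": 0.006,
    "density_resid_var": 115.68,
}

MSEM_TRUTH = {
    # within level
    "w_fled_on_temp": -0.009,
    "w_fled_on_precip": -0.002,
    "w_fled_on_interaction": 0.0044,
    "w_fled_on_clutch": 0.695,
    "w_clutch_on_hatch": -0.058,
    "w_temp_var": 0.994,
    "w_precip_var": 16.02,
    "w_temp_precip_cov": -0.023,
    "w_hatch_var": 2.35,
    "w_fled_resid_var": 2.98,
    "w_clutch_resid_var": 0.58,
    # between level
    "b_fled_on_clutch": 1.489,
    "b_fled_on_temp": 0.058,
    "b_fled_on_precip": 0.006,
    "b_fled_on_eur_winter_temp": -0.071,
    "b_fled_on_afr_winter_temp": 0.670,
    "b_clutch_on_hatch": -0.037,
    "b_clutch_on_eur_winter_temp": -0.013,
    "b_clutch_on_afr_winter_temp": 0.019,
    "b_hatch_on_eur_winter_temp": -0.003,
    "b_hatch_on_afr_winter_temp": -0.048,
    "b_fled_intercept": -5.55,
    "b_clutch_intercept": 8.89,
    "b_hatch_intercept": 69.07,
    "b_temp_mean": 15.11,
    "b_precip_mean": 27.35,
    "b_temp_var": 3.46,
    "b_precip_var": 30.99,
    "b_temp_precip_cov": -0.057,
    "b_hatch_resid_var": 0.80,
    "b_clutch_resid_var": 0.011,
    "b_fled_resid_var": 0.166,
}

#: Planted climate windows (site, variable, open_lag, close_lag with
#: reference month June of the breeding year) and the seasonal process of
#: each site. Window months: Dec-Jan Mediterranean temperature (lags 5-6),
#: Sep-Oct African precipitation (lags 8-9), Jan-Apr European precipitation
#: (lags 2-5), Feb European temperature (lag 4), Nov African temperature
#: (lag 7).
PLANTED_WINDOWS = {
    "med_winter_temp": {"site": "mediterranean", "variable": "temp", "open_lag": 6, "close_lag": 5},
    "eur_spring_precip": {"site": "europe", "variable": "precip", "open_lag": 5, "close_lag": 2},
    "afr_autumn_precip": {"site": "africa_nonbreeding", "variable": "precip", "open_lag": 9, "close_lag": 8},
    "eur_winter_temp": {"site": "europe", "variable": "temp", "open_lag": 4, "close_lag": 4},
    "afr_winter_temp": {"site": "africa_nonbreeding", "variable": "temp", "open_lag": 7, "close_lag": 7},
}

#: Seasonal climate of each site: annual-mean temperature, seasonal
#: half-amplitude, warmest month, annual-mean monthly precipitation and its
#: seasonal half-amplitude, plus year-to-year anomaly SDs. The non-breeding
#: sites get small temperature anomalies (interannual spread within ~2 deg C).
DEFAULT_SITES = {
    "breeding_grounds":   dict(t_mean=5.0,  t_amp=11.0, t_peak=7, p_mean=55.0,  p_amp=20.0, t_sd=1.5, p_sd=12.0),
    "europe":             dict(t_mean=9.0,  t_amp=9.0,  t_peak=7, p_mean=60.0,  p_amp=15.0, t_sd=2.0, p_sd=12.0),
    "mediterranean":      dict(t_mean=15.0, t_amp=8.0,  t_peak=7, p_mean=45.0,  p_amp=25.0, t_sd=1.5, p_sd=15.0),
    "sahel_stopover":     dict(t_mean=27.0, t_amp=4.0,  t_peak=5, p_mean=40.0,  p_amp=45.0, t_sd=0.6, p_sd=18.0),
    "africa_nonbreeding": dict(t_mean=26.0, t_amp=2.0,  t_peak=3, p_mean=120.0, p_amp=90.0, t_sd=0.5, p_sd=30.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the forward simulator.

    Defaults emulate the field regime: a 77-year annual series, on the order
    of 85 first-brood nests per year, and monthly climate at sites spanning
    the annual cycle with the designated true windows driving the structural
    equations.
    """

    n_years: int = 77
    start_year: int = 1942
    nests_per_year_mean: float = 85.0
    nests_per_year_min: int = 10
    boxes_surveyed: int = 113
    parid_fraction: float = 0.12
    realism_mode: str = "gaussian"
    residual_variance_convention: str = "innovation"
    burn_in: int = 30
    rdsem_truth: dict = field(default_factory=lambda: dict(RDSEM_TRUTH))
    msem_truth: dict = field(default_factory=lambda: dict(MSEM_TRUTH))
    sites: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SITES.items()})
    reference_month: int = 6

    def __post_init__(self):
        if self.realism_mode not in ("gaussian", "clamped"):
            raise ValueError("realism_mode must be 'gaussian' or 'clamped'")
        if self.residual_variance_convention not in ("innovation", "marginal"):
            raise ValueError("residual_variance_convention must be 'innovation' or 'marginal'")
        for key, truth in (("rdsem", self.rdsem_truth), ("msem", self.msem_truth)):
            for name, val in truth.items():
                if name.endswith("_var") and val <= 0:
                    raise ValueError(f"{key} truth {name} must be > 0, got {val}")


# ---------------------------------------------------------------------------
# climate

def gen_monthly_climate(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Monthly temperature/precipitation for all sites and years.

    Covers calendar years ``start_year - 2 .. start_year + n_years - 1`` so
    that every lag up to 12 months before June of the first response year
    (and two response-year lags on top) exists.
    """
    years = np.arange(config.start_year - 2, config.start_year + config.n_years)
    months = np.arange(1, 13)
    frames = []
    for site, p in config.sites.items():
        t_season = p["t_mean"] + p["t_amp"] * np.cos(2 * np.pi * (months - p["t_peak"]) / 12.0)
        p_season = p["p_mean"] + p["p_amp"] * np.cos(2 * np.pi * (months - p.get("p_peak", p["t_peak"])) / 12.0)
        t_anom = rng.normal(0.0, p["t_sd"], size=(len(years), 12))
        p_anom = rng.normal(0.0, p["p_sd"], size=(len(years), 12))
        temp = t_season[None, :] + t_anom
        precip = np.maximum(p_season[None, :] + p_anom, 0.0)
        frames.append(pd.DataFrame({
            "site": site,
            "year": np.repeat(years, 12),
            "month": np.tile(months, len(years)),
            "temp": temp.ravel(),
            "precip": precip.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def planted_window_aggregates(climate: pd.DataFrame, years: np.ndarray,
                              reference_month: int = 6) -> pd.DataFrame:
    """Annual aggregates of the designated true windows, one column each."""
    from .windows import WindowSpec, aggregate_window

    out = pd.DataFrame(index=pd.Index(years, name="year"))
    for name, w in PLANTED_WINDOWS.items():
        spec = WindowSpec(site=w["site"], variable=w["variable"],
                          open_lag=w["open_lag"], close_lag=w["close_lag"],
                          reference_month=reference_month, aggregate="mean")
        out[name] = aggregate_window(climate, spec, years)
    return out.reset_index()


# ---------------------------------------------------------------------------
# annual population block

def _ar_innovation_sd(truth: dict, prefix: str, convention: str) -> float:
    """Innovation SD implied by the truth table under either convention."""
    var = truth[f"{prefix}_resid_var"]
    if convention == "innovation":
        return float(np.sqrt(var))
    phi1 = truth.get(f"{prefix}_ar1", 0.0)
    phi2 = truth.get(f"{prefix}_ar2", 0.0)
    # stationary variance of AR(2): gamma0 = s2 (1-phi2) / ((1+phi2)((1-phi2)^2 - phi1^2))
    factor = (1.0 - phi2) / ((1.0 + phi2) * ((1.0 - phi2) ** 2 - phi1 ** 2))
    return float(np.sqrt(var / factor))


def _simulate_ar(rng, n, phi1, phi2, sd):
    eps = np.zeros(n)
    for t in range(n):
        eps[t] = (phi1 * eps[t - 1] if t >= 1 else 0.0) \
            + (phi2 * eps[t - 2] if t >= 2 else 0.0) + rng.normal(0.0, sd)
    return eps


def gen_population_series(config: GeneratorConfig, climate_aggregates: pd.DataFrame,
                          rng: np.random.Generator):
    """Annual series and nest-box counts from the population-growth model.

    Iterates the density and growth equations forward (with burn-in so the
    AR residual processes are effectively stationary) and back-computes
    occupancy counts from the density index. Returns ``(series, counts)``
    where `series` carries, for every emitted year, the growth rate, density
    index, the lagged covariates actually used in its equations, and the
    annual mean fledgling number.
    """
    tr = config.rdsem_truth
    n_out = config.n_years
    burn = config.burn_in
    n = n_out + burn
    conv = config.residual_variance_convention

    fled = rng.normal(tr["fledglings_mean"], np.sqrt(tr["fledglings_var"]), size=n)
    eps_d = _simulate_ar(rng, n, tr["density_ar1"], tr["density_ar2"],
                         _ar_innovation_sd(tr, "density", conv))
    dens = tr["density_intercept"] + tr["density_on_fledglings_lag1"] \
        * np.concatenate([[tr["fledglings_mean"]], fled[:-1]]) + eps_d
    if config.realism_mode == "clamped":
        dens = np.abs(dens)  # reflect at 0
        dens = np.where(dens > 100.0, 200.0 - dens, dens)
        dens = np.clip(dens, 1e-3, 100.0)
    elif np.any((dens <= 0) | (dens > 100)):
        import warnings
        warnings.warn("density index left (0, 100] in gaussian mode", stacklevel=2)

    agg = climate_aggregates.set_index("year")
    years = np.arange(config.start_year - burn, config.start_year + n_out)
    med = agg["med_winter_temp"].reindex(years).to_numpy()
    eurp = agg["eur_spring_precip"].reindex(years).to_numpy()
    afrp = agg["afr_autumn_precip"].reindex(years).to_numpy()
    # Structural climate covariates are anomalies relative to the
    # study-period mean of the window aggregate (the fitted intercepts are
    # only coherent with near-zero-mean covariates). Burn-in years, which
    # have no climate, sit at the climatological zero.
    for arr in (med, eurp, afrp):
        arr -= np.nanmean(arr)
        arr[np.isnan(arr)] = 0.0

    eps_g = _simulate_ar(rng, n, 0.0, tr["growth_ar2"],
                         _ar_innovation_sd(tr, "growth", conv))
    dens_l1 = np.concatenate([[np.mean(dens)], dens[:-1]])
    fled_l1 = np.concatenate([[tr["fledglings_mean"]], fled[:-1]])
    fled_l2 = np.concatenate([[tr["fledglings_mean"]] * 2, fled[:-2]])
    growth = (tr["growth_intercept"]
              + tr["growth_on_density_lag1"] * dens_l1
              + tr["growth_on_fledglings_lag1"] * fled_l1
              + tr["growth_on_fledglings_lag2"] * fled_l2
              + tr["growth_on_med_winter_temp"] * med
              + tr["growth_on_eur_spring_precip"] * eurp
              + tr["growth_on_afr_autumn_precip"] * afrp
              + eps_g)

    keep = slice(burn, n)
    series = pd.DataFrame({
        "year": years[keep],
        "density_index": dens[keep],
        "growth_rate": growth[keep],
        "mean_fledglings": fled[keep],
        "density_lag1": dens_l1[keep],
        "fledglings_lag1": fled_l1[keep],
        "fledglings_lag2": fled_l2[keep],
        "med_winter_temp": med[keep],
        "eur_spring_precip": eurp[keep],
        "afr_autumn_precip": afrp[keep],
    })

    avail = np.maximum(np.round(config.boxes_surveyed * (1.0 - config.parid_fraction)), 1)
    parid = config.boxes_surveyed - int(avail)
    focal = np.round(series["density_index"].clip(0, 100) / 100.0 * avail).astype(int)
    counts = pd.DataFrame({
        "year": series["year"],
        "surveyed": config.boxes_surveyed,
        "focal": focal,
        "parid": parid,
        "label": "synthetic",
    })
    return series, counts


# ---------------------------------------------------------------------------
# nest-level block

def gen_nests(config: GeneratorConfig, between_covariates: pd.DataFrame,
              rng: np.random.Generator):
    """Nest table from the two-level fledgling model.

    `between_covariates` must have columns year, eur_winter_temp and
    afr_winter_temp. Returns ``(nests, year_latents)`` where `year_latents`
    holds the simulated latent annual means (the between-level truth for
    recovery scoring).
    """
    tr = config.msem_truth
    years = between_covariates["year"].to_numpy()
    eur = between_covariates["eur_winter_temp"].to_numpy(dtype=float)
    afr = between_covariates["afr_winter_temp"].to_numpy(dtype=float)
    J = len(years)

    cov_b = np.array([[tr["b_temp_var"], tr["b_temp_precip_cov"]],
                      [tr["b_temp_precip_cov"], tr["b_precip_var"]]])
    tp = rng.multivariate_normal([tr["b_temp_mean"], tr["b_precip_mean"]], cov_b, size=J)
    a_temp, a_precip = tp[:, 0], tp[:, 1]
    a_hatch = (tr["b_hatch_intercept"] + tr["b_hatch_on_eur_winter_temp"] * eur
               + tr["b_hatch_on_afr_winter_temp"] * afr
               + rng.normal(0, np.sqrt(tr["b_hatch_resid_var"]), J))
    a_clutch = (tr["b_clutch_intercept"] + tr["b_clutch_on_hatch"] * a_hatch
                + tr["b_clutch_on_eur_winter_temp"] * eur
                + tr["b_clutch_on_afr_winter_temp"] * afr
                + rng.normal(0, np.sqrt(tr["b_clutch_resid_var"]), J))
    a_fled = (tr["b_fled_intercept"] + tr["b_fled_on_clutch"] * a_clutch
              + tr["b_fled_on_temp"] * a_temp + tr["b_fled_on_precip"] * a_precip
              + tr["b_fled_on_eur_winter_temp"] * eur
              + tr["b_fled_on_afr_winter_temp"] * afr
              + rng.normal(0, np.sqrt(tr["b_fled_resid_var"]), J))

    n_j = np.maximum(rng.poisson(config.nests_per_year_mean, J), config.nests_per_year_min)
    idx = np.repeat(np.arange(J), n_j)
    n = len(idx)

    cov_w = np.array([[tr["w_temp_var"], tr["w_temp_precip_cov"]],
                      [tr["w_temp_precip_cov"], tr["w_precip_var"]]])
    dtp = rng.multivariate_normal([0.0, 0.0], cov_w, size=n)
    d_temp, d_precip = dtp[:, 0], dtp[:, 1]
    d_hatch = rng.normal(0, np.sqrt(tr["w_hatch_var"]), n)
    d_clutch = tr["w_clutch_on_hatch"] * d_hatch + rng.normal(0, np.sqrt(tr["w_clutch_resid_var"]), n)
    d_fled = (tr["w_fled_on_clutch"] * d_clutch + tr["w_fled_on_temp"] * d_temp
              + tr["w_fled_on_precip"] * d_precip
              + tr["w_fled_on_interaction"] * d_temp * d_precip
              + rng.normal(0, np.sqrt(tr["w_fled_resid_var"]), n))

    hatch = a_hatch[idx] + d_hatch
    clutch = a_clutch[idx] + d_clutch
    fled = a_fled[idx] + d_fled
    temp = a_temp[idx] + d_temp
    precip = np.maximum(a_precip[idx] + d_precip, 0.0) if config.realism_mode == "clamped" \
        else a_precip[idx] + d_precip
    if config.realism_mode == "clamped":
        clutch = np.clip(np.round(clutch), 1, None)
        fled = np.clip(np.round(fled), 0, clutch)
        hatch = np.round(hatch)

    nests = pd.DataFrame({
        "year": years[idx],
        "hatch_date": hatch,
        "clutch": clutch,
        "fledglings": fled,
        "nest_temp": temp,
        "nest_precip": precip,
    })
    year_latents = pd.DataFrame({
        "year": years, "n_nests": n_j, "alpha_hatch": a_hatch,
        "alpha_clutch": a_clutch, "alpha_fledglings": a_fled,
        "alpha_temp": a_temp, "alpha_precip": a_precip,
        "eur_winter_temp": eur, "afr_winter_temp": afr,
    })
    return nests, year_latents


# ---------------------------------------------------------------------------
# full dataset

def gen_full_dataset(config: GeneratorConfig, seed: int, out_dir=None) -> dict:
    """Generate climate, annual counts, annual series and nest tables.

    Returns a dict of DataFrames plus a truth manifest; when `out_dir` is
    given the tables are written as CSV (UTF-8, '.' decimal) and the
    manifest as JSON.
    """
    rng = np.random.default_rng(seed)
    climate = gen_monthly_climate(config, rng)
    resp_years = np.arange(config.start_year, config.start_year + config.n_years)
    aggs = planted_window_aggregates(climate, resp_years, config.reference_month)
    series, counts = gen_population_series(config, aggs, rng)
    between = aggs[["year", "eur_winter_temp", "afr_winter_temp"]].copy()
    for col in ("eur_winter_temp", "afr_winter_temp"):
        between[col] -= between[col].mean()  # anomalies, like the growth-model covariates
    nests, year_latents = gen_nests(config, between, rng)
    ann = nests.groupby("year")["fledglings"].mean().rename("mean_fledglings_nests")
    series = series.merge(ann, on="year", how="left")

    manifest = {
        "seed": int(seed),
        "config": {k: v for k, v in asdict(config).items() if k not in ("rdsem_truth", "msem_truth", "sites")},
        "rdsem_truth": config.rdsem_truth,
        "msem_truth": config.msem_truth,
        "planted_windows": PLANTED_WINDOWS,
        "climate_covariates": "anomalies relative to the study-period window mean",
        "residual_variance_convention": config.residual_variance_convention,
    }
    out = {"climate": climate, "counts": counts, "series": series,
           "nests": nests, "between": between, "year_latents": year_latents,
           "manifest": manifest}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("climate", "counts", "series", "nests", "between"):
            out[name].to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
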