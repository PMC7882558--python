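"""Parameter-recovery experiments: generate at truth, fit, score.

Because the field data behind the fitted models are not public, the primary
check of the estimators is the round trip through the forward simulator:
data are generated with the structural parameters set to the fitted
posterior medians, the models are re-fit to each replicate, and the
replicate-averaged posterior medians are compared with the generating
values. These experiments are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .msem import MultilevelSEM
from .rdsem import RDSEM, build_rdsem
from .simulate import (GeneratorConfig, gen_full_dataset, gen_monthly_climate,
                       gen_nests, gen_population_series, planted_window_aggregates)

RDSEM_TARGETS = ["growth_on_med_winter_temp", "growth_on_density_lag1",
                 "growth_on_fledglings_lag1", "growth_ar2"]
MSEM_TARGETS = ["w_fled_on_clutch", "w_clutch_on_hatch",
                "b_fled_on_afr_winter_temp", "b_fled_on_eur_winter_temp"]


def _replicate_seeds(base_seed: int, n: int) -> list[int]:
    # deterministic, distinct, and stable across runs with the same base seed
    return [(int(base_seed) * 1009 + r + 1) % (2**31 - 1) for r in range(n)]


def rdsem_recovery(n_replicates: int = 20, base_seed: int = 0, chains: int = 2,
                   draws: int = 800, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Replicated growth-model round trip at the default truth values.

    Each replicate simulates a fresh 77-year annual series, fits the
    AR-pruned growth/density system, and records the posterior median of
    every parameter plus which AR lags survived pruning. One row per
    replicate.
    """
    config = config or GeneratorConfig()
    rows = []
    for rep, rep_seed in enumerate(_replicate_seeds(base_seed, n_replicates)):
        rng = np.random.default_rng(rep_seed)
        climate = gen_monthly_climate(config, rng)
        years = np.arange(config.start_year, config.start_year + config.n_years)
        aggs = planted_window_aggregates(climate, years, config.reference_month)
        series, _ = gen_population_series(config, aggs, rng)
        fit = RDSEM(chains=chains, draws=draws, random_state=rep_seed + 1).fit(
            build_rdsem(series))
        row = {"replicate": rep, "seed": rep_seed,
               "growth_lags": tuple(fit.growth_lags_),
               "density_lags": tuple(fit.density_lags_),
               "converged": fit.converged_}
        med = fit.summary_.set_index("parameter")["median"]
        for name, value in med.items():
            row[name] = value
        eff = fit.effects_.set_index("effect")["median"]
        for name, value in eff.items():
            row[f"fledglings_lag2_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def msem_recovery(n_replicates: int = 10, base_seed: int = 0, chains: int = 2,
                  draws: int = 600, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Replicated nest-model round trip at the default truth values.

    Each replicate simulates winter-temperature anomalies, 77 year-clusters
    of nests at the between/within truth, fits the two-level SEM (gaussian
    mode) and records the posterior medians. One row per replicate.
    """
    config = config or GeneratorConfig()
    rows = []
    for rep, rep_seed in enumerate(_replicate_seeds(base_seed, n_replicates)):
        rng = np.random.default_rng(rep_seed)
        climate = gen_monthly_climate(config, rng)
        years = np.arange(config.start_year, config.start_year + config.n_years)
        aggs = planted_window_aggregates(climate, years, config.reference_month)
        between = aggs[["year", "eur_winter_temp", "afr_winter_temp"]].copy()
        for col in ("eur_winter_temp", "afr_winter_temp"):
            between[col] -= between[col].mean()
        nests, _ = gen_nests(config, between, rng)
        fit = MultilevelSEM(chains=chains, draws=draws, random_state=rep_seed + 1).fit(
            nests, between)
        row = {"replicate": rep, "seed": rep_seed, "converged": fit.converged_}
        med = fit.summary_.set_index("parameter")["median"]
        for name, value in med.items():
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_score(results: pd.DataFrame, truth: dict, params: list[str]) -> pd.DataFrame:
    """Replicate-averaged medians vs truth, with Monte-Carlo standard errors."""
    rows = []
    for name in params:
        vals = results[name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append({"parameter": name, "truth": truth[name], "mean_median": mean,
                     "mc_se": se, "n": len(vals),
                     "z": (mean - truth[name]) / se if se and se > 0 else np.nan})
    return pd.DataFrame(rows)
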