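"""End-to-end pipeline: prep -> window scan -> growth model -> nest model.

A single config dict (usually loaded from YAML) drives every stage; all
randomness flows from one seed, so a rerun with the same config and inputs
reproduces the summary tables exactly. Window selection is deliberately not
automatic: the scan stage only ranks candidates, and the structural stages
refuse to run unless the config either names the selected windows or sets
``windows.auto_select`` explicitly (the scan is an exploratory tool and can
overfit).
"""

from __future__ import annotations

import json
import logging
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, data_prep
from .msem import MultilevelSEM, decompose_effects, simple_slopes, within_total_hatch_effect
from .rdsem import RDSEM, build_rdsem
from .simulate import GeneratorConfig, gen_full_dataset
from .windows import ClimateWindowScanner, WindowSpec, aggregate_window

log = logging.getLogger(__name__)

#: Covariate roles each structural stage needs, as {role: response}.
RDSEM_ROLES = ("med_winter_temp", "eur_spring_precip", "afr_autumn_precip")
MSEM_ROLES = ("eur_winter_temp", "afr_winter_temp")


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(config, out_dir):
    if "generate" in config:
        gen_cfg = GeneratorConfig(**config.get("generate_options", {}))
        seed = int(config["seed"])
        data = gen_full_dataset(gen_cfg, seed=seed, out_dir=out_dir / "inputs")
        return data
    try:
        paths = config["inputs"]
        data = {name: pd.read_csv(paths[name]) for name in ("counts", "nests", "climate")}
    except KeyError as e:
        raise PipelineError("inputs", f"missing input entry {e}") from e
    if "series" in paths:
        data["series"] = pd.read_csv(paths["series"])
    if "between" in paths:
        data["between"] = pd.read_csv(paths["between"])
    return data


def _selected_window_aggregates(config, climate, years, roles, stage):
    wcfg = config.get("windows", {})
    selected = wcfg.get("selected", {})
    out = pd.DataFrame({"year": years})
    for role in roles:
        if role not in selected:
            if not wcfg.get("auto_select", False):
                raise PipelineError(
                    stage,
                    f"no selected window for {role!r} and windows.auto_select is not set; "
                    "the sliding-window scan is exploratory — name the windows explicitly "
                    "or opt in to automatic selection",
                )
            raise PipelineError(stage, f"auto_select needs a scan result for {role!r} "
                                       "(provide windows.selected after running scan)")
        w = selected[role]
        spec = WindowSpec(site=w["site"], variable=w["variable"],
                          open_lag=int(w["open_lag"]), close_lag=int(w["close_lag"]),
                          reference_month=int(w.get("reference_month",
                                                    config.get("reference_month", 6))),
                          aggregate=w.get("aggregate", "mean"))
        out[role] = aggregate_window(climate, spec, years).to_numpy()
    return out


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every configured stage; write a report bundle under `out_dir`.

    Returns a dict with the in-memory results (series, scan tables, fitted
    models, summary tables). Outputs written so far are preserved when a
    later stage fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "seed" not in config:
        raise PipelineError("config", "a seed is required")
    seed = int(config["seed"])
    started = datetime.now(timezone.utc).isoformat()
    results: dict = {}
    convergence = {}

    data = _load_inputs(config, out_dir)

    # ---- prep ------------------------------------------------------------
    try:
        if "series" in data and "growth_rate" in data["series"].columns:
            series = data["series"]
        else:
            series = data_prep.build_annual_series(
                data["counts"], nests=data.get("nests"),
                prefer=config.get("prefer_population"),
                strict=config.get("strict_validation", False))
        series.to_csv(out_dir / "annual_series.csv", index=False)
        results["series"] = series
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("prep", str(e)) from e

    years = series.loc[np.isfinite(series["growth_rate"].to_numpy(dtype=float)), "year"].to_numpy() \
        if "growth_rate" in series.columns else series["year"].to_numpy()

    # ---- scan ------------------------------------------------------------
    scan_cfg = config.get("scan", {})
    if scan_cfg.get("enabled", True):
        try:
            scanner = ClimateWindowScanner(
                max_lag=int(scan_cfg.get("max_lag", 12)),
                reference_month=int(scan_cfg.get("reference_month", 6)),
                aggregate=scan_cfg.get("aggregate", "mean"))
            resp = series.set_index("year")["growth_rate"].astype(float)
            scanner.fit(data["climate"], resp)
            scanner.results_.to_csv(out_dir / "window_scan_growth.csv", index=False)
            results["scan_growth"] = scanner.results_
            if "mean_fledglings" in series.columns:
                respf = series.set_index("year")["mean_fledglings"].astype(float)
                scan_f = ClimateWindowScanner(
                    max_lag=int(scan_cfg.get("max_lag", 12)),
                    reference_month=int(scan_cfg.get("reference_month", 6)),
                    aggregate=scan_cfg.get("aggregate", "mean")).fit(data["climate"], respf)
                scan_f.results_.to_csv(out_dir / "window_scan_fledglings.csv", index=False)
                results["scan_fledglings"] = scan_f.results_
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("scan", str(e)) from e

    # ---- growth model ----------------------------------------------------
    if config.get("rdsem", {}).get("enabled", True):
        try:
            if set(RDSEM_ROLES) <= set(series.columns):
                spec = build_rdsem(series)
            else:
                clim_cov = _selected_window_aggregates(config, data["climate"], years,
                                                       RDSEM_ROLES, "rdsem")
                spec = build_rdsem(series, clim_cov)
            rcfg = config.get("rdsem", {})
            model = RDSEM(chains=int(rcfg.get("chains", 2)),
                          draws=int(rcfg.get("draws", 1000)),
                          ar_candidates=tuple(rcfg.get("ar_candidates", (1, 2, 3))),
                          random_state=seed + 1)
            model.fit(spec)
            model.summary_table().to_csv(out_dir / "rdsem_summary.csv", index=False)
            model.effects_.to_csv(out_dir / "rdsem_fledgling_lag2_effects.csv", index=False)
            pd.DataFrame(model.drop_log_).to_csv(out_dir / "rdsem_ar_drop_log.csv", index=False)
            model.draws_.to_frame().to_csv(out_dir / "rdsem_draws.csv", index=False)
            results["rdsem"] = model
            convergence["rdsem"] = model.converged_
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("rdsem", str(e)) from e

    # ---- nest model ------------------------------------------------------
    if config.get("msem", {}).get("enabled", True):
        try:
            if "between" in data and set(MSEM_ROLES) <= set(data["between"].columns):
                between = data["between"]
            else:
                all_years = np.sort(data["nests"]["year"].unique())
                between = _selected_window_aggregates(config, data["climate"], all_years,
                                                      MSEM_ROLES, "msem")
            mcfg = config.get("msem", {})
            msem = MultilevelSEM(chains=int(mcfg.get("chains", 2)),
                                 draws=int(mcfg.get("draws", 800)),
                                 random_state=seed + 2)
            msem.fit(data["nests"], between)
            msem.summary_table().to_csv(out_dir / "msem_summary.csv", index=False)
            decompose_effects(msem).to_csv(out_dir / "msem_effect_decomposition.csv", index=False)
            pd.DataFrame([within_total_hatch_effect(msem)]).to_csv(
                out_dir / "msem_within_hatch_total.csv", index=False)
            pcts = mcfg.get("slope_percentiles", (10, 25, 50, 75, 90))
            simple_slopes(msem, pcts).to_csv(out_dir / "msem_simple_slopes.csv", index=False)
            results["msem"] = msem
            convergence["msem"] = msem.converged_
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("msem", str(e)) from e

    # ---- report ----------------------------------------------------------
    run_log = {
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "cyclesem_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "convergence": convergence,
        "stages": sorted(results.keys()),
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    results["run_log"] = run_log
    return results
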