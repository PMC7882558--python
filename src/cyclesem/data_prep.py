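"""Annual population variables from nest-box survey data.

Derives the density index (percentage of available boxes occupied by the
focal species, after removing boxes taken by Parids), the annual population
growth rate ``R_t = ln(N_t) - ln(N_{t-1})``, and per-year means of the
nest-level breeding variables, and merges series from two study areas into
one long annual series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ANNUAL_COUNT_COLUMNS = ["year", "surveyed", "focal", "parid", "label"]
NEST_COLUMNS = ["year", "hatch_date", "clutch", "fledglings", "nest_temp", "nest_precip"]
CLIMATE_COLUMNS = ["site", "year", "month", "temp", "precip"]


class InvalidRecordError(ValueError):
    """A survey record violates a structural constraint (names the year)."""


@dataclass
class IndependenceReport:
    """Pearson correlation between focal and competitor occupancy rates."""

    r: float
    p_value: float
    n: int


def validate_annual_counts(counts: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Check the annual nest-box count table.

    Requires columns ``year, surveyed, focal, parid, label``. Violations of
    ``focal + parid <= surveyed`` or ``surveyed > 0`` warn by default and
    raise in strict mode; duplicate years within a label always raise.
    """
    missing = set(ANNUAL_COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise InvalidRecordError(f"annual count table missing columns: {sorted(missing)}")
    dup = counts.duplicated(subset=["label", "year"])
    if dup.any():
        raise InvalidRecordError(
            f"duplicate years within a population: {counts.loc[dup, 'year'].tolist()}"
        )
    bad = counts["focal"] + counts["parid"] > counts["surveyed"]
    bad |= counts["surveyed"] <= 0
    if bad.any():
        msg = f"count invariant violated in years {counts.loc[bad, 'year'].tolist()}"
        if strict:
            raise InvalidRecordError(msg)
        warnings.warn(msg, stacklevel=2)
    return counts


def compute_density_index(counts: pd.DataFrame) -> pd.Series:
    """Density index: 100 * focal / (surveyed - parid), per year.

    The denominator is the number of boxes actually available to the focal
    species (boxes occupied by Parids are not available). Result is on the
    0-100 percent scale.
    """
    denom = counts["surveyed"] - counts["parid"]
    bad = denom <= 0
    if bad.any():
        raise InvalidRecordError(
            f"no boxes available to focal species in years {counts.loc[bad, 'year'].tolist()}"
        )
    return 100.0 * counts["focal"] / denom


def compute_growth_rate(series: pd.DataFrame) -> pd.DataFrame:
    """Fill ``growth_rate`` with ln(N_t) - ln(N_{t-1}) for consecutive years.

    ``series`` must have ``year`` and ``density_index`` columns. R_t is left
    missing for the first year and wherever year t-1 is absent (a gap in the
    merged series); positivity of the density index is required for years
    that enter a log.
    """
    out = series.sort_values("year").reset_index(drop=True).copy()
    n = out["density_index"].to_numpy(dtype=float)
    year = out["year"].to_numpy()
    used = np.isfinite(n)
    if np.any(n[used] <= 0):
        raise InvalidRecordError(
            f"density index must be positive, got non-positive values in years "
            f"{out.loc[used & (n <= 0), 'year'].tolist()}"
        )
    r = np.full(len(out), np.nan)
    consecutive = np.zeros(len(out), dtype=bool)
    consecutive[1:] = np.diff(year) == 1
    ok = consecutive & used & np.concatenate([[False], used[:-1]])
    r[ok] = np.log(n[ok]) - np.log(np.roll(n, 1)[ok])
    gaps = np.where(np.diff(year) > 1)[0]
    if len(gaps):
        log.info("growth rate undefined across year gaps after: %s", year[gaps].tolist())
    out["growth_rate"] = r
    return out


def merge_series(a: pd.DataFrame, b: pd.DataFrame, prefer: str) -> pd.DataFrame:
    """Union of two annual series; overlapping years keep the `prefer` label.

    Years present in neither series stay absent, so a later
    :func:`compute_growth_rate` marks growth across the gap as missing.
    """
    both = pd.concat([a, b], ignore_index=True)
    if both.empty:
        return both
    keep_first = both["label"] == prefer
    both = both.iloc[np.lexsort([~keep_first.to_numpy(), both["year"].to_numpy()])]
    return both.drop_duplicates(subset="year", keep="first").reset_index(drop=True)


def occupancy_independence(focal: pd.Series, competitor: pd.Series) -> IndependenceReport:
    """Pearson correlation between paired annual occupancy rates."""
    x = np.asarray(focal, dtype=float)
    y = np.asarray(competitor, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired years")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an occupancy series")
    r, p = stats.pearsonr(x, y)
    return IndependenceReport(r=float(r), p_value=float(p), n=len(x))


def annual_summaries(nests: pd.DataFrame) -> pd.DataFrame:
    """Per-year means of fledglings, hatch date and clutch size.

    Years absent from the nest table are simply absent from the output;
    downstream joins treat them as missing.
    """
    g = nests.groupby("year", as_index=False).agg(
        mean_fledglings=("fledglings", "mean"),
        mean_hatch_date=("hatch_date", "mean"),
        mean_clutch=("clutch", "mean"),
        n_nests=("fledglings", "size"),
    )
    return g


def build_annual_series(
    counts: pd.DataFrame,
    nests: pd.DataFrame | None = None,
    prefer: str | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Full annual table: density index, growth rate and breeding means.

    When `counts` holds more than one population label, series are merged
    with overlapping years resolved in favour of ``prefer`` (required then).
    """
    counts = validate_annual_counts(counts, strict=strict)
    counts = counts.assign(density_index=compute_density_index(counts))
    labels = counts["label"].unique()
    if len(labels) > 1:
        if prefer is None:
            raise ValueError(f"multiple populations {labels.tolist()}: 'prefer' is required")
        merged = counts[counts["label"] == labels[0]]
        for lab in labels[1:]:
            merged = merge_series(merged, counts[counts["label"] == lab], prefer=prefer)
    else:
        merged = counts
    # reindex over the full year span so gap years exist as missing rows
    years = np.arange(merged["year"].min(), merged["year"].max() + 1)
    merged = merged.set_index("year").reindex(years).rename_axis("year").reset_index()
    series = compute_growth_rate(merged)
    if nests is not None:
        series = series.merge(annual_summaries(nests), on="year", how="left")
    return series


def density_dependence_interpretations(slope: float, baseline_density: float) -> dict:
    """Absolute and relative readings of a density-dependence slope.

    Returns both the absolute growth-rate change for a 10-index-point rise in
    previous-year density and the change for a 10 % relative rise from the
    baseline density. Neither is privileged: interpretation of such slopes on
    the percent scale is ambiguous, so both are reported.
    """
    return {
        "per_10_index_points": 10.0 * slope,
        "per_10pct_relative": 0.1 * baseline_density * slope,
    }
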