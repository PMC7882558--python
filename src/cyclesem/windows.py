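"""Sliding climate-window scan.

For each climate site and variable, every contiguous run of months within the
year preceding breeding (anchored at a reference month, by default June of the
breeding year) is aggregated into an annual covariate, regressed against an
annual response, and compared to an intercept-only null model by small-sample
corrected AIC. The scan is exploratory: it ranks candidate windows, it does
not by itself decide which windows enter the structural models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous monthly window, counted in lags before a reference month.

    ``open_lag`` is the earliest month of the window, ``close_lag`` the most
    recent, both as months before ``reference_month`` of the response year
    (lag 0 = the reference month itself; months cross into the previous
    calendar year as needed).
    """

    site: str
    variable: str
    open_lag: int
    close_lag: int
    reference_month: int = 6
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if not 0 <= self.close_lag <= self.open_lag:
            raise ValueError("need 0 <= close_lag <= open_lag")
        if not 1 <= self.reference_month <= 12:
            raise ValueError("reference_month must be in 1..12")

    @property
    def length(self) -> int:
        return self.open_lag - self.close_lag + 1

    def months(self, year: int) -> list[tuple[int, int]]:
        """(year, month) pairs covered by this window for a response year."""
        out = []
        for lag in range(self.close_lag, self.open_lag + 1):
            m = self.reference_month - lag
            y = year
            while m < 1:
                m += 12
                y -= 1
            out.append((y, m))
        return out


def enumerate_windows(max_lag: int) -> list[tuple[int, int]]:
    """All (open_lag, close_lag) pairs with 0 <= close <= open <= max_lag.

    The count is the triangular number (max_lag+1)(max_lag+2)/2: 91 windows
    for 13 monthly anchors (max_lag = 12).
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    return [(o, c) for o in range(max_lag + 1) for c in range(o + 1)]


def aggregate_window(climate: pd.DataFrame, spec: WindowSpec, years: np.ndarray) -> pd.Series:
    """Annual aggregate (mean or sum) of a monthly variable over a window.

    `climate` is the long monthly table (site, year, month, temp, precip).
    Years whose window touches a missing month get a missing aggregate.
    """
    sub = climate[climate["site"] == spec.site]
    lut = {(y, m): v for y, m, v in zip(sub["year"], sub["month"], sub[spec.variable])}
    func = {"mean": np.mean, "sum": np.sum}[spec.aggregate]
    vals = []
    for year in years:
        monthly = [lut.get(ym, np.nan) for ym in spec.months(int(year))]
        vals.append(func(monthly) if np.all(np.isfinite(monthly)) else np.nan)
    return pd.Series(vals, index=pd.Index(years, name="year"), name="aggregate")


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_window_model(response: pd.Series, aggregate: pd.Series) -> dict:
    """OLS of the annual response on one window aggregate, vs the null model.

    Returns slope, intercept, n_years and delta_aicc = AICc(model) -
    AICc(null), counting the error variance as a parameter (k = 3 vs k = 2).
    A zero-variance aggregate cannot be compared and gets a +inf sentinel.
    """
    df = pd.concat({"y": response, "x": aggregate}, axis=1).dropna()
    n = len(df)
    if n < 5:
        raise ValueError(f"need >= 5 complete year pairs, got {n}")
    y = df["y"].to_numpy()
    x = df["x"].to_numpy()
    if np.ptp(x) == 0:
        return {"slope": np.nan, "intercept": np.nan, "n_years": n,
                "delta_aicc": np.inf, "degenerate": True}
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    null = sm.OLS(y, np.ones((n, 1))).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "n_years": n,
        "delta_aicc": _aicc(fit.llf, 3, n) - _aicc(null.llf, 2, n),
        "degenerate": False,
    }


class ClimateWindowScanner(BaseEstimator):
    """Exhaustive per-site, per-variable sliding-window scan.

    Parameters
    ----------
    max_lag : int
        Largest lag (months before `reference_month`) considered; the scan
        covers all (open, close) pairs up to this lag.
    reference_month : int
        Calendar month anchoring lag 0 in the response year.
    aggregate : {"mean", "sum"}
        How monthly values are combined within a window.
    variables : tuple of str
        Climate columns to scan (subset of {"temp", "precip"}).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (site, variable, window), ranked by delta_aicc ascending
        with ties broken by shorter window, then more recent close.
    best_ : pandas.DataFrame
        Top-ranked window per (site, variable).
    """

    def __init__(self, max_lag: int = 12, reference_month: int = 6,
                 aggregate: str = "mean", variables: tuple = ("temp", "precip")):
        self.max_lag = max_lag
        self.reference_month = reference_month
        self.aggregate = aggregate
        self.variables = variables

    def fit(self, climate: pd.DataFrame, response: pd.Series):
        """Scan all windows against an annual response (Series indexed by year)."""
        response = response.dropna()
        years = response.index.to_numpy()
        rows = []
        for site in pd.unique(climate["site"]):
            for variable in self.variables:
                for open_lag, close_lag in enumerate_windows(self.max_lag):
                    spec = WindowSpec(site=site, variable=variable,
                                      open_lag=open_lag, close_lag=close_lag,
                                      reference_month=self.reference_month,
                                      aggregate=self.aggregate)
                    agg = aggregate_window(climate, spec, years)
                    res = fit_window_model(response, agg)
                    rows.append({"site": site, "variable": variable,
                                 "open_lag": open_lag, "close_lag": close_lag,
                                 "length": spec.length, **res})
        results = pd.DataFrame(rows)
        self.results_ = results.sort_values(
            ["delta_aicc", "length", "close_lag"],
            ascending=[True, True, True],
        ).reset_index(drop=True)
        self.best_ = (self.results_
                      .groupby(["site", "variable"], as_index=False)
                      .first()
                      .sort_values("delta_aicc")
                      .reset_index(drop=True))
        return self


def scan(climate: pd.DataFrame, response: pd.Series, sites=None,
         variables=("temp", "precip"), max_lag: int = 12,
         reference_month: int = 6, aggregate: str = "mean") -> pd.DataFrame:
    """Functional wrapper over :class:`ClimateWindowScanner`."""
    if sites is not None:
        climate = climate[climate["site"].isin(sites)]
    scanner = ClimateWindowScanner(max_lag=max_lag, reference_month=reference_month,
                                   aggregate=aggregate, variables=variables)
    return scanner.fit(climate, response).results_
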