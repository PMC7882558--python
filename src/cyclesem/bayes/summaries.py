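"""Posterior draws container, equal-tailed summaries and derived quantities.

Summaries follow the reporting convention of the structural models: posterior
median, equal-tailed 95% credibility interval, and a "nonzero" flag set when
the interval excludes zero. Indirect and total effects are always computed
draw-by-draw before summarising (the median of a product is not the product
of medians).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def split_rhat(arr: np.ndarray) -> float:
    """Split potential-scale-reduction statistic for a (chains, iters) array."""
    import arviz as az

    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        return np.nan
    if np.allclose(arr, arr.flat[0]):
        return 1.0
    with np.errstate(invalid="ignore"):
        return float(az.rhat(az.convert_to_dataset(arr[None].transpose(1, 2, 0)))["x"].item())


class Draws:
    """Named posterior draws, one (chains, iters) array per parameter."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self._arrays = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in arrays.items()}
        shapes = {v.shape for v in self._arrays.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self._arrays)

    @property
    def n_chains(self) -> int:
        return next(iter(self._arrays.values())).shape[0]

    @property
    def n_draws(self) -> int:
        a = next(iter(self._arrays.values()))
        return a.shape[0] * a.shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self._arrays

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self._arrays:
            raise KeyError(f"unknown parameter {name!r}; have {self.names}")
        return self._arrays[name]

    def flat(self, name: str) -> np.ndarray:
        return self[name].ravel()

    def add(self, name: str, values: np.ndarray) -> None:
        self._arrays[name] = np.atleast_2d(np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Long table (chain, iter, parameter, value)."""
        rows = []
        for name, arr in self._arrays.items():
            c, it = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), it),
                "iter": np.tile(np.arange(it), c),
                "parameter": name,
                "value": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Draws":
        arrays = {}
        for name, g in df.groupby("parameter", sort=False):
            piv = g.pivot(index="chain", columns="iter", values="value")
            arrays[name] = piv.to_numpy()
        return cls(arrays)


def summarize(draws: Draws, names: list[str] | None = None) -> pd.DataFrame:
    """Median, equal-tailed 95% CI, split-R-hat and nonzero flag per parameter."""
    names = draws.names if names is None else names
    rows = []
    for name in names:
        arr = draws[name]
        flat = arr.ravel()
        lo, med, hi = np.percentile(flat, [2.5, 50.0, 97.5])
        rows.append({
            "parameter": name,
            "median": med,
            "ci_lower": lo,
            "ci_upper": hi,
            "n_draws": flat.size,
            "psr": split_rhat(arr),
            "nonzero": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)


def derived_per_draw(draws: Draws, expression, name: str = "derived") -> np.ndarray:
    """Evaluate an expression draw-by-draw over named parameters.

    `expression` is either a callable receiving a dict of (chains, iters)
    arrays, or a string evaluated with the parameter arrays in scope (numpy
    available as ``np``). Returns the (chains, iters) array and registers it
    on `draws` under `name`.
    """
    if callable(expression):
        out = expression({k: draws[k] for k in draws.names})
    else:
        out = eval(expression, {"np": np, "__builtins__": {}},
                   {k: draws[k] for k in draws.names})
    out = np.broadcast_to(np.asarray(out, dtype=float),
                          next(iter(draws._arrays.values())).shape).copy()
    draws.add(name, out)
    return out
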