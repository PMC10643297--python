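"""Post-simulation statistics: smoothing, uncertainty bands and scenario
comparison.

Replicate trajectories are smoothed with a centred moving average, summarised
per year by their mean and empirical 5 %/95 % quantiles across replications,
and compared between scenarios with per-year Welch two-sample tests under a
Bonferroni correction over the whole comparison family (years x scenario
pairs), so the family-wise error of declaring any spurious scenario
difference stays at the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["moving_average", "ci_bands", "bonferroni_compare", "period_summary",
           "scenario_table", "plot_bands"]


def moving_average(series, window: int = 3):
    """Centred moving average with a window that shrinks at the edges.

    Each point is replaced by the mean of the values inside the centred
    window that fall within the series, so the output has the same length
    and a constant series is a fixed point.  ``window`` must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(series, dtype=float)
    if window == 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def ci_bands(replicates, lo: float = 0.05, hi: float = 0.95) -> pd.DataFrame:
    """Per-year mean and empirical quantile band across replicate series.

    ``replicates`` is an array-like of shape (n_replicates, n_years).
    Returns a frame with columns mean, lower, upper (lower <= mean is not
    guaranteed by quantiles in pathological cases, but lower <= upper is).
    """
    arr = np.atleast_2d(np.asarray(replicates, dtype=float))
    return pd.DataFrame({
        "mean": arr.mean(axis=0),
        "lower": np.quantile(arr, lo, axis=0),
        "upper": np.quantile(arr, hi, axis=0),
    })


@dataclass(frozen=True)
class ComparisonResult:
    """Per-year raw and Bonferroni-adjusted p-values and overall verdict."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    family_size: int
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(np.any(self.p_adjusted < self.alpha))


def bonferroni_compare(reps_a, reps_b, alpha: float = 0.05, window: int = 3,
                       family_size: int | None = None) -> ComparisonResult:
    """Compare two scenarios' replicate trajectories year by year.

    Each replicate series is smoothed by the moving average, then a Welch
    two-sample t-test is run per year and the p-values are Bonferroni
    adjusted: p_adj = min(1, m * p) with m the size of the simultaneous
    comparison family (defaults to the number of years here; pass the full
    years x pairs count when comparing several scenario pairs at once).
    The pair differs significantly if any adjusted p falls below alpha.
    """
    a = np.atleast_2d(np.asarray(reps_a, dtype=float))
    b = np.atleast_2d(np.asarray(reps_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("scenario replicate sets must cover the same years")
    a = np.apply_along_axis(moving_average, 1, a, window)
    b = np.apply_along_axis(moving_average, 1, b, window)
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p_raw = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    m = family_size if family_size is not None else a.shape[1]
    p_adj = np.minimum(1.0, m * p_raw)
    return ComparisonResult(p_raw, p_adj, m, alpha)


def period_summary(replicates) -> dict:
    """Median and range of per-replicate means over the whole period (the
    box-plot summary appended to trend figures)."""
    arr = np.atleast_2d(np.asarray(replicates, dtype=float))
    per_rep = arr.mean(axis=1)
    return {"median": float(np.median(per_rep)),
            "min": float(per_rep.min()), "max": float(per_rep.max()),
            "range": float(per_rep.max() - per_rep.min())}


def _pivot(records: pd.DataFrame, scenario: str, variable: str,
           farm_type: str = "all") -> np.ndarray:
    sub = records[(records["scenario"] == scenario)
                  & (records["variable"] == variable)
                  & (records["farm_type"] == farm_type)]
    wide = sub.pivot(index="replication", columns="year", values="value")
    return wide.to_numpy()


def scenario_table(records: pd.DataFrame, variables=None, farm_type="all",
                   alpha=0.05, window=3) -> pd.DataFrame:
    """All pairwise scenario comparisons for the given variables.

    The Bonferroni family is the full batch: years x scenario pairs x
    variables.  Returns one row per (variable, pair) with the minimum
    adjusted p and the verdict.
    """
    scenarios = sorted(records["scenario"].unique())
    variables = variables or sorted(records["variable"].unique())
    pairs = [(a, b) for i, a in enumerate(scenarios) for b in scenarios[i + 1:]]
    n_years = records["year"].nunique()
    m = n_years * len(pairs) * len(variables)
    rows = []
    for var in variables:
        for a, b in pairs:
            cmp = bonferroni_compare(_pivot(records, a, var, farm_type),
                                     _pivot(records, b, var, farm_type),
                                     alpha=alpha, window=window, family_size=m)
            rows.append({"variable": var, "scenario_a": a, "scenario_b": b,
                         "min_p_adjusted": float(cmp.p_adjusted.min()),
                         "significant": cmp.significant})
    return pd.DataFrame(rows)


def plot_bands(records: pd.DataFrame, variable: str, path, farm_type="all",
               window: int = 3):
    """Publication-style trend plot: smoothed scenario means with 5 %/95 %
    bands, one line set per scenario; saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for scen in sorted(records["scenario"].unique()):
        arr = _pivot(records, scen, variable, farm_type)
        arr = np.apply_along_axis(moving_average, 1, arr, window)
        bands = ci_bands(arr)
        years = np.arange(arr.shape[1])
        line, = ax.plot(years, bands["mean"], label=scen)
        ax.plot(years, bands["lower"], color=line.get_color(), alpha=0.4, lw=0.8)
        ax.plot(years, bands["upper"], color=line.get_color(), alpha=0.4, lw=0.8)
    ax.set_xlabel("simulation year")
    ax.set_ylabel(variable)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
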