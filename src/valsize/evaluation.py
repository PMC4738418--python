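"""Bias / precision / coverage summaries of resampling results.

Implements the standard simulation-study evaluation quantities: percent
bias (mean and median), standardized bias, root mean square error,
coverage of the nominal confidence interval with its acceptable Monte
Carlo band, mean CI width, and the proportion of replicates whose estimate
falls within a relative tolerance of the true value.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from .measures import MEASURE_NAMES

__all__ = [
    "DEFAULT_TOLERANCES",
    "percent_bias",
    "median_percent_bias",
    "standardized_bias",
    "median_standardized_bias",
    "rmse",
    "coverage",
    "mean_ci_width",
    "within_tolerance",
    "summarize",
]

#: Relative tolerances (percent) for the proportion-within summaries.
DEFAULT_TOLERANCES = (0.5, 2.5, 5.0, 10.0)


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def percent_bias(estimates, theta: float) -> float:
    """``100 * (mean(estimates) - theta) / theta``; NaN when theta == 0."""
    est = _clean(estimates)
    if theta == 0 or est.size == 0:
        return math.nan
    return 100.0 * (est.mean() - theta) / theta


def median_percent_bias(estimates, theta: float) -> float:
    est = _clean(estimates)
    if theta == 0 or est.size == 0:
        return math.nan
    return 100.0 * (float(np.median(est)) - theta) / theta


def standardized_bias(estimates, theta: float) -> float:
    """Raw bias as a percentage of the empirical SE (SD over replicates).

    -25 means the average estimate sits a quarter of a standard error
    below the true value. Undefined (NaN) when the replicate SD is zero.
    """
    est = _clean(estimates)
    if est.size < 2:
        return math.nan
    sd = est.std(ddof=1)
    if sd == 0:
        return math.nan
    return 100.0 * (est.mean() - theta) / sd


def median_standardized_bias(estimates, theta: float) -> float:
    est = _clean(estimates)
    if est.size < 2:
        return math.nan
    sd = est.std(ddof=1)
    if sd == 0:
        return math.nan
    return 100.0 * (float(np.median(est)) - theta) / sd


def rmse(estimates, theta: float) -> float:
    """``sqrt(mean((estimate - theta)^2))`` over non-missing replicates."""
    est = _clean(estimates)
    if est.size == 0:
        return math.nan
    return float(np.sqrt(np.mean((est - theta) ** 2)))


def coverage(
    estimates, ses, theta: float, level: float = 0.95, b: int | None = None
) -> tuple[float, float, float]:
    """Wald-CI coverage plus the acceptable Monte Carlo band.

    Returns ``(proportion, band_low, band_high)`` where the band is
    ``level +/- 2 * sqrt(level * (1 - level) / B)`` and B defaults to the
    number of replicates with both an estimate and an SE.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    good = np.isfinite(est) & np.isfinite(se)
    n_used = int(good.sum())
    if n_used == 0:
        return math.nan, math.nan, math.nan
    z = norm.ppf(0.5 + level / 2.0)
    lo = est[good] - z * se[good]
    hi = est[good] + z * se[good]
    prop = float(np.mean((lo <= theta) & (theta <= hi)))
    b = n_used if b is None else b
    half = 2.0 * math.sqrt(level * (1.0 - level) / b)
    return prop, level - half, level + half


def mean_ci_width(ses, level: float = 0.95) -> float:
    """``mean(2 * z_{1-alpha/2} * SE)`` over non-missing SEs."""
    se = _clean(ses)
    if se.size == 0:
        return math.nan
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.mean(2.0 * z * se))


def within_tolerance(estimates, theta: float, tolerances=DEFAULT_TOLERANCES) -> dict[float, float]:
    """Proportion of replicates with ``|estimate - theta| <= x% * |theta|``."""
    est = _clean(estimates)
    out: dict[float, float] = {}
    for x in tolerances:
        if theta == 0 or est.size == 0:
            out[x] = math.nan
        else:
            out[x] = float(np.mean(np.abs(est - theta) <= (x / 100.0) * abs(theta)))
    return out


_BASE_COLUMNS = [
    "measure",
    "events",
    "n_replicates",
    "n_used",
    "n_missing",
    "mean_estimate",
    "percent_bias",
    "median_percent_bias",
    "standardized_bias",
    "median_standardized_bias",
    "rmse",
    "empirical_se",
    "mean_model_se",
    "coverage",
    "coverage_low",
    "coverage_high",
    "coverage_acceptable",
    "mean_ci_width",
]


def summarize(
    results,
    theta: dict[str, float],
    *,
    level: float = 0.95,
    tolerances=DEFAULT_TOLERANCES,
) -> pd.DataFrame:
    """Long-format evaluation table: one row per measure x event count.

    ``results`` is an iterable of :class:`~valsize.resampling.ScenarioResult`
    (or anything with ``spec.events`` and a replicate ``table``); ``theta``
    maps measure names to true values. Coverage cells stay NaN for
    measures whose replicate SEs are entirely missing rather than being
    invented.
    """
    columns = _BASE_COLUMNS + [f"within_{x:g}pct" for x in tolerances]
    rows = []
    for res in results:
        table = res.table
        for name in MEASURE_NAMES:
            if name not in table.columns:
                continue
            est = table[name].to_numpy(dtype=float)
            se = table[f"{name}_se"].to_numpy(dtype=float)
            th = theta.get(name, math.nan)
            good = np.isfinite(est)
            cov, cov_lo, cov_hi = coverage(est, se, th, level)
            row = {
                "measure": name,
                "events": res.spec.events,
                "n_replicates": len(table),
                "n_used": int(good.sum()),
                "n_missing": int((~good).sum()),
                "mean_estimate": float(est[good].mean()) if good.any() else math.nan,
                "percent_bias": percent_bias(est, th),
                "median_percent_bias": median_percent_bias(est, th),
                "standardized_bias": standardized_bias(est, th),
                "median_standardized_bias": median_standardized_bias(est, th),
                "rmse": rmse(est, th),
                "empirical_se": float(est[good].std(ddof=1)) if good.sum() > 1 else math.nan,
                "mean_model_se": float(np.nanmean(se)) if np.isfinite(se).any() else math.nan,
                "coverage": cov,
                "coverage_low": cov_lo,
                "coverage_high": cov_hi,
                "coverage_acceptable": (cov_lo <= cov <= cov_hi) if np.isfinite(cov) else math.nan,
                "mean_ci_width": mean_ci_width(se, level),
            }
            for x, prop in within_tolerance(est, th, tolerances).items():
                row[f"within_{x:g}pct"] = prop
            rows.append(row)
    return pd.DataFrame(rows, columns=columns).sort_values(["measure", "events"]).reset_index(
        drop=True
    )


def plot_summary(summary: pd.DataFrame, metric: str, *, ax=None):
    """Quick look at one evaluation metric against the event grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, grp in summary.groupby("measure"):
        ax.plot(grp["events"], grp[metric], marker="o", label=name)
    ax.set_xscale("log")
    ax.set_xlabel("number of events")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    return ax
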