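"""Validation performance measures for time-to-event prognostic models.

Implements the six measures used throughout the package -- Harrell's
c-index, the prognostic-separation D statistic, its explained-variation
transform R2_D, explained randomness rho2_OXS, the IPCW Brier score at a
fixed horizon, and the calibration slope -- together with the survival
primitives they need (single-covariate Cox fit, Kaplan-Meier estimate of
the censoring distribution) and a smoothed calibration curve.

Conventions
-----------
* Orientation: a higher prognostic index means higher risk, i.e. shorter
  survival. Concordance is counted accordingly, so informative models score
  above 0.5.
* Cox ties use the Efron correction.
* Confidence intervals are Wald intervals on the natural scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import stats as _sps

from ._concordance import concordance_counts
from ._cox import CoxDivergenceError, CoxFit, cox_fit_single

__all__ = [
    "KAPPA",
    "SIGMA2",
    "MEASURE_NAMES",
    "MeasureEstimate",
    "MeasureSet",
    "StepFunction",
    "CalibrationCurve",
    "cox_fit_single",
    "CoxFit",
    "CoxDivergenceError",
    "km_censoring",
    "km_survival",
    "harrell_c",
    "normal_order_scores",
    "d_statistic",
    "r2_from_d",
    "r2_se_from_d",
    "explained_randomness",
    "brier_score",
    "calibration_slope",
    "calibration_curve",
    "compute_all",
]

logger = logging.getLogger(__name__)

#: Scaling constant of the D statistic, sqrt(8/pi) ~= 1.596.
KAPPA: float = math.sqrt(8.0 / math.pi)

#: Variance constant of the R2_D formula, pi^2/6 ~= 1.645.
SIGMA2: float = math.pi**2 / 6.0

MEASURE_NAMES = ("c_index", "d_stat", "r2_d", "rho2_oxs", "brier", "cal_slope")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasureEstimate:
    """Point estimate of one performance measure with optional Wald CI."""

    name: str
    estimate: float
    se: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_boot_failed: int = 0

    def with_ci(self, level: float = 0.95) -> "MeasureEstimate":
        """Return a copy with a Wald interval ``estimate +/- z * se``."""
        if not np.isfinite(self.se):
            return self
        z = _sps.norm.ppf(0.5 + level / 2.0)
        return replace(
            self, ci_low=self.estimate - z * self.se, ci_high=self.estimate + z * self.se
        )


@dataclass
class MeasureSet:
    """One :class:`MeasureEstimate` per measure name."""

    c_index: MeasureEstimate | None = None
    d_stat: MeasureEstimate | None = None
    r2_d: MeasureEstimate | None = None
    rho2_oxs: MeasureEstimate | None = None
    brier: MeasureEstimate | None = None
    cal_slope: MeasureEstimate | None = None

    def __iter__(self) -> Iterator[MeasureEstimate]:
        for name in MEASURE_NAMES:
            est = getattr(self, name)
            if est is not None:
                yield est

    def __getitem__(self, name: str) -> MeasureEstimate:
        if name not in MEASURE_NAMES:
            raise KeyError(name)
        est = getattr(self, name)
        if est is None:
            raise KeyError(name)
        return est

    def theta_dict(self) -> dict[str, float]:
        """Measure name -> point estimate (for use as true values)."""
        return {m.name: m.estimate for m in self}

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            m.name: {
                "estimate": m.estimate,
                "se": m.se,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
            }
            for m in self
        }


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous non-increasing step function starting at 1.

    ``knots`` are the (sorted) times where the function drops; ``values``
    are the function values at the knots (i.e. just after the drop).
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "knots", np.asarray(self.knots, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.knots.ndim != 1 or self.knots.shape != self.values.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    def __call__(self, t):
        """Evaluate at ``t`` (right-continuous)."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate(([1.0], self.values))
        return vals[idx]

    def left(self, t):
        """Left limit at ``t``."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate(([1.0], self.values))
        return vals[idx]


@dataclass(frozen=True)
class CalibrationCurve:
    """Observed-vs-predicted event probabilities at a fixed horizon."""

    predicted: np.ndarray
    observed: np.ndarray
    method: str  # "spline_cox" or "decile_km"
    horizon: float


# ---------------------------------------------------------------------------
# survival primitives
# ---------------------------------------------------------------------------


def _product_limit(time, indicator) -> StepFunction:
    """Kaplan-Meier product-limit estimator for the given 'event' indicator.

    At tied times all subjects with ``time >= t`` count as at risk; no
    ordering convention between the two kinds of endpoints is applied.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(indicator)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    uniq, start = np.unique(t, return_index=True)
    n = t.shape[0]
    at_risk = n - start
    events = np.add.reduceat(d.astype(float), start)
    mask = events > 0
    if not np.any(mask):
        return StepFunction(np.empty(0), np.empty(0))
    factors = 1.0 - events[mask] / at_risk[mask]
    return StepFunction(uniq[mask], np.cumprod(factors))


def km_survival(time, event) -> StepFunction:
    """Kaplan-Meier estimate of the event-time survival function."""
    return _product_limit(time, np.asarray(event).astype(int))


def km_censoring(time, event) -> StepFunction:
    """Kaplan-Meier estimate of the censoring survival function G.

    Computed from ``(t_i, 1 - delta_i)``: censorings are treated as the
    events of interest and events as censored observations.
    """
    return _product_limit(time, 1 - np.asarray(event).astype(int))


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


def harrell_c(pi, time, event, *, presorted: bool = False, level: float = 0.95) -> MeasureEstimate:
    """Harrell's c-index for right-censored data with a Noether-type SE.

    Pairs are usable when the member with the shorter follow-up time had the
    event (or, at tied times, exactly one member had the event). A usable
    pair is concordant when the earlier event carries the higher prognostic
    index; prediction ties count one half.

    The standard error is the asymptotic U-statistic (Noether-type)
    estimator for Somers' d rescaled to the c scale, i.e. the approach of
    the classical concordance routines for censored data.
    """
    counts = concordance_counts(pi, time, event, presorted=presorted)
    usable = counts["usable"]
    if usable == 0:
        raise ValueError("no usable pairs: c-index undefined")
    c = (counts["concordant"] + 0.5 * counts["tied_risk"]) / usable
    dxy = (counts["concordant"] - counts["discordant"]) / usable
    resid = counts["w"] - dxy * counts["r"]
    var_d = float(np.sum(resid * resid)) / usable**2
    se_c = math.sqrt(var_d) / 2.0
    return MeasureEstimate("c_index", c, se_c).with_ci(level)


def normal_order_scores(pi) -> np.ndarray:
    """Rank-based expected-normal-order-score transform, scaled by 1/kappa.

    Uses the Blom approximation ``Phi^-1((r - 3/8) / (n + 1/4))`` of the
    expected standard normal order statistics; tied values receive the
    average of their positions' scores. The result is divided by
    ``kappa = sqrt(8/pi)``.
    """
    p = np.asarray(pi, dtype=float)
    n = p.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    scores = _sps.norm.ppf((ranks - 0.375) / (n + 0.25))
    sorted_p = p[order]
    # average scores within tie groups
    boundaries = np.flatnonzero(np.r_[True, sorted_p[1:] != sorted_p[:-1]])
    group_sum = np.add.reduceat(scores, boundaries)
    group_len = np.diff(np.r_[boundaries, n])
    averaged = np.repeat(group_sum / group_len, group_len)
    out = np.empty(n)
    out[order] = averaged / KAPPA
    return out


def d_statistic(pi, time, event, *, presorted: bool = False, level: float = 0.95) -> MeasureEstimate:
    """Prognostic-separation D statistic.

    The prognostic index is replaced by its scaled normal order scores and
    fitted as the single covariate of a Cox model; D and its SE are the
    resulting coefficient and standard error.
    """
    z = normal_order_scores(pi)
    fit = cox_fit_single(z, time, event, presorted=presorted)
    if not fit.converged:
        raise CoxDivergenceError("D-statistic Cox fit diverged")
    return MeasureEstimate("d_stat", fit.beta, fit.se_beta).with_ci(level)


def r2_from_d(d: float) -> float:
    """Explained-variation transform of the D statistic.

    ``R2 = (D^2/kappa^2) / (sigma^2 + D^2/kappa^2)`` with
    ``kappa^2 = 8/pi`` and ``sigma^2 = pi^2/6``.
    """
    q = d * d / (KAPPA * KAPPA)
    return q / (SIGMA2 + q)


def r2_se_from_d(d: float, se_d: float) -> float:
    """Delta-method standard error of ``r2_from_d`` given D and SE(D)."""
    k2 = KAPPA * KAPPA
    denom = SIGMA2 + d * d / k2
    deriv = (2.0 * d * SIGMA2 / k2) / (denom * denom)
    return abs(deriv) * se_d


# ---------------------------------------------------------------------------
# explained randomness and Brier score
# ---------------------------------------------------------------------------


def _bootstrap_se(statistic, n, n_boot, rng) -> tuple[float, int]:
    """SE of ``statistic(idx)`` under row resampling with replacement.

    Replicates where the statistic raises or returns non-finite values are
    skipped and counted.
    """
    vals = np.empty(n_boot)
    failed = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(idx)
        except (ValueError, CoxDivergenceError, ZeroDivisionError):
            failed += 1
            continue
        if not np.isfinite(v):
            failed += 1
            continue
        vals[kept] = v
        kept += 1
    if kept < 2:
        return math.nan, failed
    return float(np.std(vals[:kept], ddof=1)), failed


def explained_randomness(
    pi,
    time,
    event,
    *,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    _fit: CoxFit | None = None,
) -> MeasureEstimate:
    """Explained randomness ``rho2 = 1 - exp(-(2/k)(l_beta - l_0))``.

    ``k`` is the number of events; ``l_beta`` and ``l_0`` are the log
    partial likelihoods of the refitted single-covariate Cox model on the
    prognostic index and of the null model. The SE is a nonparametric
    bootstrap over rows (default 200 replications); pass ``n_boot=0`` to
    skip it.
    """
    pi = np.asarray(pi, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    k = int(event.sum())
    if k < 1:
        raise ValueError("explained randomness requires at least one event")

    def _rho2(p, t, d, fit=None):
        fit = fit or cox_fit_single(p, t, d)
        if not fit.converged:
            raise CoxDivergenceError("Cox fit diverged")
        kk = int(np.asarray(d).sum())
        return 1.0 - math.exp(-(2.0 / kk) * (fit.loglik - fit.loglik_null))

    est = _rho2(pi, time, event, _fit)
    se, failed = math.nan, 0
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        se, failed = _bootstrap_se(
            lambda idx: _rho2(pi[idx], time[idx], event[idx]), pi.shape[0], n_boot, rng
        )
    return MeasureEstimate("rho2_oxs", est, se, n_boot_failed=failed).with_ci(level)


def brier_score(
    risk10,
    time,
    event,
    t: float = 10.0,
    *,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
    left_limit: bool = True,
    level: float = 0.95,
) -> MeasureEstimate:
    """Inverse-probability-of-censoring-weighted Brier score at horizon t.

    ``BS(t) = (1/n) sum_i [ S_i^2 I(t_i <= t, d_i = 1)/G(t_i) +
    (1 - S_i)^2 I(t_i > t)/G(t) ]`` with ``S_i = 1 - risk10_i`` the
    predicted survival probability and G the Kaplan-Meier estimate of the
    censoring distribution.

    Parameters
    ----------
    left_limit : bool
        Evaluate G at ``t_i-`` in the first term (standard IPCW
        convention, default) rather than at ``t_i``.
    n_boot : int
        Nonparametric bootstrap replications for the SE; 0 skips the SE.
    """
    risk = np.asarray(risk10, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)

    def _bs(r, tt, dd):
        G = km_censoring(tt, dd)
        g_t = float(G(t))
        if g_t <= 0.0:
            raise ValueError(f"censoring survival is zero at horizon t={t}; Brier undefined")
        surv = 1.0 - r
        had_event = (tt <= t) & (dd == 1)
        still_in = tt > t
        g_ti = G.left(tt[had_event]) if left_limit else G(tt[had_event])
        if np.any(g_ti <= 0.0):
            raise ValueError("censoring survival is zero before an observed event")
        total = float(np.sum(surv[had_event] ** 2 / g_ti))
        total += float(np.sum((1.0 - surv[still_in]) ** 2)) / g_t
        return total / r.shape[0]

    est = _bs(risk, time, event)
    se, failed = math.nan, 0
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        se, failed = _bootstrap_se(
            lambda idx: _bs(risk[idx], time[idx], event[idx]), risk.shape[0], n_boot, rng
        )
    return MeasureEstimate("brier", est, se, n_boot_failed=failed).with_ci(level)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibration_slope(
    pi, time, event, *, presorted: bool = False, level: float = 0.95, _fit: CoxFit | None = None
) -> MeasureEstimate:
    """Calibration slope: Cox coefficient of the prognostic index.

    A slope below 1 means the model's risk ordering is too extreme in the
    validation data; above 1, too conservative.
    """
    fit = _fit or cox_fit_single(pi, time, event, presorted=presorted)
    if not fit.converged:
        raise CoxDivergenceError("calibration-slope Cox fit diverged")
    return MeasureEstimate("cal_slope", fit.beta, fit.se_beta).with_ci(level)


def _natural_spline_basis(x, knots, boundary):
    """Natural cubic spline basis (no intercept), R ``ns()`` construction."""
    b0, b1 = boundary

    def dd(xi, knot):
        return (np.clip(xi - knot, 0, None) ** 3 - np.clip(xi - b1, 0, None) ** 3) / (b1 - knot)

    cols = [x]
    for k in knots:
        cols.append(dd(x, k) - dd(x, b0))
    return np.column_stack(cols)


def calibration_curve(
    risk10,
    time,
    event,
    t: float = 10.0,
    grid=None,
    *,
    df: int = 4,
    min_events: int = 15,
) -> CalibrationCurve:
    """Smoothed observed event probability at horizon t vs predicted risk.

    A Cox model is fitted on a natural-cubic-spline basis (``df`` degrees of
    freedom) of ``cloglog(risk10)`` and its fitted survival at ``t`` gives
    the observed probability over the grid. This is a deliberately simple
    stand-in for adaptive hazard regression. When the fit is degenerate
    (too few events, no risk spread, or non-convergence) the estimator
    falls back to Kaplan-Meier observed risks within deciles of predicted
    risk; the fallback is logged, never silent.
    """
    risk = np.clip(np.asarray(risk10, dtype=float), 1e-12, 1 - 1e-12)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.unique(risk).size < 2:
        raise ValueError("calibration curve requires at least two distinct predicted risks")
    if grid is None:
        grid = np.quantile(risk, np.linspace(0.02, 0.98, 49))
    grid = np.asarray(grid, dtype=float)

    if int(event.sum()) >= min_events:
        try:
            return _spline_cox_curve(risk, time, event, t, grid, df)
        except Exception as exc:  # degenerate fit of any flavour
            logger.warning("spline calibration fit failed (%s); falling back to decile KM", exc)
    else:
        logger.warning(
            "only %d events (< %d); falling back to decile-KM calibration", event.sum(), min_events
        )
    return _decile_km_curve(risk, time, event, t)


def _spline_cox_curve(risk, time, event, t, grid, df):
    import pandas as pd
    from lifelines import CoxPHFitter

    z = np.log(-np.log(1.0 - risk))
    qs = np.linspace(0, 1, df + 1)[1:-1]
    knots = np.quantile(z, qs)
    boundary = (z.min(), z.max())
    basis = _natural_spline_basis(z, knots, boundary)
    # standardize columns: raw truncated-cube columns are badly scaled and
    # nearly collinear, which stalls the Newton iterations
    center = basis.mean(axis=0)
    spread = basis.std(axis=0)
    spread[spread == 0] = 1.0
    basis = (basis - center) / spread
    frame = pd.DataFrame(basis, columns=[f"b{i}" for i in range(basis.shape[1])])
    frame["T"] = time
    frame["E"] = event
    cph = CoxPHFitter(penalizer=1e-5)
    cph.fit(frame, duration_col="T", event_col="E")
    zg = np.log(-np.log(1.0 - np.clip(grid, 1e-12, 1 - 1e-12)))
    basis_g = (_natural_spline_basis(zg, knots, boundary) - center) / spread
    newdata = pd.DataFrame(basis_g, columns=[f"b{i}" for i in range(basis_g.shape[1])])
    surv = cph.predict_survival_function(newdata, times=[t]).to_numpy().ravel()
    observed = 1.0 - surv
    if not np.all(np.isfinite(observed)):
        raise ValueError("non-finite fitted probabilities")
    return CalibrationCurve(grid, observed, "spline_cox", t)


def _decile_km_curve(risk, time, event, t):
    edges = np.unique(np.quantile(risk, np.linspace(0, 1, 11)))
    bins = np.clip(np.searchsorted(edges, risk, side="right") - 1, 0, len(edges) - 2)
    preds, obs = [], []
    for b in range(len(edges) - 1):
        sel = bins == b
        if not np.any(sel):
            continue
        preds.append(float(risk[sel].mean()))
        obs.append(1.0 - float(km_survival(time[sel], event[sel])(t)))
    return CalibrationCurve(np.asarray(preds), np.asarray(obs), "decile_km", t)


# ---------------------------------------------------------------------------
# one-shot evaluation
# ---------------------------------------------------------------------------


def compute_all(
    cohort,
    *,
    horizon: float = 10.0,
    bootstrap_reps: int = 0,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    measures=MEASURE_NAMES,
) -> MeasureSet:
    """Compute the requested measures on a cohort.

    Degenerate fits raise; callers running replicate loops should catch
    ``ValueError``/``CoxDivergenceError`` per measure (see
    :mod:`valsize.resampling`). ``bootstrap_reps`` controls the bootstrap
    SEs of rho2_OXS and the Brier score (0 leaves them without SEs).
    """
    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    d = cohort.event[order]
    pi = cohort.pi[order]
    risk = cohort.risk10[order]
    rng = rng or np.random.default_rng()
    out = MeasureSet()

    fit = None
    if "cal_slope" in measures or "rho2_oxs" in measures:
        fit = cox_fit_single(pi, t, d, presorted=True)
    if "cal_slope" in measures:
        out.cal_slope = calibration_slope(pi, t, d, presorted=True, level=level, _fit=fit)
    if "rho2_oxs" in measures:
        out.rho2_oxs = explained_randomness(
            pi, t, d, n_boot=bootstrap_reps, rng=rng, level=level, _fit=fit
        )
    if "d_stat" in measures or "r2_d" in measures:
        dst = d_statistic(pi, t, d, presorted=True, level=level)
        if "d_stat" in measures:
            out.d_stat = dst
        if "r2_d" in measures:
            out.r2_d = MeasureEstimate(
                "r2_d", r2_from_d(dst.estimate), r2_se_from_d(dst.estimate, dst.se)
            ).with_ci(level)
    if "c_index" in measures:
        out.c_index = harrell_c(pi, t, d, presorted=True, level=level)
    if "brier" in measures:
        out.brier = brier_score(
            risk, t, d, horizon, n_boot=bootstrap_reps, rng=rng, level=level
        )
    return out
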