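"""Fixed-event-count stratified resampling with replacement.

Each replicate draws a fixed number of events plus the matching number of
non-events (so the sample event fraction equals the population fraction),
computes all performance measures, and streams replicate-level rows to
disk. Seeding is counter-based: any replicate can be regenerated in
isolation from ``(scenario seed, replicate index)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import measures
from .cohort import Cohort
from .measures import MEASURE_NAMES, CoxDivergenceError

__all__ = [
    "DEFAULT_EVENT_GRID",
    "ScenarioSpec",
    "ScenarioResult",
    "nonevent_count",
    "draw_fixed_event_sample",
    "run_scenario",
    "run_grid",
    "make_grid",
    "se_comparison_study",
]

logger = logging.getLogger(__name__)

#: Event-count grid of the full design.
DEFAULT_EVENT_GRID = (5, 10, 25, 50, 75, 100, 150, 200, 300, 400, 500, 1000)


@dataclass(frozen=True)
class ScenarioSpec:
    """One resampling scenario: a fixed event count and replicate budget."""

    events: int
    replicates: int = 10000
    seed: int = 0
    bootstrap_reps: int = 200

    def __post_init__(self):
        if self.events < 1:
            raise ValueError("events must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


@dataclass
class ScenarioResult:
    """Replicate-level estimates and SEs for one scenario."""

    spec: ScenarioSpec
    table: pd.DataFrame
    missing: dict[str, int] = field(default_factory=dict)
    path: str | None = None


def nonevent_count(events: int, p: float) -> int:
    """Non-events per replicate: ``round(events * (1-p)/p)`` (half-to-even)."""
    if not 0.0 < p < 1.0:
        raise ValueError("event fraction must lie in (0, 1)")
    return int(round(events * (1.0 - p) / p))


def draw_fixed_event_sample(population: Cohort, events: int, rng: np.random.Generator) -> Cohort:
    """Stratified with-replacement sample with a fixed number of events."""
    ev_idx = np.flatnonzero(population.event == 1)
    nev_idx = np.flatnonzero(population.event == 0)
    if ev_idx.size == 0 or nev_idx.size == 0:
        raise ValueError("population must contain both events and non-events")
    m = nonevent_count(events, population.event_fraction)
    idx = np.concatenate(
        [
            ev_idx[rng.integers(0, ev_idx.size, size=events)],
            nev_idx[rng.integers(0, nev_idx.size, size=m)],
        ]
    )
    return population.subset(idx)


def _replicate_rng(scenario_seed: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario_seed, spawn_key=(b,)))


_NAN_ROW = {f"{name}{suffix}": math.nan for name in MEASURE_NAMES for suffix in ("", "_se")}


def _replicate_row(sample: Cohort, spec: ScenarioSpec, rng, horizon, which) -> dict:
    row = dict(_NAN_ROW)
    row["n"] = sample.n
    row["n_events"] = sample.n_events
    order = np.argsort(sample.time, kind="stable")
    t = sample.time[order]
    d = sample.event[order]
    pi = sample.pi[order]
    risk = sample.risk10[order]

    fit = None
    if "cal_slope" in which or "rho2_oxs" in which:
        try:
            fit = measures.cox_fit_single(pi, t, d, presorted=True)
            if not fit.converged:
                fit = None
        except ValueError:
            fit = None
    if "cal_slope" in which and fit is not None:
        row["cal_slope"] = fit.beta
        row["cal_slope_se"] = fit.se_beta
    if "rho2_oxs" in which and fit is not None:
        try:
            est = measures.explained_randomness(
                pi, t, d, n_boot=spec.bootstrap_reps, rng=rng, _fit=fit
            )
            row["rho2_oxs"], row["rho2_oxs_se"] = est.estimate, est.se
        except (ValueError, CoxDivergenceError):
            pass
    if "d_stat" in which or "r2_d" in which:
        try:
            est = measures.d_statistic(pi, t, d, presorted=True)
            if "d_stat" in which:
                row["d_stat"], row["d_stat_se"] = est.estimate, est.se
            if "r2_d" in which:
                row["r2_d"] = measures.r2_from_d(est.estimate)
                row["r2_d_se"] = measures.r2_se_from_d(est.estimate, est.se)
        except (ValueError, CoxDivergenceError):
            pass
    if "c_index" in which:
        try:
            est = measures.harrell_c(pi, t, d, presorted=True)
            row["c_index"], row["c_index_se"] = est.estimate, est.se
        except ValueError:
            pass
    if "brier" in which:
        try:
            est = measures.brier_score(risk, t, d, horizon, n_boot=spec.bootstrap_reps, rng=rng)
            row["brier"], row["brier_se"] = est.estimate, est.se
        except ValueError:
            pass
    return row


def run_scenario(
    population: Cohort,
    spec: ScenarioSpec,
    *,
    out_path=None,
    horizon: float = 10.0,
    which=MEASURE_NAMES,
    chunk_size: int = 1000,
) -> ScenarioResult:
    """Run ``spec.replicates`` draws, computing the measures on each.

    Replicates whose fits diverge or whose measures are undefined record
    NaN for the affected measure; per-measure missingness is tallied in
    ``ScenarioResult.missing`` and never dropped silently. When
    ``out_path`` is given, rows are appended in chunks so memory stays
    bounded.
    """
    rows: list[dict] = []
    written = 0
    handle = open(out_path, "w", newline="") if out_path is not None else None
    try:
        for b in range(spec.replicates):
            rng = _replicate_rng(spec.seed, b)
            sample = draw_fixed_event_sample(population, spec.events, rng)
            row = {"replicate": b}
            row.update(_replicate_row(sample, spec, rng, horizon, which))
            rows.append(row)
            if handle is not None and len(rows) - written >= chunk_size:
                pd.DataFrame(rows[written:]).to_csv(handle, index=False, header=written == 0)
                written = len(rows)
        if handle is not None and written < len(rows):
            pd.DataFrame(rows[written:]).to_csv(handle, index=False, header=written == 0)
    finally:
        if handle is not None:
            handle.close()
    table = pd.DataFrame(rows)
    missing = {name: int(table[name].isna().sum()) for name in which}
    if any(missing.values()):
        logger.info("events=%d: missing replicate counts %s", spec.events, missing)
    return ScenarioResult(spec, table, missing, str(out_path) if out_path else None)


def make_grid(
    events_grid,
    replicates: int,
    master_seed: int,
    bootstrap_reps: int = 0,
) -> list[ScenarioSpec]:
    """Scenario specs with independent per-scenario seeds from a master seed."""
    specs = []
    for i, events in enumerate(events_grid):
        sub = np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0]
        specs.append(ScenarioSpec(int(events), replicates, int(sub), bootstrap_reps))
    return specs


def run_grid(
    population: Cohort,
    specs,
    *,
    out_dir=None,
    horizon: float = 10.0,
    which=MEASURE_NAMES,
) -> list[ScenarioResult]:
    """Map :func:`run_scenario` over a grid; scenario failures are isolated."""
    results = []
    for spec in specs:
        out_path = None
        if out_dir is not None:
            out_path = f"{out_dir}/scenario_{spec.events}.csv"
        logger.info("running scenario events=%d B=%d", spec.events, spec.replicates)
        try:
            results.append(
                run_scenario(population, spec, out_path=out_path, horizon=horizon, which=which)
            )
        except Exception:
            logger.exception("scenario events=%d failed; continuing", spec.events)
    return results


# ---------------------------------------------------------------------------
# model-based vs empirical vs bootstrap SE sub-study
# ---------------------------------------------------------------------------


def _d_fit(sample_pi, sample_t, sample_d):
    z = measures.normal_order_scores(sample_pi)
    fit = measures.cox_fit_single(z, sample_t, sample_d)
    if not fit.converged:
        raise CoxDivergenceError("divergent")
    return fit.beta, fit.se_beta


def se_comparison_study(
    population: Cohort,
    events_grid,
    *,
    n_sim: int = 1000,
    bootstrap_reps: int = 500,
    seed: int = 0,
    theta: dict[str, float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Compare model-based, empirical and bootstrap SEs of D and R2_D.

    For each event count: ``n_sim`` resampled validation sets each yield a
    model-based SE and a bootstrap SE (``bootstrap_reps`` unstratified row
    resamples); the empirical SE is the SD of the point estimates across
    the simulations. When ``theta`` supplies true values (keys ``d_stat``,
    ``r2_d``), Wald-CI coverage under the model-based and bootstrap SEs is
    reported as well.
    """
    from scipy.stats import norm

    z_crit = norm.ppf(0.5 + level / 2.0)
    records = []
    for gi, events in enumerate(events_grid):
        scen_seed = int(np.random.SeedSequence(seed, spawn_key=(gi,)).generate_state(1)[0])
        d_est = np.full(n_sim, np.nan)
        d_mse = np.full(n_sim, np.nan)
        d_bse = np.full(n_sim, np.nan)
        for s in range(n_sim):
            rng = _replicate_rng(scen_seed, s)
            sample = draw_fixed_event_sample(population, events, rng)
            order = np.argsort(sample.time, kind="stable")
            t, d, pi = sample.time[order], sample.event[order], sample.pi[order]
            try:
                z = measures.normal_order_scores(pi)
                fit = measures.cox_fit_single(z, t, d, presorted=True)
                if not fit.converged:
                    raise CoxDivergenceError("divergent")
            except (ValueError, CoxDivergenceError):
                continue
            d_est[s], d_mse[s] = fit.beta, fit.se_beta
            if bootstrap_reps > 0:
                boots = np.full(bootstrap_reps, np.nan)
                for bb in range(bootstrap_reps):
                    idx = rng.integers(0, sample.n, size=sample.n)
                    try:
                        boots[bb], _ = _d_fit(pi[idx], t[idx], d[idx])
                    except (ValueError, CoxDivergenceError):
                        continue
                good = np.isfinite(boots)
                if good.sum() >= 2:
                    d_bse[s] = np.std(boots[good], ddof=1)

        def _nanmean(arr):
            arr = np.asarray(arr, dtype=float)
            good = np.isfinite(arr)
            return float(arr[good].mean()) if good.any() else math.nan

        ok = np.isfinite(d_est)
        r2_est = measures.r2_from_d(d_est)
        r2_mse = np.array(
            [measures.r2_se_from_d(dd, ss) for dd, ss in zip(d_est, d_mse)]
        )
        rec = {
            "events": events,
            "nonevents": nonevent_count(events, population.event_fraction),
            "n_sim_used": int(ok.sum()),
            "d_model_se": _nanmean(d_mse),
            "d_empirical_se": float(np.nanstd(d_est[ok], ddof=1)),
            "d_boot_se": _nanmean(d_bse),
            "r2_model_se": _nanmean(r2_mse),
            "r2_empirical_se": float(np.nanstd(r2_est[ok], ddof=1)),
            "r2_boot_se": math.nan,
        }
        if bootstrap_reps > 0:
            # bootstrap SE of R2 via the delta factor of each simulation's D
            with np.errstate(invalid="ignore"):
                factor = np.where(np.isfinite(d_mse) & (d_mse > 0), r2_mse / d_mse, np.nan)
            rec["r2_boot_se"] = _nanmean(d_bse * factor)
        if theta is not None:
            for key, est, mse, bse in (
                ("d", theta["d_stat"], (d_est, d_mse), (d_est, d_bse)),
                ("r2", theta["r2_d"], (r2_est, r2_mse), (r2_est, d_bse * factor if bootstrap_reps else None)),
            ):
                for label, pair in (("model", mse), ("boot", bse)):
                    if pair is None or pair[1] is None:
                        rec[f"{key}_coverage_{label}"] = math.nan
                        continue
                    e, se_arr = pair
                    good = np.isfinite(e) & np.isfinite(se_arr)
                    if good.sum() == 0:
                        rec[f"{key}_coverage_{label}"] = math.nan
                        continue
                    lo = e[good] - z_crit * se_arr[good]
                    hi = e[good] + z_crit * se_arr[good]
                    rec[f"{key}_coverage_{label}"] = float(np.mean((lo <= est) & (est <= hi)))
        records.append(rec)
        logger.info("se study events=%d done", events)
    return pd.DataFrame.from_records(records)
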