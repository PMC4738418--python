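"""Synthetic survival populations with known ground truth.

Generates registry-like cohorts: correlated normal covariates drive a
Weibull proportional-hazards outcome, with exponential dropout and
administrative censoring, plus a "published model" whose coefficients may
be shrunken/inflated or perturbed so that the true calibration slope
differs from 1 in a controlled way.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import measures

__all__ = [
    "CovariateSpec",
    "TrueDataModel",
    "PrognosticModel",
    "Cohort",
    "CalibrationWarning",
    "default_covariate_spec",
    "beta_for_pi_sd",
    "generate_population",
    "calibrate_event_rate",
    "make_validation_model",
    "true_performance",
]


class CalibrationWarning(UserWarning):
    """Event-rate calibration could not reach the requested target."""


@dataclass(frozen=True)
class CovariateSpec:
    """Correlated covariates with exchangeable (copula) correlation.

    ``marginal="gaussian"`` gives multivariate-normal covariates and hence
    an exactly normal prognostic index. ``marginal="mirrored_lognormal"``
    pushes the same Gaussian copula through a standardized, sign-flipped
    lognormal transform, producing left-skewed covariates and a left-skewed
    prognostic index -- the kind of case-mix under which the model-based
    standard error of the separation statistic overestimates the sampling
    variability. For non-gaussian marginals ``correlation`` is the copula
    correlation; the realized covariate correlation is slightly weaker.
    """

    n_covariates: int
    correlation: float = 0.2
    scales: np.ndarray | None = None
    marginal: str = "gaussian"
    lognormal_sigma: float = 1.0

    def __post_init__(self):
        if self.n_covariates < 1:
            raise ValueError("n_covariates must be >= 1")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if self.marginal not in ("gaussian", "mirrored_lognormal"):
            raise ValueError("marginal must be 'gaussian' or 'mirrored_lognormal'")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        scales = self.scales
        if scales is None:
            scales = np.ones(self.n_covariates)
        scales = np.asarray(scales, dtype=float)
        if scales.shape != (self.n_covariates,) or np.any(scales <= 0):
            raise ValueError("scales must be positive, one per covariate")
        object.__setattr__(self, "scales", scales)

    def correlation_matrix(self) -> np.ndarray:
        k = self.n_covariates
        corr = np.full((k, k), self.correlation)
        np.fill_diagonal(corr, 1.0)
        return corr

    def covariance(self) -> np.ndarray:
        return self.correlation_matrix() * np.outer(self.scales, self.scales)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample an (n, k) covariate matrix."""
        # exchangeable correlation in [0,1) is always positive definite
        chol = np.linalg.cholesky(self.correlation_matrix())
        Z = rng.standard_normal((n, self.n_covariates)) @ chol.T
        if self.marginal == "mirrored_lognormal":
            sig = self.lognormal_sigma
            mean = math.exp(sig * sig / 2.0)
            sd = math.sqrt((math.exp(sig * sig) - 1.0) * math.exp(sig * sig))
            Z = -(np.exp(sig * Z) - mean) / sd
        return Z * self.scales


@dataclass(frozen=True)
class TrueDataModel:
    """Data-generating mechanism: Weibull PH outcome plus censoring.

    The conditional survival is ``S(t|x) = exp(-rate * t^shape * exp(PI))``
    with ``PI = beta_true . x``. Dropout is exponential with rate
    ``censor_rate``; everyone still in follow-up is administratively
    censored at ``admin_horizon`` years.
    """

    beta_true: np.ndarray
    baseline_shape: float = 1.1
    baseline_rate: float = 0.005
    censor_rate: float = 0.05
    admin_horizon: float = 15.0
    target_event_fraction: float = 0.054

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta_true, dtype=float))
        object.__setattr__(self, "beta_true", beta)
        for name in ("baseline_shape", "baseline_rate", "admin_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not 0.0 < self.target_event_fraction < 1.0:
            raise ValueError("target_event_fraction must lie in (0, 1)")

    def baseline_survival(self, t: float) -> float:
        """Baseline survival S0(t) = exp(-rate * t^shape), clamped to (0, 1).

        The clamp guards against floating-point underflow at extreme rates
        probed during event-rate bisection.
        """
        s = math.exp(-self.baseline_rate * t**self.baseline_shape)
        return min(max(s, 1e-300), 1.0 - 1e-16)

    def as_prognostic_model(self, horizon: float = 10.0) -> "PrognosticModel":
        """The truth itself, packaged as the model to validate."""
        return PrognosticModel(self.beta_true, self.baseline_survival(horizon))


@dataclass(frozen=True)
class PrognosticModel:
    """A published model: linear predictor plus baseline survival at 10y."""

    beta_model: np.ndarray
    s0_10: float

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta_model, dtype=float))
        object.__setattr__(self, "beta_model", beta)
        if not 0.0 < self.s0_10 < 1.0:
            raise ValueError("s0_10 must lie in (0, 1)")

    def pi(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta_model

    def risk10(self, X: np.ndarray) -> np.ndarray:
        """Predicted 10-year risk ``1 - s0_10 ** exp(PI)``, clipped to (0,1)."""
        r = 1.0 - self.s0_10 ** np.exp(self.pi(X))
        return np.clip(r, 1e-12, 1.0 - 1e-12)


@dataclass(frozen=True)
class Cohort:
    """Follow-up time (years), event indicator, prognostic index, 10y risk."""

    time: np.ndarray
    event: np.ndarray
    pi: np.ndarray
    risk10: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event).astype(np.int64)
        pi = np.asarray(self.pi, dtype=float)
        risk = np.asarray(self.risk10, dtype=float)
        n = time.shape[0]
        if not (event.shape[0] == pi.shape[0] == risk.shape[0] == n):
            raise ValueError("columns must have equal length")
        if np.any(time < 0):
            raise ValueError("negative follow-up times")
        if np.any((event != 0) & (event != 1)):
            raise ValueError("event indicator must be 0/1")
        if np.any((risk <= 0) | (risk >= 1)):
            raise ValueError("risk10 must lie strictly in (0, 1)")
        for name, arr in (("time", time), ("event", event), ("pi", pi), ("risk10", risk)):
            object.__setattr__(self, name, arr)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def event_fraction(self) -> float:
        return self.n_events / self.n

    def subset(self, idx) -> "Cohort":
        return Cohort(self.time[idx], self.event[idx], self.pi[idx], self.risk10[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "time": self.time,
                "event": self.event,
                "pi": self.pi,
                "risk10": self.risk10,
            }
        )

    def to_csv(self, path) -> None:
        # %.17g guarantees float64 round-trips exactly through text
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"time", "event", "pi", "risk10"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort file is missing columns: {sorted(missing)}")
        return cls(
            df["time"].to_numpy(), df["event"].to_numpy(), df["pi"].to_numpy(),
            df["risk10"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_BETA_PATTERN_DECAY = 0.3  # relative size of the weakest predictor


def default_covariate_spec(n_covariates: int = 8, correlation: float = 0.2) -> CovariateSpec:
    return CovariateSpec(n_covariates=n_covariates, correlation=correlation)


def beta_for_pi_sd(spec: CovariateSpec, pi_sd: float) -> np.ndarray:
    """Coefficient vector with a tapered pattern scaled so SD(PI) == pi_sd.

    Exact for gaussian marginals; for transformed marginals the implied
    covariance (and hence the achieved SD) is approximate.
    """
    if pi_sd <= 0:
        raise ValueError("pi_sd must be positive")
    pattern = np.linspace(1.0, _BETA_PATTERN_DECAY, spec.n_covariates)
    var = pattern @ spec.covariance() @ pattern
    return pattern * (pi_sd / math.sqrt(var))


def generate_population(
    spec: CovariateSpec,
    model: TrueDataModel,
    n: int,
    seed: int,
    *,
    validated: PrognosticModel | None = None,
    horizon: float = 10.0,
) -> Cohort:
    """Draw a population of size ``n`` from the data-generating model.

    Event times follow the Weibull proportional-hazards inversion
    ``T = (-log U / (rate * exp(PI)))^(1/shape)``; the observed time is the
    minimum of T, exponential dropout and the administrative horizon, with
    ``event = 1`` iff T comes first. The stored prognostic index and
    10-year risk are those of ``validated`` (default: the truth itself),
    so the cohort carries the predictions of the model under validation.

    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if model.beta_true.shape[0] != spec.n_covariates:
        raise ValueError("beta_true length must match n_covariates")
    rng = np.random.default_rng(seed)
    X = spec.draw(n, rng)
    pi_true = X @ model.beta_true
    u = rng.uniform(size=n)
    T = (-np.log(u) / (model.baseline_rate * np.exp(pi_true))) ** (1.0 / model.baseline_shape)
    if model.censor_rate > 0:
        dropout = rng.exponential(1.0 / model.censor_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(dropout, model.admin_horizon)
    time = np.minimum(T, censor)
    event = (T <= censor).astype(np.int64)
    if not np.all(np.isfinite(time)):
        raise ValueError("non-finite follow-up times; check censoring settings")
    published = validated if validated is not None else model.as_prognostic_model(horizon)
    return Cohort(time, event, published.pi(X), published.risk10(X))


def calibrate_event_rate(
    spec: CovariateSpec,
    model: TrueDataModel,
    n_pilot: int,
    seed: int,
    *,
    tol: float = 0.001,
    max_iter: int = 60,
) -> TrueDataModel:
    """Adjust ``baseline_rate`` so the pilot event fraction hits the target.

    Bisection on log baseline_rate against pilot populations regenerated
    with a fixed seed (hence monotone in the rate and fully reproducible).
    Stops when the achieved fraction is within ``tol`` (default 0.1
    percentage points) of ``model.target_event_fraction``. An unreachable
    target raises :class:`CalibrationWarning` and returns the boundary
    model, reporting the achievable bounds.
    """
    target = model.target_event_fraction

    def fraction_at(log_rate: float) -> float:
        trial = dataclasses.replace(model, baseline_rate=math.exp(log_rate))
        return generate_population(spec, trial, n_pilot, seed).event_fraction

    lo = math.log(model.baseline_rate) - 15.0
    hi = math.log(model.baseline_rate) + 15.0
    f_lo, f_hi = fraction_at(lo), fraction_at(hi)
    if f_lo > target + tol or f_hi < target - tol:
        warnings.warn(
            f"target event fraction {target:.4f} unreachable; achievable range "
            f"[{f_lo:.4f}, {f_hi:.4f}] at the bisection boundaries",
            CalibrationWarning,
        )
        boundary = lo if abs(f_lo - target) <= abs(f_hi - target) else hi
        return dataclasses.replace(model, baseline_rate=math.exp(boundary))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = fraction_at(mid)
        if abs(f_mid - target) <= tol:
            return dataclasses.replace(model, baseline_rate=math.exp(mid))
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("event-rate bisection failed to converge")


def make_validation_model(
    truth: TrueDataModel,
    shrinkage: float = 1.0,
    noise_sd: float = 0.0,
    s0_10: float | None = None,
    seed: int = 0,
    *,
    horizon: float = 10.0,
) -> PrognosticModel:
    """Build an imperfect "published model" from the truth.

    ``beta_model = shrinkage * beta_true + noise_sd * N(0, 1)`` per
    coefficient. With ``shrinkage=1, noise_sd=0`` the model equals the
    truth; coefficient inflation (shrinkage > 1) yields a downstream
    calibration slope of about ``1/shrinkage``. The baseline survival
    defaults to the truth's value at the horizon.
    """
    if shrinkage <= 0:
        raise ValueError("shrinkage must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    beta = shrinkage * truth.beta_true
    if noise_sd > 0:
        beta = beta + noise_sd * np.random.default_rng(seed).standard_normal(beta.shape)
    return PrognosticModel(beta, truth.baseline_survival(horizon) if s0_10 is None else s0_10)


def true_performance(
    population: Cohort,
    *,
    horizon: float = 10.0,
    bootstrap_reps: int = 0,
    seed: int | None = None,
    level: float = 0.95,
) -> measures.MeasureSet:
    """True values of the six measures, computed on the full population.

    The population should be large -- as a rule of thumb at least 10^4
    events -- for these to be stable enough to serve as the simulation
    truth.
    """
    if population.n_events < 1 or population.n_events == population.n:
        raise ValueError("population must contain both events and non-events")
    rng = np.random.default_rng(seed) if seed is not None else None
    return measures.compute_all(
        population, horizon=horizon, bootstrap_reps=bootstrap_reps, rng=rng, level=level
    )
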