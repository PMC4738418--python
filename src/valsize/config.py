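"""Flat key-value run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .resampling import DEFAULT_EVENT_GRID

__all__ = ["RunConfig", "load_config", "DESK_EVENT_GRID"]

#: Reduced grid for desk-scale runs (minutes, not hours).
DESK_EVENT_GRID = (10, 25, 50, 100, 200, 500)


@dataclass
class RunConfig:
    """Parameters for the simulate / run / evaluate pipeline.

    ``seed`` has no default on purpose: every run must state one.
    """

    seed: int
    n: int = 200_000
    n_covariates: int = 8
    correlation: float = 0.2
    pi_sd: float = 0.95
    baseline_shape: float = 1.1
    censor_rate: float = 0.05
    admin_horizon: float = 15.0
    event_fraction: float = 0.054
    horizon: float = 10.0
    shrinkage: float = 1.0
    noise_sd: float = 0.0
    events: tuple[int, ...] = DESK_EVENT_GRID
    replicates: int = 2000
    bootstrap_reps: int = 0
    paper_scale: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.paper_scale:
            self.events = DEFAULT_EVENT_GRID
            self.replicates = 10_000
            if self.bootstrap_reps == 0:
                self.bootstrap_reps = 200

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["events"] = list(self.events)
        return d


_INT_KEYS = {"seed", "n", "n_covariates", "replicates", "bootstrap_reps"}
_BOOL_KEYS = {"paper_scale"}


def load_config(path, **overrides) -> RunConfig:
    """Parse ``key = value`` lines (``#`` comments allowed) into a RunConfig.

    Keyword overrides win over file values. Unknown keys raise with the
    offending key named.
    """
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
                values[key] = _parse_value(key, val)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "seed" not in values:
        raise ValueError("seed is mandatory: set it in the config file or pass --seed")
    return RunConfig(**values)


def _parse_value(key: str, val: str):
    if key == "events":
        return tuple(int(v) for v in val.replace(",", " ").split())
    if key in _BOOL_KEYS:
        return val.lower() in {"1", "true", "yes", "on"}
    if key in _INT_KEYS:
        return int(val)
    return float(val)
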