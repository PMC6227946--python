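"""Configuration, seeded-fixture generation, and summary/time-series writers.

All artifacts are plain text: JSON for summaries (with a schema version),
CSV for time series, YAML for configuration.  Every stochastic run records
its master seed in the summary it writes, and one master seed fans out into
independent per-trial and per-agent substreams so adding trials never
perturbs earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .order_stats import SpeedDistribution

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "SpeedSampleSet",
    "generate_speed_fixture",
    "write_summary",
    "read_summary",
    "write_timeseries",
    "read_timeseries",
]

SCHEMA_VERSION = 1

#: Defaults reproducing the adaptive- and stepping-experiment settings.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "anttow-out",
    "log_level": "INFO",
    "controller": {
        "epsilon": 0.2,
        "gamma": 0.02,
        "alpha": 0.1,
        "tau": 0.5,
        "K_a": 1.0,
        "K_v": 0.8,
        "theta_max": float(np.pi),
        "decision_rate": 0.5,
        "deadband": 0.01,
        "signed_penalty": False,
    },
    "speed_distribution": {"mu": 0.7, "sigma": 0.36, "lower": 0.0, "upper": 1.2},
    "gait": {"t_c": 1.5, "t_s": 3.0},
}


class ConfigError(ValueError):
    """Malformed or unreadable run configuration."""


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Merged run configuration with precedence CLI > config file > default."""

    values: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    @classmethod
    def load(cls, path: str | Path | None = None, overrides: dict | None = None):
        values = dict(DEFAULT_CONFIG)
        if path is not None:
            try:
                with open(path) as fh:
                    loaded = yaml.safe_load(fh) or {}
            except OSError as exc:
                raise ConfigError(f"cannot read config file {path}: {exc}") from exc
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} must contain a mapping")
            values = _deep_merge(values, loaded)
        if overrides:
            values = _deep_merge(
                values, {k: v for k, v in overrides.items() if v is not None}
            )
        return cls(values=values)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


@dataclass(frozen=True)
class SpeedSampleSet:
    """Synthetic individual-speed sample emulating single-transporter data."""

    samples: np.ndarray
    mu: float
    sigma: float
    lower: float
    upper: float
    n: int
    seed: int

    def summary(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "n": self.n,
            "seed": self.seed,
            "mu": self.mu,
            "sigma": self.sigma,
            "lower": self.lower,
            "upper": self.upper,
            "sample_mean": float(self.samples.mean()),
            "sample_sd": float(self.samples.std(ddof=1)) if self.n > 1 else 0.0,
        }


def generate_speed_fixture(
    dist: SpeedDistribution, n: int, seed: int
) -> SpeedSampleSet:
    """Draw ``n`` synthetic individual maximum speeds by inverse-cdf sampling.

    A reproducible stand-in for single-transporter towing-speed data with
    the fitted truncated-Gaussian shape; the sample moments converge to the
    truncated-normal moments as n grows.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    samples = dist.ppf(rng.random(n))
    return SpeedSampleSet(
        samples=samples,
        mu=dist.mu,
        sigma=dist.sigma,
        lower=dist.lower,
        upper=dist.upper,
        n=n,
        seed=seed,
    )


def write_summary(summary: dict, path: str | Path) -> Path:
    """Write a JSON summary with a schema version; round-trips losslessly."""
    if not summary:
        raise ValueError("refusing to write an empty summary")
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, **summary}
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc
    return path


def read_summary(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except OSError as exc:
        raise OSError(f"cannot read summary from {path}: {exc}") from exc


def write_timeseries(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a time-series CSV (no index column); schema is the column set."""
    if frame.empty:
        raise ValueError("refusing to write an empty time series")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
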