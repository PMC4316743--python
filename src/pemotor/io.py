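"""Run configuration and trial-table file formats.

Configs are YAML (or JSON — YAML is a superset) mapping directly onto the
model, noise and protocol dataclasses; unknown keys are rejected by name.
Trial tables are plain UTF-8 CSV with '.' decimals, one row per trial, and
round-trip numerically to full double precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MODES, ModelParams, NoiseModel
from .protocols import Schedule, block_random_schedule, concat_phases, constant_schedule

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "write_config",
    "schedule_from_config",
    "write_trial_table",
    "read_trial_table",
    "TRIAL_TABLE_COLUMNS",
]

TRIAL_TABLE_COLUMNS = [
    "subject_id", "group", "phase", "trial", "mode",
    "p_deg", "x_deg", "e_deg", "pe_hat_deg", "angle_deg", "force_au", "excluded",
]


class ConfigError(ValueError):
    """Raised on schema violations, naming the offending keys."""


@dataclass(frozen=True)
class PhaseConfig:
    """One protocol phase: either a constant perturbation or block-random
    draws from a value set."""

    label: str
    n_trials: int
    mode: str = "normal"
    p: float | None = None
    values: tuple | None = None
    block_len: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"phase {self.label!r}: unknown mode {self.mode!r}")
        if self.n_trials < 1:
            raise ConfigError(f"phase {self.label!r}: n_trials must be >= 1")
        if (self.p is None) == (self.values is None):
            raise ConfigError(
                f"phase {self.label!r}: exactly one of 'p' or 'values' is required")
        if self.block_len < 1:
            raise ConfigError(f"phase {self.label!r}: block_len must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    model: ModelParams = field(default_factory=ModelParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    phases: tuple = ()
    n_runs: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if len(self.phases) == 0:
            raise ConfigError("at least one phase is required")


def _build(cls, mapping: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {unknown}")
    try:
        return cls(**{k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in mapping.items()})
    except (ValueError, TypeError) as err:
        raise ConfigError(f"{context}: {err}") from err


def read_config(path) -> RunConfig:
    """Load and validate a run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = sorted(set(raw) - {"model", "noise", "phases", "n_runs", "master_seed"})
    if unknown:
        raise ConfigError(f"{path}: unknown keys {unknown}")
    if "phases" not in raw:
        raise ConfigError(f"{path}: missing required key 'phases'")
    phases = tuple(
        _build(PhaseConfig, ph, f"phases[{i}]") for i, ph in enumerate(raw["phases"])
    )
    model = _build(ModelParams, raw.get("model", {}), "model")
    noise = _build(NoiseModel, raw.get("noise", {}), "noise")
    return RunConfig(model=model, noise=noise, phases=phases,
                     n_runs=int(raw.get("n_runs", 1)),
                     master_seed=int(raw.get("master_seed", 0)))


def write_config(cfg: RunConfig, path) -> None:
    """Serialise a run configuration to YAML (round-trips with
    :func:`read_config`)."""
    doc = {
        "model": dataclasses.asdict(cfg.model),
        "noise": dataclasses.asdict(cfg.noise),
        "phases": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(ph).items() if v is not None}
            for ph in cfg.phases
        ],
        "n_runs": cfg.n_runs,
        "master_seed": cfg.master_seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def schedule_from_config(cfg: RunConfig, rng: np.random.Generator | None = None) -> Schedule:
    """Build the concrete trial schedule a config describes."""
    parts = []
    for ph in cfg.phases:
        if ph.p is not None:
            parts.append(constant_schedule(ph.p, ph.n_trials, ph.mode, ph.label))
        else:
            parts.append(block_random_schedule(ph.values, ph.block_len, ph.n_trials,
                                               ph.mode, rng, ph.label))
    return concat_phases(*parts)


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV with full-precision floats."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    table[TRIAL_TABLE_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Rejects files with a wrong header or unknown trial-mode tags, reporting
    the offending data line numbers.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["mode"].isin(MODES)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: unknown mode tag on line(s) {lines[:10]}")
    df["excluded"] = df["excluded"].astype(bool)
    return df
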