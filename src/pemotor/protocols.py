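"""Perturbation schedules and (ensemble) simulation drivers.

A :class:`Schedule` is an ordered list of trials, each with a perturbation
angle and a trial mode, partitioned into labelled phases (training, washout,
test, ...).  :func:`run_schedule` iterates the core model over a schedule;
:func:`run_ensemble` repeats it with independently derived seeds and averages
across runs, which is how the simulated learning curves are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MODES,
    ModelParams,
    ModelState,
    NoiseModel,
    PrimitivePopulation,
    TrialRecord,
    step_trial,
)

__all__ = [
    "TrialSpec",
    "Schedule",
    "TrialLog",
    "EnsembleResult",
    "block_random_schedule",
    "constant_schedule",
    "concat_phases",
    "run_schedule",
    "run_ensemble",
]


@dataclass(frozen=True)
class TrialSpec:
    """One trial: perturbation angle (degrees) and trial mode."""

    p: float
    mode: str = "normal"

    def __post_init__(self) -> None:
        if not np.isfinite(self.p):
            raise ValueError("perturbation must be finite")
        if self.mode not in MODES:
            raise ValueError(f"unknown trial mode {self.mode!r}")


@dataclass(frozen=True)
class Schedule:
    """Ordered trial list with per-trial phase labels."""

    p: np.ndarray
    mode: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        mode = np.asarray(self.mode, dtype=object)
        phase = np.asarray(self.phase, dtype=object)
        if not (len(p) == len(mode) == len(phase)):
            raise ValueError("p, mode and phase must have equal lengths")
        if len(p) == 0:
            raise ValueError("schedule must be non-empty")
        if not np.all(np.isfinite(p)):
            raise ValueError("perturbations must be finite")
        bad = sorted({m for m in mode if m not in MODES})
        if bad:
            raise ValueError(f"unknown trial modes {bad}")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "mode", mode)
        object.__setattr__(self, "phase", phase)

    def __len__(self) -> int:
        return len(self.p)

    def specs(self) -> list[TrialSpec]:
        return [TrialSpec(float(p), str(m)) for p, m in zip(self.p, self.mode)]

    def phase_slice(self, label: str) -> slice:
        """Contiguous trial range carrying the given phase label."""
        idx = np.flatnonzero(self.phase == label)
        if idx.size == 0:
            raise KeyError(f"no phase {label!r} in schedule")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def phase_labels(self) -> list[str]:
        out: list[str] = []
        for lab in self.phase:
            if not out or out[-1] != lab:
                out.append(str(lab))
        return out


def block_random_schedule(
    value_set,
    block_len: int,
    n_trials: int,
    mode: str = "normal",
    rng: np.random.Generator | None = None,
    phase: str = "training",
) -> Schedule:
    """Block-random perturbation schedule.

    The perturbation is constant within consecutive blocks of ``block_len``
    trials; each block's value is drawn uniformly (i.i.d., repeats allowed)
    from ``value_set``.  ``block_len=1`` gives fully independent draws; a
    final partial block is allowed.
    """
    if block_len < 1:
        raise ValueError(f"block_len must be >= 1, got {block_len}")
    values = np.asarray(value_set, dtype=float)
    if values.size == 0:
        raise ValueError("value_set must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_blocks = -(-n_trials // block_len)
    draws = rng.choice(values, size=n_blocks)
    p = np.repeat(draws, block_len)[:n_trials]
    return Schedule(p=p, mode=np.full(n_trials, mode, dtype=object),
                    phase=np.full(n_trials, phase, dtype=object))


def constant_schedule(p: float, n_trials: int, mode: str = "normal",
                      phase: str = "test") -> Schedule:
    """``n_trials`` identical trials at perturbation ``p``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return Schedule(p=np.full(n_trials, float(p)),
                    mode=np.full(n_trials, mode, dtype=object),
                    phase=np.full(n_trials, phase, dtype=object))


def concat_phases(*schedules: Schedule) -> Schedule:
    """Concatenate schedules, preserving order and phase labels."""
    if len(schedules) == 0:
        raise ValueError("concat_phases needs at least one schedule")
    return Schedule(
        p=np.concatenate([s.p for s in schedules]),
        mode=np.concatenate([s.mode for s in schedules]),
        phase=np.concatenate([s.phase for s in schedules]),
    )


@dataclass
class TrialLog:
    """Column-wise log of one simulated run (all angles in degrees)."""

    p: np.ndarray
    x: np.ndarray
    x_raw: np.ndarray
    e: np.ndarray
    pe_hat: np.ndarray
    mode: np.ndarray
    phase: np.ndarray
    final_state: ModelState

    def __len__(self) -> int:
        return len(self.p)

    def records(self) -> list[TrialRecord]:
        return [
            TrialRecord(p=float(p), x=float(x), e=float(e), pe_hat=float(h),
                        mode=str(m), x_raw=float(xr))
            for p, x, xr, e, h, m in zip(self.p, self.x, self.x_raw,
                                         self.e, self.pe_hat, self.mode)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.p)),
                "phase": self.phase,
                "mode": self.mode,
                "p_deg": self.p,
                "x_deg": self.x,
                "x_raw_deg": self.x_raw,
                "e_deg": self.e,
                "pe_hat_deg": self.pe_hat,
            }
        )


def run_schedule(
    params: ModelParams,
    schedule: Schedule,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    pop: PrimitivePopulation | None = None,
    state: ModelState | None = None,
    reset: bool = True,
) -> TrialLog:
    """Simulate one run of the model over a schedule.

    Starts from the zero state (weights and PE all 0) unless ``reset`` is
    false and a continuing ``state`` is supplied.
    """
    if pop is None:
        pop = PrimitivePopulation.grid(params)
    if reset or state is None:
        state = ModelState.zeros(len(pop))
    n = len(schedule)
    x = np.empty(n)
    x_raw = np.empty(n)
    e = np.empty(n)
    pe = np.empty(n)
    for t in range(n):
        state, rec = step_trial(state, schedule.p[t], schedule.mode[t],
                                params, pop, noise, rng)
        x[t], x_raw[t], e[t], pe[t] = rec.x, rec.x_raw, rec.e, rec.pe_hat
    return TrialLog(p=schedule.p.copy(), x=x, x_raw=x_raw, e=e, pe_hat=pe,
                    mode=schedule.mode.copy(), phase=schedule.phase.copy(),
                    final_state=state)


@dataclass
class EnsembleResult:
    """Per-run logs plus across-run mean trajectories."""

    runs: list[TrialLog]
    schedule: Schedule

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def mean_x(self) -> np.ndarray:
        return np.mean([r.x for r in self.runs], axis=0)

    @property
    def mean_x_raw(self) -> np.ndarray:
        return np.mean([r.x_raw for r in self.runs], axis=0)

    @property
    def mean_e(self) -> np.ndarray:
        return np.mean([r.e for r in self.runs], axis=0)

    @property
    def mean_pe_hat(self) -> np.ndarray:
        return np.mean([r.pe_hat for r in self.runs], axis=0)

    @property
    def final_weights(self) -> np.ndarray:
        """(n_runs, n_primitives) array of end-of-run weights."""
        return np.stack([r.final_state.weights for r in self.runs])


def run_ensemble(
    params: ModelParams,
    schedule: Schedule | None,
    n_runs: int,
    noise: NoiseModel | None = None,
    master_seed: int = 0,
    pop: PrimitivePopulation | None = None,
    schedule_factory=None,
) -> EnsembleResult:
    """Run ``n_runs`` independent simulations and collect them.

    Per-run seeds are spawned from ``master_seed`` with a splittable scheme
    (``numpy`` seed sequences), so increasing ``n_runs`` never reshuffles
    earlier runs.  If ``schedule_factory`` is given it is called with each
    run's generator to build a fresh (e.g. block-random) schedule per run;
    otherwise the fixed ``schedule`` is reused.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if schedule is None and schedule_factory is None:
        raise ValueError("either schedule or schedule_factory is required")
    if pop is None:
        pop = PrimitivePopulation.grid(params)
    seeds = np.random.SeedSequence(master_seed).spawn(n_runs)
    runs = []
    sched = schedule
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if schedule_factory is not None:
            sched = schedule_factory(rng)
        runs.append(run_schedule(params, sched, noise=noise, rng=rng, pop=pop))
    return EnsembleResult(runs=runs, schedule=sched)
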