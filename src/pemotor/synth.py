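"""Synthetic behavioural datasets with the structure of the rotation study.

The emulated experiment: three groups of 12 subjects (6 adapting to a +30
deg counter-clockwise rotation, 6 to a -30 deg clockwise rotation).  During
training the cursor rotation is redrawn from the 7-value set every one, two
or three trials (group 1/2/3) while the hand is held on a force channel;
after washout, subjects adapt to a constant +/-30 deg rotation in free test
trials.  Channel trials record a corrective force, test trials a movement
angle; trial-to-trial motor noise perturbs the angles.

The generator drives the PE model through the full protocol at the
generating parameters.  The recorded channel force is, by default, the
fresh single-trial correction ``m * f(e_prev) + n`` (the response the naive
model makes to the previous trial's error), which is the observable that the
error-correction fitting stage is defined on; ``channel_force_mode="full"``
records the full-dynamics would-be command instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams, NoiseModel, PrimitivePopulation, error_correction, error_correction_peak
from .phenomena import ROTATION_SET
from .protocols import block_random_schedule, concat_phases, constant_schedule, run_schedule

__all__ = ["GenConfig", "generate_subject", "generate_group", "normalize_sign", "inject_outlier"]

TABLE_COLUMNS = [
    "subject_id", "group", "phase", "trial", "mode",
    "p_deg", "x_deg", "e_deg", "pe_hat_deg", "angle_deg", "force_au", "excluded",
]


@dataclass(frozen=True)
class GenConfig:
    """Generator settings.

    ``angle_noise_sd`` is trial-to-trial motor noise on movement angles
    (degrees); it enters the error feedback the model receives, so noisy
    subjects also learn slightly more slowly.  ``force_gain``/``force_offset``
    map model corrections (degrees) to recorded force units; the default
    force noise is 10% of the peak corrective response.
    """

    params: ModelParams = field(default_factory=ModelParams.best_fit)
    angle_noise_sd: float = 5.0
    force_gain: float = 1.0
    force_offset: float = 0.0
    force_noise_sd: float | None = None
    train_n: int = 84
    washout_n: int = 10
    test_n: int = 30
    rotation_set: tuple = ROTATION_SET
    test_rotation: float = 30.0
    channel_force_mode: str = "fresh"

    def __post_init__(self) -> None:
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be >= 0")
        if self.force_noise_sd is not None and self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be >= 0")
        if self.channel_force_mode not in ("fresh", "full"):
            raise ValueError("channel_force_mode must be 'fresh' or 'full'")

    @property
    def resolved_force_noise_sd(self) -> float:
        if self.force_noise_sd is not None:
            return self.force_noise_sd
        if self.angle_noise_sd == 0:
            return 0.0
        peak = abs(self.force_gain) * error_correction(
            error_correction_peak(self.params), self.params)
        return 0.1 * peak


def _protocol(cfg: GenConfig, group_k: int, sign: int, rng: np.random.Generator):
    train = block_random_schedule(cfg.rotation_set, group_k, cfg.train_n,
                                  mode="channel", rng=rng, phase="training")
    parts = [train]
    if cfg.washout_n > 0:
        parts.append(constant_schedule(0.0, cfg.washout_n, "normal", "washout"))
    parts.append(constant_schedule(sign * cfg.test_rotation, cfg.test_n,
                                   "normal", "test"))
    return concat_phases(*parts)


def generate_subject(
    group_k: int,
    sign: int,
    cfg: GenConfig,
    rng: np.random.Generator,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Simulate one subject through the full protocol.

    ``sign`` is +1 (counter-clockwise, +30 deg test rotation) or -1
    (clockwise).  Returns a trial table (one row per trial) with movement
    angles on normal trials and corrective forces on channel trials.
    """
    if group_k not in (1, 2, 3):
        raise ValueError("group_k must be 1, 2 or 3")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 (CCW) or -1 (CW)")
    if subject_id is None:
        subject_id = f"g{group_k}_{'ccw' if sign > 0 else 'cw'}"
    sched = _protocol(cfg, group_k, sign, rng)
    noise = NoiseModel(sigma_G=cfg.angle_noise_sd)
    pop = PrimitivePopulation.grid(cfg.params)
    log = run_schedule(cfg.params, sched, noise=noise, rng=rng, pop=pop)

    n = len(sched)
    angle = np.full(n, np.nan)
    force = np.full(n, np.nan)
    normal = log.mode != "channel"
    # recorded movement angle: the hand direction actually produced, i.e. the
    # command plus motor noise, recovered as p - e on non-clamp normal trials
    angle[normal] = log.p[normal] - log.e[normal]
    chan = ~normal
    f_noise_sd = cfg.resolved_force_noise_sd
    if cfg.channel_force_mode == "full":
        f_model = log.x_raw[chan]
    else:
        e_chan = log.e[chan]
        prev_e = np.concatenate([[0.0], e_chan[:-1]])
        f_model = error_correction(prev_e, cfg.params)
    f = cfg.force_gain * f_model + cfg.force_offset
    if f_noise_sd > 0:
        f = f + rng.normal(0.0, f_noise_sd, size=f.shape)
    force[chan] = f

    return pd.DataFrame({
        "subject_id": subject_id,
        "group": group_k,
        "phase": log.phase,
        "trial": np.arange(n),
        "mode": log.mode,
        "p_deg": log.p,
        "x_deg": log.x,
        "e_deg": log.e,
        "pe_hat_deg": log.pe_hat,
        "angle_deg": angle,
        "force_au": force,
        "excluded": False,
    })[TABLE_COLUMNS]


def generate_group(
    group_k: int,
    cfg: GenConfig,
    master_seed: int = 0,
    n_subjects: int = 12,
) -> pd.DataFrame:
    """Generate a full group: half CCW (+30 deg), half CW (-30 deg)."""
    if n_subjects < 2 or n_subjects % 2:
        raise ValueError("n_subjects must be an even count >= 2")
    seeds = np.random.SeedSequence(master_seed).spawn(n_subjects)
    tables = []
    for i, ss in enumerate(seeds):
        sign = 1 if i < n_subjects // 2 else -1
        sid = f"g{group_k}_{'ccw' if sign > 0 else 'cw'}_s{i:02d}"
        tables.append(generate_subject(group_k, sign, cfg,
                                       np.random.default_rng(ss), subject_id=sid))
    return pd.concat(tables, ignore_index=True)


_SIGNED_COLUMNS = ["p_deg", "x_deg", "e_deg", "pe_hat_deg", "angle_deg", "force_au"]


def normalize_sign(table: pd.DataFrame) -> pd.DataFrame:
    """Flip clockwise subjects onto the +30 deg convention.

    Subjects whose test-phase rotation is negative have every signed column
    negated, so CW and CCW data pool on a common sign.  Idempotent.
    """
    out = table.copy()
    test = out[out["phase"] == "test"]
    for sid, sub in test.groupby("subject_id"):
        if float(sub["p_deg"].median()) < 0:
            m = out["subject_id"] == sid
            out.loc[m, _SIGNED_COLUMNS] = -out.loc[m, _SIGNED_COLUMNS]
    return out


def inject_outlier(
    table: pd.DataFrame,
    magnitude_sd_multiples: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replace one test-phase angle by mean + k*sd of its trial column.

    Exercises the mean +/- 3 sd exclusion screen: a multiplier above 3
    guarantees removal, one below 3 survives.  All other rows are untouched.
    """
    if magnitude_sd_multiples <= 0:
        raise ValueError("multiplier must be > 0")
    out = table.copy()
    test_idx = out.index[(out["phase"] == "test") & out["angle_deg"].notna()]
    if test_idx.empty:
        raise ValueError("table has no test-phase angles")
    row = out.loc[rng.choice(test_idx)]
    same_trial = out[(out["phase"] == "test") & (out["trial"] == row["trial"])]
    col = same_trial["angle_deg"]
    out.loc[row.name, "angle_deg"] = float(col.mean() + magnitude_sd_multiples * col.std(ddof=1))
    return out
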