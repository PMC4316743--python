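"""Pre-packaged experiments reproducing classic motor-learning phenomena.

Each function builds the corresponding protocol, runs the PE model over it
(as an ensemble where averaging matters), computes the phenomenon's summary
metric and returns a :class:`PhenomenonReport`.  All of them are pure
functions of (parameters, protocol arguments, seeds) and therefore
bit-reproducible.

Phenomena covered: structural learning (faster adaptation after structured
random training), the uncertainty effect (feedback blur slows adaptation),
savings (faster relearning after washout) and its persistence under long
washouts, anterograde interference (prior learning slows opposite learning),
spontaneous recovery under error clamps, and a rival model in which
primitive recruitment follows a predicted perturbation instead of the
prospective error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ModelParams,
    ModelState,
    NoiseModel,
    PrimitivePopulation,
    motor_command,
    movement_error,
    tuning_activities,
    update_pe,
    update_weights,
)
from .core import _eta_step
from .fitstats import exp_fit, state_space_fit
from .protocols import (
    Schedule,
    TrialLog,
    block_random_schedule,
    concat_phases,
    constant_schedule,
    run_ensemble,
    run_schedule,
)

__all__ = [
    "PhenomenonReport",
    "ROTATION_SET",
    "structural_learning",
    "uncertainty_effect",
    "savings",
    "savings_washout_sweep",
    "anterograde_interference",
    "spontaneous_recovery",
    "perturbation_prediction_model",
    "run_pp_schedule",
    "half_rise_trials",
]

#: The rotation set used in the structured-training protocols (degrees).
ROTATION_SET = (-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0)


@dataclass
class PhenomenonReport:
    """Named bundle of trajectories and derived metrics for one phenomenon."""

    name: str
    params: ModelParams
    metrics: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """JSON-friendly metrics dictionary."""
        out = {"name": self.name}
        out.update({k: (float(v) if np.isscalar(v) or isinstance(v, (int, float))
                        else np.asarray(v).tolist())
                    for k, v in self.metrics.items()})
        return out


def structural_learning(
    params: ModelParams,
    group_k: int,
    n_runs: int = 100,
    train_n: int = 210,
    train_mode: str = "channel",
    washout_n: int = 10,
    test_p: float = 30.0,
    test_n: int = 30,
    rotation_set=ROTATION_SET,
    noise: NoiseModel | None = None,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Structured random training followed by constant-rotation test.

    Training perturbations are block-random draws from the 7-value rotation
    set, constant over blocks of ``group_k`` trials (group 1 changes every
    trial, group 3 every three).  Training uses force-channel trials by
    default (executed command clamped to 0), then washout, then a constant
    ``test_p`` rotation.  The report carries the across-run mean test curve
    and its fitted learning speed ``b``.
    """
    if group_k < 1:
        raise ValueError("group_k must be >= 1")

    def factory(rng: np.random.Generator) -> Schedule:
        train = block_random_schedule(rotation_set, group_k, train_n,
                                      mode=train_mode, rng=rng, phase="training")
        parts = [train]
        if washout_n > 0:
            parts.append(constant_schedule(0.0, washout_n, "normal", "washout"))
        parts.append(constant_schedule(test_p, test_n, "normal", "test"))
        return concat_phases(*parts)

    ens = run_ensemble(params, None, n_runs, noise=noise,
                       master_seed=master_seed, schedule_factory=factory)
    sl = ens.schedule.phase_slice("test")
    mean_test_x = ens.mean_x[sl]
    fit = exp_fit(test_p - mean_test_x)
    return PhenomenonReport(
        name=f"structural_learning_group{group_k}",
        params=params,
        metrics={"learning_speed_b": fit.b, "group_k": group_k},
        curves={"mean_test_x": mean_test_x, "mean_x": ens.mean_x,
                "mean_pe_hat": ens.mean_pe_hat},
    )


def uncertainty_effect(
    params: ModelParams,
    sigma_G_list=(0.0, 18.0, 30.0, 36.0, 60.0),
    n_trials: int = 50,
    n_runs: int = 100,
    p: float = 30.0,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Adaptation under feedback blur of increasing width.

    For each ``sigma_G`` the model adapts to a constant rotation for
    ``n_trials`` with error feedback blurred by N(0, sigma_G^2); the linear
    state-space model ``x_{t+1} = A x_t + B e_t`` is then fit to the
    across-run mean trajectories.  Larger blur yields a smaller adaptation
    rate ``B``.
    """
    sched = constant_schedule(p, n_trials, "normal", "test")
    rates, retentions, curves = [], [], {}
    for sg in sigma_G_list:
        if sg < 0:
            raise ValueError("sigma_G must be >= 0")
        # common random numbers across blur conditions: the same master seed
        # scales the same standardised noise draws by sigma_G, which sharpens
        # the comparison of fitted rates between conditions
        ens = run_ensemble(params, sched, n_runs,
                           noise=NoiseModel(sigma_G=float(sg)),
                           master_seed=master_seed)
        fit = state_space_fit(ens.mean_x, ens.mean_e)
        rates.append(fit.B_adaptation)
        retentions.append(fit.A_retention)
        curves[f"mean_x_sigma_{sg:g}"] = ens.mean_x
    return PhenomenonReport(
        name="uncertainty_effect",
        params=params,
        metrics={"sigma_G": list(sigma_G_list),
                 "adaptation_rate_B": rates,
                 "retention_A": retentions},
        curves=curves,
    )


def _phased_run(params, phases, n_runs=10, noise=None, master_seed=0):
    sched = concat_phases(*phases)
    ens = run_ensemble(params, sched, n_runs, noise=noise, master_seed=master_seed)
    return sched, ens


def savings(
    params: ModelParams,
    initial_n: int = 30,
    opposite_n: int = 5,
    relearn_n: int = 30,
    p: float = 30.0,
    n_runs: int = 10,
    noise: NoiseModel | None = None,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Initial learning, brief opposite learning, relearning.

    The savings metric is the summed difference of the compensatory command
    over the first five trials of the relearning versus initial phases;
    positive values mean faster relearning.
    """
    for n, lbl in ((initial_n, "initial_n"), (opposite_n, "opposite_n"),
                   (relearn_n, "relearn_n")):
        if n < 1:
            raise ValueError(f"{lbl} must be >= 1")
    phases = [
        constant_schedule(p, initial_n, "normal", "initial"),
        constant_schedule(-p, opposite_n, "normal", "opposite"),
        constant_schedule(p, relearn_n, "normal", "relearn"),
    ]
    sched, ens = _phased_run(params, phases, n_runs, noise, master_seed)
    xi = ens.mean_x[sched.phase_slice("initial")]
    xr = ens.mean_x[sched.phase_slice("relearn")]
    k = min(5, initial_n, relearn_n)
    metric = float(np.sum(xr[:k] - xi[:k]))
    return PhenomenonReport(
        name="savings", params=params,
        metrics={"savings_effect": metric, "n_compared_trials": k},
        curves={"mean_x": ens.mean_x, "initial_x": xi, "relearn_x": xr},
    )


def savings_washout_sweep(
    params: ModelParams,
    lam_list=(0.9586, 0.9786, 0.9986),
    washout_lengths=(0, 25, 50, 100, 200, 400),
    initial_n: int = 60,
    relearn_n: int = 20,
    p: float = 30.0,
    n_runs: int = 1,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Persistence of savings as a function of washout length.

    For each forgetting rate, the initial-learning/washout/relearning
    protocol is run at every washout length; per forgetting rate the savings
    metric is normalised to its maximum.  Forgetting rates close to 1
    preserve savings across long washouts.
    """
    curves = {}
    raw = {}
    for lam in lam_list:
        if not (0.0 < lam <= 1.0):
            raise ValueError("forgetting rates must be in (0, 1]")
        pars = params.with_(lam=float(lam))
        vals = []
        for w in washout_lengths:
            phases = [constant_schedule(p, initial_n, "normal", "initial")]
            if w > 0:
                phases.append(constant_schedule(0.0, int(w), "normal", "washout"))
            phases.append(constant_schedule(p, relearn_n, "normal", "relearn"))
            sched, ens = _phased_run(pars, phases, n_runs, None, master_seed)
            xi = ens.mean_x[sched.phase_slice("initial")]
            xr = ens.mean_x[sched.phase_slice("relearn")]
            k = min(5, relearn_n)
            vals.append(float(np.sum(xr[:k] - xi[:k])))
        vals = np.asarray(vals)
        raw[float(lam)] = vals
        peak = np.max(np.abs(vals))
        curves[float(lam)] = vals / peak if peak > 0 else vals
    return PhenomenonReport(
        name="savings_washout_sweep", params=params,
        metrics={"washout_lengths": list(washout_lengths),
                 "normalized_savings": {k: v.tolist() for k, v in curves.items()},
                 "raw_savings": {k: v.tolist() for k, v in raw.items()}},
        curves={f"normalized_lam_{k}": v for k, v in curves.items()},
    )


def half_rise_trials(compensation: np.ndarray) -> float:
    """Interpolated number of trials for a compensation curve (fraction of
    the perturbation compensated, per trial) to first reach 0.5.  Larger
    means slower adaptation; returns the curve length if 0.5 is never
    reached."""
    c = np.asarray(compensation, dtype=float)
    above = np.flatnonzero(c >= 0.5)
    if above.size == 0:
        return float(len(c))
    k = int(above[0])
    if k == 0:
        return 0.0
    f0, f1 = c[k - 1], c[k]
    return k - 1 + (0.5 - f0) / (f1 - f0)


def anterograde_interference(
    params: ModelParams,
    initial_lengths=(10, 30, 50),
    opposite_n: int = 50,
    p: float = 30.0,
    n_runs: int = 10,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Opposite learning after initial learning of varying length.

    For each initial-phase length the model first adapts to ``+p`` and then
    to ``-p``.  Opposite-phase progress is expressed as the per-trial
    fraction of the ``-p`` perturbation compensated, ``-x_t / p`` (negative
    at phase start while the old memory still pushes the wrong way).  Two
    indices are reported per initial length: the interpolated trials to
    reach 50% compensation (larger = slower) and the phase-mean compensation
    (smaller = slower).  Both show adaptation slower than naive and slowing
    further with initial-phase length.
    """
    if opposite_n < 1:
        raise ValueError("opposite_n must be >= 1")
    naive = run_ensemble(params, constant_schedule(-p, opposite_n, "normal", "opposite"),
                         n_runs, master_seed=master_seed)
    naive_comp = -naive.mean_x / p
    indices, mean_comp, curves = [], [], {"naive_opposite_x": naive.mean_x}
    for n0 in initial_lengths:
        if n0 < 1:
            raise ValueError("initial lengths must be >= 1")
        phases = [constant_schedule(p, int(n0), "normal", "initial"),
                  constant_schedule(-p, opposite_n, "normal", "opposite")]
        sched, ens = _phased_run(params, phases, n_runs, None, master_seed)
        xo = ens.mean_x[sched.phase_slice("opposite")]
        comp = -xo / p
        indices.append(half_rise_trials(comp))
        mean_comp.append(float(comp.mean()))
        curves[f"opposite_x_init_{n0}"] = xo
    return PhenomenonReport(
        name="anterograde_interference", params=params,
        metrics={"initial_lengths": list(initial_lengths),
                 "trials_to_half_compensation": indices,
                 "mean_compensation": mean_comp,
                 "naive_trials_to_half": half_rise_trials(naive_comp),
                 "naive_mean_compensation": float(naive_comp.mean())},
        curves=curves,
    )


def spontaneous_recovery(
    params: ModelParams,
    initial_n: int = 50,
    opposite_n: int = 5,
    clamp_n: int = 50,
    p: float = 30.0,
    n_runs: int = 10,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Initial learning, brief opposite learning, error-clamp phase.

    During the clamp the observed error is forced to 0, so the PE decays
    geometrically to 0 at rate ``1 - alpha`` and re-activates the primitives
    that stored the initial memory: the command climbs back above its
    end-of-opposite value.  Recovery metric: max clamp-phase command minus
    the command on the last opposite trial.
    """
    for n, lbl in ((initial_n, "initial_n"), (opposite_n, "opposite_n"),
                   (clamp_n, "clamp_n")):
        if n < 1:
            raise ValueError(f"{lbl} must be >= 1")
    phases = [constant_schedule(p, initial_n, "normal", "initial"),
              constant_schedule(-p, opposite_n, "normal", "opposite"),
              constant_schedule(0.0, clamp_n, "error_clamp", "clamp")]
    sched, ens = _phased_run(params, phases, n_runs, None, master_seed)
    xo = ens.mean_x[sched.phase_slice("opposite")]
    xc = ens.mean_x[sched.phase_slice("clamp")]
    pec = ens.mean_pe_hat[sched.phase_slice("clamp")]
    return PhenomenonReport(
        name="spontaneous_recovery", params=params,
        metrics={"recovery": float(np.max(xc) - xo[-1]),
                 "end_opposite_x": float(xo[-1]),
                 "max_clamp_x": float(np.max(xc))},
        curves={"mean_x": ens.mean_x, "clamp_x": xc, "clamp_pe_hat": pec},
    )


# ---------------------------------------------------------------------------
# rival model: perturbation prediction


def run_pp_schedule(
    params: ModelParams,
    schedule: Schedule,
    clamp_phat: float,
    pop: PrimitivePopulation | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> TrialLog:
    """Simulate the perturbation-prediction variant over a schedule.

    Identical learning rule, but primitive recruitment follows a predicted
    perturbation ``p_hat`` updated as ``p_hat + alpha (p - p_hat)`` from the
    (noiseless) perturbation on non-clamp trials; during error-clamp trials
    ``p_hat`` is forced to ``clamp_phat`` since the perturbation itself is
    unobservable there.
    """
    if pop is None:
        pop = PrimitivePopulation.grid(params)
    state = ModelState.zeros(len(pop))
    eta = _eta_step(params, pop)
    n = len(schedule)
    x = np.empty(n)
    x_raw = np.empty(n)
    e = np.empty(n)
    phat_log = np.empty(n)
    p_hat = 0.0
    for t in range(n):
        p, mode = float(schedule.p[t]), str(schedule.mode[t])
        a = tuning_activities(pop, p_hat)
        xr = motor_command(state, a)
        xt = 0.0 if mode == "channel" else xr
        et = movement_error(p, xt, mode, noise, rng)
        state = ModelState(update_weights(state.weights, et, a, params.lam, eta),
                           0.0, state.trial_index + 1)
        phat_log[t] = p_hat
        if mode == "error_clamp":
            p_hat = float(clamp_phat)
        else:
            p_hat = update_pe(p_hat, p, params.alpha)
        x[t], x_raw[t], e[t] = xt, xr, et
    return TrialLog(p=schedule.p.copy(), x=x, x_raw=x_raw, e=e, pe_hat=phat_log,
                    mode=schedule.mode.copy(), phase=schedule.phase.copy(),
                    final_state=state)


def perturbation_prediction_model(
    params: ModelParams,
    clamp_phat: float = -30.0,
    initial_n: int = 50,
    opposite_n: int = 5,
    clamp_n: int = 50,
    p: float = 30.0,
    master_seed: int = 0,
) -> PhenomenonReport:
    """Spontaneous-recovery protocol under the perturbation-prediction model.

    Returns the rival model's trajectory and recovery metric side by side
    with the PE model's on the identical protocol and seed, isolating the
    structural difference (recruitment by predicted perturbation vs
    prospective error).
    """
    if clamp_phat not in (0.0, -30.0) and abs(clamp_phat) > 180:
        raise ValueError("clamp_phat must be a plausible rotation angle")
    sched = concat_phases(
        constant_schedule(p, initial_n, "normal", "initial"),
        constant_schedule(-p, opposite_n, "normal", "opposite"),
        constant_schedule(0.0, clamp_n, "error_clamp", "clamp"),
    )
    rng = np.random.default_rng(master_seed)
    pp = run_pp_schedule(params, sched, clamp_phat, rng=rng)
    pe_log = run_schedule(params, sched, rng=np.random.default_rng(master_seed))
    sl_o, sl_c = sched.phase_slice("opposite"), sched.phase_slice("clamp")
    rec_pp = float(np.max(pp.x[sl_c]) - pp.x[sl_o][-1])
    rec_pe = float(np.max(pe_log.x[sl_c]) - pe_log.x[sl_o][-1])
    return PhenomenonReport(
        name="perturbation_prediction_model", params=params,
        metrics={"clamp_phat": float(clamp_phat),
                 "recovery_pp": rec_pp, "recovery_pe": rec_pe},
        curves={"pp_x": pp.x, "pe_x": pe_log.x, "pp_phat": pp.pe_hat},
    )
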