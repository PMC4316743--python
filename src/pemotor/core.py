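"""Core prospective-error (PE) motor-primitive model.

A population of motor primitives is tuned to the prospective error — the
movement error predicted for the upcoming trial.  Primitive ``i`` has a
Gaussian tuning curve with preferred PE ``mu_i`` and shared width ``sigma``;
the motor command is the weighted sum of primitive activities,

    x = sum_i W_i * A_i(pe_hat),      A_i(pe_hat) = exp(-(pe_hat - mu_i)^2 / (2 sigma^2)).

After each trial the weights are updated by a forgetting/learning rule

    W_i <- lam * W_i + eta_step * e * A_i,

and the prospective error tracks the observed error with a constant gain,

    pe_hat <- pe_hat + alpha * (e - pe_hat),

which is the steady-state Kalman predictor for a random-walk error process
(see :func:`pe_kalman_equivalence`).

Gain convention
---------------
``eta`` is quoted on the scale of the population readout: the per-primitive
step ``eta_step`` divides out the population inner-product mass so that the
trial-to-trial command recursion in the dense-population limit is

    x_{t+1} ~= lam * x_t + eta * C0(sigma) * exp(-d^2 / (4 sigma^2)) * e_t,

with ``d`` the trial-to-trial change of the PE and
``C0(sigma) = rho0 / (2 sqrt(pi) sigma)`` at the reference density
``rho0 = 1000 primitives / 360 deg``.  This makes the dynamics independent of
the primitive count (law-of-large-numbers regime) and identical to a
population of density-normalised Gaussian tuning curves with 1000 primitives
spanning a full circle.  All angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MODES",
    "ModelParams",
    "PrimitivePopulation",
    "ModelState",
    "NoiseModel",
    "TrialRecord",
    "REFERENCE_DENSITY",
    "tuning_activities",
    "motor_command",
    "movement_error",
    "update_pe",
    "update_weights",
    "step_trial",
    "inner_product",
    "inner_product_closed_form",
    "effective_learning_rate",
    "error_correction",
    "error_correction_peak",
    "uncertainty_averaged_correction",
    "pe_kalman_equivalence",
]

#: Recognised trial modes.  ``normal``: free movement with veridical (possibly
#: noisy) error feedback.  ``channel``: the hand is constrained straight to the
#: target, so the executed command is forced to 0 while error feedback still
#: reflects the perturbation.  ``error_clamp``: feedback is manipulated so the
#: observed error is exactly 0.
MODES = ("normal", "channel", "error_clamp")

#: Reference primitive density (primitives per degree) fixing the readout gain;
#: see the module docstring.
REFERENCE_DENSITY = 1000.0 / 360.0

#: degrees per radian; tuning widths quoted in radians elsewhere convert via
#: this factor.
DEG_PER_RAD = 360.0 / (2.0 * math.pi)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the PE motor-primitive model.

    Parameters
    ----------
    lam : float
        Forgetting rate of the weights, in (0, 1].
    eta : float
        Learning rate on the population-readout scale (see module docstring).
    alpha : float
        PE update gain, in [0, 1].  ``alpha=1`` copies the last observed
        error; ``alpha=0`` never updates the prediction.
    sigma : float
        Tuning width of the primitives, degrees.
    n_primitives : int
        Population size.  Outputs are insensitive to it above a few hundred.
    mu_low, mu_high : float
        Bounds of the preferred-PE range, degrees.
    """

    lam: float = 0.9586
    eta: float = 2.3913
    alpha: float = 0.8
    sigma: float = 0.2868 * DEG_PER_RAD
    n_primitives: int = 1000
    mu_low: float = -180.0
    mu_high: float = 180.0

    def __post_init__(self) -> None:
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        if not self.eta >= 0.0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.n_primitives < 1:
            raise ValueError("n_primitives must be >= 1")
        if not self.mu_low < self.mu_high:
            raise ValueError("mu_low must be < mu_high")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def best_fit(cls) -> "ModelParams":
        """Default parameter set (the best-fit values for naive adaptation)."""
        return cls()


@dataclass(frozen=True)
class PrimitivePopulation:
    """Preferred PEs and shared tuning width of the primitive population."""

    mu: np.ndarray
    sigma: float
    mu_low: float = -180.0
    mu_high: float = 180.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if mu.ndim != 1 or mu.size < 1:
            raise ValueError("mu must be a non-empty 1-D array")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if mu.min() < self.mu_low or mu.max() > self.mu_high:
            raise ValueError("preferred PEs outside [mu_low, mu_high]")

    def __len__(self) -> int:
        return self.mu.size

    @property
    def density(self) -> float:
        """Primitives per degree of preferred-PE range."""
        return self.mu.size / (self.mu_high - self.mu_low)

    @classmethod
    def grid(cls, params: ModelParams) -> "PrimitivePopulation":
        """Deterministic even grid of preferred PEs, symmetric about the
        centre of the range (the tested default)."""
        n = params.n_primitives
        span = params.mu_high - params.mu_low
        mu = params.mu_low + (np.arange(n) + 0.5) * span / n
        return cls(mu=mu, sigma=params.sigma,
                   mu_low=params.mu_low, mu_high=params.mu_high)

    @classmethod
    def random(cls, params: ModelParams, rng: np.random.Generator) -> "PrimitivePopulation":
        """Preferred PEs sampled uniformly at random over the range."""
        mu = rng.uniform(params.mu_low, params.mu_high, size=params.n_primitives)
        return cls(mu=np.sort(mu), sigma=params.sigma,
                   mu_low=params.mu_low, mu_high=params.mu_high)


@dataclass
class ModelState:
    """Mutable simulation state: weights, current PE and trial counter."""

    weights: np.ndarray
    pe_hat: float = 0.0
    trial_index: int = 0

    @classmethod
    def zeros(cls, n_primitives: int) -> "ModelState":
        """The canonical initial state: all weights 0 and PE 0."""
        return cls(weights=np.zeros(n_primitives), pe_hat=0.0, trial_index=0)

    def copy(self) -> "ModelState":
        return ModelState(self.weights.copy(), self.pe_hat, self.trial_index)


@dataclass(frozen=True)
class NoiseModel:
    """Noise standard deviations (degrees).

    ``sigma_G`` is the experimentally imposed feedback blur added to the
    observed error on non-clamp trials.  ``sigma_xi`` and ``sigma_zeta`` are
    the observation-noise and random-walk-drift scales of the generative
    error model underlying the PE update (used by the Kalman correspondence,
    not injected into simulations).
    """

    sigma_xi: float = 0.0
    sigma_zeta: float = 0.0
    sigma_G: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_xi", "sigma_zeta", "sigma_G"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial log entry.

    ``x`` is the executed motor command (0 on channel trials); ``x_raw`` is
    the command the population would have produced — on a channel trial this
    is the force the subject expresses against the channel wall.
    """

    p: float
    x: float
    e: float
    pe_hat: float
    mode: str
    x_raw: float = 0.0


# ---------------------------------------------------------------------------
# elementary operations


def tuning_activities(pop: PrimitivePopulation, pe_hat: float) -> np.ndarray:
    """Gaussian activity of every primitive at the given prospective error.

    ``A_i = exp(-(pe_hat - mu_i)^2 / (2 sigma^2))`` — unit peak at the
    preferred PE.
    """
    if not np.isfinite(pe_hat):
        raise ValueError(f"pe_hat must be finite, got {pe_hat}")
    d = pe_hat - pop.mu
    return np.exp(-(d * d) / (2.0 * pop.sigma**2))


def motor_command(state: ModelState, activities: np.ndarray) -> float:
    """Population readout ``x = sum_i W_i A_i``."""
    a = np.asarray(activities, dtype=float)
    if a.shape != state.weights.shape:
        raise ValueError(
            f"length mismatch: {state.weights.shape} weights vs {a.shape} activities"
        )
    return float(state.weights @ a)


def movement_error(
    p: float,
    x: float,
    mode: str,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Observed movement error for one trial.

    normal      -> e = p - x + xi,  xi ~ N(0, sigma_G^2)
    channel     -> e = p + xi       (the executed command is forced to 0)
    error_clamp -> e = 0
    """
    if mode == "error_clamp":
        return 0.0
    if mode == "normal":
        e = p - x
    elif mode == "channel":
        e = p
    else:
        raise ValueError(f"unknown trial mode {mode!r}; expected one of {MODES}")
    if noise is not None and noise.sigma_G > 0:
        if rng is None:
            raise ValueError("rng required when sigma_G > 0")
        e += rng.normal(0.0, noise.sigma_G)
    return float(e)


def update_pe(pe_hat: float, e: float, alpha: float) -> float:
    """PE update ``pe_hat + alpha * (e - pe_hat)``."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return float(pe_hat + alpha * (e - pe_hat))


def update_weights(
    weights: np.ndarray, e: float, activities: np.ndarray, lam: float, eta: float
) -> np.ndarray:
    """Raw weight update ``W_i <- lam W_i + eta e A_i`` (no gain scaling)."""
    w = np.asarray(weights, dtype=float)
    a = np.asarray(activities, dtype=float)
    if w.shape != a.shape:
        raise ValueError(f"length mismatch: {w.shape} weights vs {a.shape} activities")
    return lam * w + eta * e * a


def _eta_step(params: ModelParams, pop: PrimitivePopulation) -> float:
    """Per-primitive learning step realising the readout-scale ``eta``.

    Chosen so that ``eta_step * sum_i A_i(u) A_i(v)`` equals
    ``eta * C0(sigma) * exp(-(u-v)^2/(4 sigma^2))`` in the dense limit, with
    ``C0 = REFERENCE_DENSITY / (2 sqrt(pi) sigma)``.
    """
    return params.eta * REFERENCE_DENSITY / (2.0 * math.pi * params.sigma**2 * pop.density)


def effective_learning_rate(params: ModelParams) -> float:
    """Zero-lag gain ``eta * C0(sigma)`` of the reduced command recursion."""
    return params.eta * REFERENCE_DENSITY / (2.0 * math.sqrt(math.pi) * params.sigma)


def step_trial(
    state: ModelState,
    p: float,
    mode: str,
    params: ModelParams,
    pop: PrimitivePopulation,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ModelState, TrialRecord]:
    """Advance the model by one trial.

    Order of operations: (1) activities at the current PE; (2) motor command
    (forced to 0 on channel trials); (3) observed error per trial mode;
    (4) weight update and PE update.  Weights and PE update on every trial
    mode, including channel and error-clamp trials.
    """
    if mode not in MODES:
        raise ValueError(f"unknown trial mode {mode!r}; expected one of {MODES}")
    a = tuning_activities(pop, state.pe_hat)
    x_raw = motor_command(state, a)
    x = 0.0 if mode == "channel" else x_raw
    e = movement_error(p, x, mode, noise, rng)
    new_w = update_weights(state.weights, e, a, params.lam, _eta_step(params, pop))
    new_pe = update_pe(state.pe_hat, e, params.alpha)
    rec = TrialRecord(p=float(p), x=x, e=e, pe_hat=state.pe_hat, mode=mode, x_raw=x_raw)
    return ModelState(new_w, new_pe, state.trial_index + 1), rec


# ---------------------------------------------------------------------------
# closed-form quantities


def inner_product(pop: PrimitivePopulation, pe_a: float, pe_b: float) -> float:
    """Brute-force population inner product ``sum_i A_i(pe_a) A_i(pe_b)``."""
    return float(tuning_activities(pop, pe_a) @ tuning_activities(pop, pe_b))


def inner_product_closed_form(delta: float, sigma: float, density: float) -> float:
    """Dense-population limit of the tuning inner product.

    For preferred PEs uniform with the given density over the whole line,
    ``sum_i A_i(u) A_i(u + delta) -> density * sigma * sqrt(pi) *
    exp(-delta^2 / (4 sigma^2))`` — maximal at ``delta = 0`` and falling off
    with the squared PE change at twice the tuning variance.
    """
    return density * sigma * math.sqrt(math.pi) * math.exp(-(delta**2) / (4.0 * sigma**2))


def error_correction(e, params: ModelParams):
    """Single-trial corrective response from the naive state.

    Starting from ``W = 0`` and ``pe_hat = 0``, observing error ``e`` once
    yields the next-trial command

        f(e) = eta * C0(sigma) * e * exp(-(alpha e)^2 / (4 sigma^2)).

    Non-monotonic in ``e``: corrections grow for small errors, then shrink
    for large ones, peaking at ``e = sqrt(2) sigma / alpha``.  Accepts
    scalars or arrays.
    """
    e = np.asarray(e, dtype=float)
    g = effective_learning_rate(params)
    out = g * e * np.exp(-((params.alpha * e) ** 2) / (4.0 * params.sigma**2))
    return float(out) if out.ndim == 0 else out


def error_correction_peak(params: ModelParams) -> float:
    """Error magnitude maximising :func:`error_correction`:
    ``sqrt(2) * sigma / alpha`` degrees."""
    return math.sqrt(2.0) * params.sigma / params.alpha


def uncertainty_averaged_correction(e, sigma_G: float, params: ModelParams):
    """Expected corrective response under feedback blur.

    With the observed error blurred by ``xi ~ N(0, sigma_G^2)``, the mean
    next-trial correction is ``E[f(e + xi)]``.  For the Gaussian form of
    :func:`error_correction` this integral is closed:

        E[f(e + xi)] = eta * C0 * e * kappa^{-3/2} * exp(-beta e^2 / kappa),

    with ``beta = alpha^2 / (4 sigma^2)`` and
    ``kappa = 1 + 2 beta sigma_G^2``.  Blur both attenuates and broadens the
    correction curve, so larger ``sigma_G`` means smaller corrections for
    small errors.  Reduces to :func:`error_correction` at ``sigma_G = 0``.
    """
    if sigma_G < 0:
        raise ValueError(f"sigma_G must be >= 0, got {sigma_G}")
    e = np.asarray(e, dtype=float)
    g = effective_learning_rate(params)
    beta = params.alpha**2 / (4.0 * params.sigma**2)
    kappa = 1.0 + 2.0 * beta * sigma_G**2
    out = g * e * kappa**-1.5 * np.exp(-beta * e * e / kappa)
    return float(out) if out.ndim == 0 else out


def pe_kalman_equivalence(sigma_zeta: float, sigma_xi: float) -> float:
    """Steady-state Kalman gain of the random-walk error model.

    For ``g_{t+1} = g_t + zeta`` observed as ``e_t = g_t + xi``, the
    steady-state one-step predictor is ``ghat <- ghat + K (e - ghat)`` with

        K = S / (S + r),   S = (q + sqrt(q^2 + 4 q r)) / 2,

    ``q = sigma_zeta^2``, ``r = sigma_xi^2``.  Setting ``alpha = K`` makes
    the PE update the optimal one-step error predictor: drift dominating
    observation noise pushes ``alpha`` to 1, a static error process pushes it
    to 0.
    """
    if sigma_xi <= 0:
        raise ValueError("sigma_xi must be > 0")
    q = float(sigma_zeta) ** 2
    r = float(sigma_xi) ** 2
    s = 0.5 * (q + math.sqrt(q * q + 4.0 * q * r))
    return s / (s + r)
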