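"""Unit and property tests for the core PE motor-primitive model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, optimize

import pemotor as pm
from pemotor.core import REFERENCE_DENSITY, ModelState, _eta_step


# ---------------------------------------------------------------------------
# tuning / command / error primitives


def test_tuning_peak_and_width(grid_pop):
    """Unit activity at the preferred PE; exp(-1/2) one tuning width away."""
    i = 137
    mu_i = grid_pop.mu[i]
    assert pm.tuning_activities(grid_pop, mu_i)[i] == pytest.approx(1.0)
    a = pm.tuning_activities(grid_pop, mu_i + grid_pop.sigma)
    assert a[i] == pytest.approx(math.exp(-0.5), rel=1e-12)


@given(d=st.floats(0.0, 90.0))
def test_tuning_symmetry(d):
    """Activity is symmetric about the preferred PE."""
    params = pm.ModelParams(n_primitives=11)
    pop = pm.PrimitivePopulation.grid(params)
    i = 5
    mu_i = pop.mu[i]
    left = pm.tuning_activities(pop, mu_i - d)[i]
    right = pm.tuning_activities(pop, mu_i + d)[i]
    assert left == pytest.approx(right, rel=1e-12)


def test_tuning_rejects_nonfinite(grid_pop):
    with pytest.raises(ValueError):
        pm.tuning_activities(grid_pop, float("nan"))


def test_motor_command_basics():
    s = ModelState(weights=np.array([2.0]))
    assert pm.motor_command(s, np.array([0.5])) == pytest.approx(1.0)
    z = ModelState.zeros(7)
    assert pm.motor_command(z, np.ones(7)) == 0.0
    with pytest.raises(ValueError):
        pm.motor_command(z, np.ones(5))


def test_motor_command_linearity_and_permutation(rng):
    w = rng.normal(size=40)
    a = rng.uniform(0, 1, size=40)
    x = pm.motor_command(ModelState(weights=w), a)
    assert pm.motor_command(ModelState(weights=3.0 * w), a) == pytest.approx(3.0 * x)
    perm = rng.permutation(40)
    assert pm.motor_command(ModelState(weights=w[perm]), a[perm]) == pytest.approx(x)


@pytest.mark.parametrize(
    "p, x, mode, expected",
    [
        (30.0, 30.0, "normal", 0.0),
        (30.0, 10.0, "normal", 20.0),
        (30.0, 10.0, "channel", 30.0),  # executed command forced to 0
        (30.0, 25.0, "error_clamp", 0.0),
    ],
)
def test_movement_error_modes(p, x, mode, expected):
    assert pm.movement_error(p, x, mode) == pytest.approx(expected)


def test_movement_error_unknown_mode():
    with pytest.raises(ValueError):
        pm.movement_error(0.0, 0.0, "free")


@pytest.mark.parametrize(
    "pe, e, alpha, expected",
    [(0.0, 30.0, 0.8, 24.0), (5.0, 30.0, 1.0, 30.0), (5.0, 30.0, 0.0, 5.0)],
)
def test_update_pe(pe, e, alpha, expected):
    assert pm.update_pe(pe, e, alpha) == pytest.approx(expected)


def test_update_pe_rejects_bad_alpha():
    with pytest.raises(ValueError):
        pm.update_pe(0.0, 1.0, 1.5)


def test_update_weights_arithmetic():
    w = np.array([1.0, -2.0])
    a = np.array([0.5, 1.0])
    # degenerate rates leave weights untouched
    assert np.allclose(pm.update_weights(w, 5.0, a, lam=1.0, eta=0.0), w)
    # zero error is pure forgetting
    assert np.allclose(pm.update_weights(w, 0.0, a, lam=0.9, eta=2.0), 0.9 * w)
    # raw update at the default rates from the zero state
    out = pm.update_weights(np.zeros(3), 30.0, np.ones(3), lam=0.9586, eta=2.3913)
    assert np.allclose(out, 71.739)
    with pytest.raises(ValueError):
        pm.update_weights(w, 1.0, np.ones(3), 0.9, 1.0)


# ---------------------------------------------------------------------------
# the trial loop


def test_step_trial_fixed_point(best_params, grid_pop):
    """No perturbation, no noise: the zero state is a fixed point."""
    state = ModelState.zeros(len(grid_pop))
    state, rec = pm.step_trial(state, 0.0, "normal", best_params, grid_pop)
    assert rec.x == rec.e == 0.0
    assert state.pe_hat == 0.0
    assert np.all(state.weights == 0.0)


def test_step_trial_one_step_unroll(best_params, grid_pop):
    """First exposure: e equals the perturbation, PE moves by alpha*e and
    each weight gains eta_step * e * A_i(0)."""
    state = ModelState.zeros(len(grid_pop))
    new, rec = pm.step_trial(state, 30.0, "normal", best_params, grid_pop)
    assert rec.e == pytest.approx(30.0)
    assert new.pe_hat == pytest.approx(best_params.alpha * 30.0)
    a0 = pm.tuning_activities(grid_pop, 0.0)
    expected_w = _eta_step(best_params, grid_pop) * 30.0 * a0
    assert np.allclose(new.weights, expected_w)


def test_step_trial_two_step_matches_scalar_oracle(best_params):
    """Two constant-perturbation trials agree with an independently unrolled
    scalar computation of the same equations on a tiny population."""
    params = best_params.with_(n_primitives=9)
    pop = pm.PrimitivePopulation.grid(params)
    state = ModelState.zeros(9)
    for _ in range(2):
        state, rec = pm.step_trial(state, 30.0, "normal", params, pop)
    x2 = rec.x

    # oracle: direct loops over the defining formulas
    lam, alpha, sigma = params.lam, params.alpha, params.sigma
    eta_s = params.eta * REFERENCE_DENSITY / (
        2.0 * math.pi * sigma**2 * (9 / 360.0))
    mu = [-180 + (i + 0.5) * 40.0 for i in range(9)]
    w = [0.0] * 9
    pe = 0.0
    x_last = None
    for _ in range(2):
        acts = [math.exp(-((pe - m) ** 2) / (2 * sigma**2)) for m in mu]
        x_last = sum(wi * ai for wi, ai in zip(w, acts))
        e = 30.0 - x_last
        w = [lam * wi + eta_s * e * ai for wi, ai in zip(w, acts)]
        pe = pe + alpha * (e - pe)
    assert x2 == pytest.approx(x_last, rel=1e-12)


def test_step_trial_updates_during_channel_and_clamp(best_params, grid_pop):
    """Weights and PE keep updating on channel trials (x forced to 0) and
    the PE decays during error clamps."""
    state = ModelState.zeros(len(grid_pop))
    state, rec = pm.step_trial(state, 30.0, "channel", best_params, grid_pop)
    assert rec.x == 0.0
    assert rec.e == pytest.approx(30.0)
    assert state.pe_hat == pytest.approx(24.0)
    assert np.any(state.weights != 0.0)
    state, rec = pm.step_trial(state, 30.0, "error_clamp", best_params, grid_pop)
    assert rec.e == 0.0
    assert state.pe_hat == pytest.approx((1 - best_params.alpha) * 24.0)


def test_dynamics_insensitive_to_population_size(best_params):
    """Key outputs change by <2% between 1000 and 4000 primitives."""
    out = {}
    for n in (1000, 4000):
        params = best_params.with_(n_primitives=n)
        pop = pm.PrimitivePopulation.grid(params)
        state = ModelState.zeros(n)
        for _ in range(30):
            state, rec = pm.step_trial(state, 30.0, "normal", params, pop)
        out[n] = rec.x
    assert out[4000] == pytest.approx(out[1000], rel=0.02)


# ---------------------------------------------------------------------------
# closed forms


def test_inner_product_shape_ratio():
    """closed_form(delta)/closed_form(0) = exp(-delta^2/(4 sigma^2))."""
    sigma = 16.434
    c0 = pm.inner_product_closed_form(0.0, sigma, 1.0)
    c = pm.inner_product_closed_form(2 * sigma, sigma, 1.0)
    assert c / c0 == pytest.approx(math.exp(-1.0), rel=1e-12)


def test_inner_product_brute_force_small():
    params = pm.ModelParams(n_primitives=2048, mu_low=-720.0, mu_high=720.0)
    pop = pm.PrimitivePopulation.grid(params)
    for delta in (0.0, 15.0, 45.0):
        brute = pm.inner_product(pop, -10.0, -10.0 + delta)
        closed = pm.inner_product_closed_form(delta, pop.sigma, pop.density)
        assert brute == pytest.approx(closed, rel=1e-3)


def test_error_correction_properties(best_params):
    f = pm.error_correction
    assert f(0.0, best_params) == 0.0
    es = np.linspace(1.0, 80.0, 40)
    assert np.allclose(f(-es, best_params), -f(es, best_params))
    # numeric maximisation agrees with the closed-form peak location
    res = optimize.minimize_scalar(lambda e: -f(e, best_params),
                                   bounds=(1.0, 120.0), method="bounded")
    assert res.x == pytest.approx(pm.error_correction_peak(best_params), abs=1e-4)


def test_error_correction_matches_one_trial_simulation(best_params, grid_pop):
    """The closed form reproduces an actual two-trial simulation: observe e
    once from the naive state, then read out the next command."""
    for e_obs in (5.0, 20.0, 45.0):
        state = ModelState.zeros(len(grid_pop))
        # first trial: a channel trial delivering exactly e_obs
        state, _ = pm.step_trial(state, e_obs, "channel", best_params, grid_pop)
        a = pm.tuning_activities(grid_pop, state.pe_hat)
        x_next = pm.motor_command(state, a)
        assert x_next == pytest.approx(pm.error_correction(e_obs, best_params),
                                       rel=1e-6)


def test_uncertainty_averaged_correction(best_params):
    f = pm.uncertainty_averaged_correction
    # no blur reduces to the plain correction
    assert f(15.0, 0.0, best_params) == pytest.approx(
        pm.error_correction(15.0, best_params), rel=1e-12)
    # monotone decreasing in the blur at small positive error
    vals = [f(5.0, sg, best_params) for sg in (0.0, 10.0, 20.0, 40.0)]
    assert np.all(np.diff(vals) < 0)
    with pytest.raises(ValueError):
        f(5.0, -1.0, best_params)


def test_uncertainty_averaged_matches_quadrature(best_params):
    for sg in (18.0, 30.0, 36.0, 60.0):
        num, _ = integrate.quad(
            lambda xi: pm.error_correction(15.0 + xi, best_params)
            * math.exp(-(xi**2) / (2 * sg**2)) / (sg * math.sqrt(2 * math.pi)),
            -8 * sg, 8 * sg)
        closed = pm.uncertainty_averaged_correction(15.0, sg, best_params)
        assert closed == pytest.approx(num, rel=1e-6)


# ---------------------------------------------------------------------------
# Kalman correspondence


def test_kalman_gain_limits():
    assert pm.pe_kalman_equivalence(1e6, 1.0) == pytest.approx(1.0, abs=1e-5)
    assert pm.pe_kalman_equivalence(0.0, 1.0) == 0.0


def test_pe_update_matches_steady_state_kalman(rng):
    """Iterating the constant-gain PE update with alpha set to the
    steady-state gain matches the full time-varying Kalman predictor after
    burn-in on a simulated random-walk error sequence."""
    sz, sx = 2.0, 5.0
    alpha = pm.pe_kalman_equivalence(sz, sx)
    g = 0.0
    errors = []
    for _ in range(200):
        errors.append(g + rng.normal(0, sx))
        g += rng.normal(0, sz)

    # oracle: exact Kalman recursion with time-varying gain
    ghat, P = 0.0, 1e4  # diffuse prior
    kalman_pred = []
    for e in errors:
        S = P + sz**2
        K = S / (S + sx**2)
        ghat = ghat + K * (e - ghat)
        P = (1 - K) * S
        kalman_pred.append(ghat)

    pe = 0.0
    pe_pred = []
    for e in errors:
        pe = pm.update_pe(pe, e, alpha)
        pe_pred.append(pe)

    diff = np.abs(np.array(pe_pred) - np.array(kalman_pred))
    assert diff[50:].max() < 1e-6 * max(1.0, np.abs(errors).max())
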