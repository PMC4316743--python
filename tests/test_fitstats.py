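"""Tests for the fitting and statistics toolchain."""

import numpy as np
import pytest
from scipy import stats

import pemotor as pm
from pemotor.fitstats import fit_error_correction


# ---------------------------------------------------------------------------
# exponential fits


def test_exp_fit_exact_recovery():
    t = np.arange(40)
    y = 30.0 * np.exp(-0.3 * t) + 0.0
    fit = pm.exp_fit(y)
    assert fit.b == pytest.approx(0.3, abs=1e-6)
    assert fit.a == pytest.approx(30.0, abs=1e-5)
    assert fit.c == pytest.approx(0.0, abs=1e-5)
    assert not fit.degenerate


def test_exp_fit_rising_curve():
    """Learning curves that rise (negative amplitude) fit equally well."""
    t = np.arange(30)
    y = 25.0 * (1 - np.exp(-0.2 * t)) + 3.0
    fit = pm.exp_fit(y)
    assert fit.b == pytest.approx(0.2, abs=1e-6)
    assert fit.a == pytest.approx(-25.0, abs=1e-5)


def test_exp_fit_constant_series_flagged():
    fit = pm.exp_fit(np.full(10, 4.2))
    assert fit.degenerate
    assert fit.a == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValueError):
        pm.exp_fit([1.0, 2.0])


def test_exp_fit_noisy_recovery():
    """Group-averaged noisy curves (trial sd 5 deg over 12 subjects) recover
    the generating learning speed with ~7% mean relative error."""
    rng = np.random.default_rng(0)
    t = np.arange(30)
    rel_errs = []
    for _ in range(100):
        y = 30 * np.exp(-0.3 * t) + rng.normal(0, 5 / np.sqrt(12), 30)
        rel_errs.append(abs(pm.exp_fit(y).b - 0.3) / 0.3)
    assert np.mean(rel_errs) < 0.10


# ---------------------------------------------------------------------------
# state-space and affine fits


def test_state_space_exact_recovery(rng):
    A, B, p = 0.95, 0.2, 30.0
    x = np.zeros(60)
    e = np.zeros(60)
    for t in range(59):
        e[t] = p - x[t]
        x[t + 1] = A * x[t] + B * e[t]
    e[-1] = p - x[-1]
    fit = pm.state_space_fit(x, e)
    assert fit.A_retention == pytest.approx(A, abs=1e-10)
    assert fit.B_adaptation == pytest.approx(B, abs=1e-10)


def test_state_space_zero_error_flagged():
    x = 0.9 ** np.arange(10)
    fit = pm.state_space_fit(x, np.zeros(10))
    assert fit.degenerate
    assert np.isnan(fit.B_adaptation)
    assert fit.A_retention == pytest.approx(0.9, abs=1e-10)


def test_state_space_on_model_run(best_params):
    log = pm.run_schedule(best_params,
                          pm.constant_schedule(30.0, 50, "normal", "test"))
    fit = pm.state_space_fit(log.x, log.e)
    assert 0.0 < fit.A_retention <= 1.0
    assert 0.0 < fit.B_adaptation < 1.0


def test_affine_fit_exact_and_degenerate():
    f = np.linspace(-1, 1, 20)
    fit = pm.affine_fit(f, 2.0 * f + 3.0)
    assert (fit.m, fit.n) == (pytest.approx(2.0), pytest.approx(3.0))
    assert fit.r_squared == pytest.approx(1.0)
    # constant data vs varying model: zero gain, R^2 undefined
    flat = pm.affine_fit(f, np.full(20, 7.0))
    assert flat.m == pytest.approx(0.0)
    assert flat.degenerate and np.isnan(flat.r_squared)
    # constant model vs varying data: zero gain, R^2 = 0
    const_model = pm.affine_fit(np.full(20, 1.0), f)
    assert const_model.m == 0.0
    assert const_model.r_squared == pytest.approx(0.0)


def test_affine_fit_r2_decreases_with_noise(best_params, rng):
    es = np.linspace(-45, 45, 60)
    model = pm.error_correction(es, best_params)
    r2 = []
    for sd in (0.0, 2.0, 5.0, 10.0):
        data = 2.0 * model + 1.0 + rng.normal(0, sd, model.shape)
        r2.append(pm.affine_fit(model, data).r_squared)
    assert np.all(np.diff(r2) < 0)
    assert r2[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# model-parameter identification


def test_fit_error_correction_recovers_ratio(best_params, rng):
    es = rng.uniform(-45, 45, 200)
    f = 1.7 * pm.error_correction(es, best_params) - 0.4
    fit = fit_error_correction(es, f)
    truth = best_params.sigma / best_params.alpha
    assert fit.ratio == pytest.approx(truth, rel=1e-4)
    assert fit.scale.n == pytest.approx(-0.4, abs=1e-6)
    assert fit.scale.r_squared == pytest.approx(1.0)


def test_fit_model_params_requires_channel_phase(best_params):
    log = pm.run_schedule(best_params,
                          pm.constant_schedule(30.0, 10, "normal", "test"))
    df = log.to_frame()
    df["subject_id"] = "s0"
    df["angle_deg"] = df["x_deg"]
    df["force_au"] = np.nan
    with pytest.raises(ValueError):
        pm.fit_model_params(df, stage="error-correction")


# ---------------------------------------------------------------------------
# resampling


def test_bootstrap_identical_subjects_zero_variance(rng):
    curve = 30 * np.exp(-0.3 * np.arange(30))
    curves = np.tile(curve, (6, 1))
    res = pm.bootstrap_learning_speed(curves, n_boot=25, rng=rng)
    assert res.speeds.std() < 1e-12
    assert res.mean == pytest.approx(0.3, abs=1e-6)
    single = pm.bootstrap_learning_speed(curves, n_boot=1, rng=rng)
    assert single.n_boot == 1 and single.speeds.size == 1


def test_randomization_identical_samples(rng):
    a = np.full(20, 1.0)
    p = pm.randomization_test(a, a.copy(), n_perm=200, rng=rng)
    assert p == pytest.approx(1.0)


def test_randomization_separated_samples(rng):
    a = np.ones(15) + 10
    b = np.zeros(15)
    p = pm.randomization_test(a, b, n_perm=999, rng=rng)
    assert p == pytest.approx(1 / 1000)


def test_randomization_two_sided_label_swap(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.5, 1, 12)
    p_ab = pm.randomization_test(a, b, n_perm=500,
                                 rng=np.random.default_rng(5),
                                 alternative="two-sided")
    p_ba = pm.randomization_test(b, a, n_perm=500,
                                 rng=np.random.default_rng(5),
                                 alternative="two-sided")
    assert p_ab == p_ba


def test_randomization_null_uniform_small():
    """Under the null, one-sided permutation p-values are uniform (coarse
    check; the acceptance suite runs the full calibration)."""
    rng = np.random.default_rng(77)
    ps = [
        pm.randomization_test(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                              n_perm=199, rng=rng)
        for _ in range(60)
    ]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# screening and filtering


def test_exclude_outliers_keeps_equal_values():
    kept, removed = pm.exclude_outliers(np.full(10, 3.3))
    assert removed.size == 0 and kept.size == 10


def test_exclude_outliers_removes_extreme_point():
    v = np.array([0.0] * 11 + [100.0])
    kept, removed = pm.exclude_outliers(v)
    assert list(removed) == [100.0]
    assert kept.size == 11


def test_moving_average():
    assert np.allclose(pm.moving_average(np.full(20, 2.5), 16), 2.5)
    alt = np.resize([1.0, -1.0], 32)
    assert np.allclose(pm.moving_average(alt, 16), 0.0)
    ramp = np.arange(1.0, 33.0)
    out = pm.moving_average(ramp, 16)
    assert out[0] == pytest.approx(8.5)
    assert out.size == 17
    with pytest.raises(ValueError):
        pm.moving_average(np.arange(10.0), 16)
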