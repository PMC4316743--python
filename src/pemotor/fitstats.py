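"""Fitting and statistical procedures for trial-by-trial learning data.

Covers the analysis toolchain used around the model: exponential
learning-speed fits, linear state-space fits, affine scaling between model
output and measured data, the two-stage identification of the model
parameters from behavioural trial tables, subject-level bootstrap of
learning speeds, randomization (permutation) tests, a mean +/- 3 sd outlier
screen, and uniform moving-average filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ModelParams
from .protocols import constant_schedule, run_schedule

__all__ = [
    "ExpFit",
    "StateSpaceFit",
    "AffineScale",
    "ResampleResult",
    "Stage1Fit",
    "Stage2Fit",
    "exp_fit",
    "state_space_fit",
    "affine_fit",
    "fit_error_correction",
    "fit_learning_curve",
    "fit_model_params",
    "bootstrap_learning_speed",
    "randomization_test",
    "exclude_outliers",
    "moving_average",
    "ALPHA_GRID",
]

#: Grid over which the PE update gain is searched in the learning-curve fit.
#: The 0 point is excluded: the fit ties sigma to alpha through the
#: error-correction ratio, and alpha = 0 would force a zero tuning width.
ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


@dataclass(frozen=True)
class ExpFit:
    """Exponential learning-curve fit ``y_t = a exp(-b t) + c``.

    ``b`` is the learning speed (per trial).  ``degenerate`` flags series on
    which the decay rate is unidentifiable (e.g. constant input).
    """

    a: float
    b: float
    c: float
    rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class StateSpaceFit:
    """Linear state-space fit ``x_{t+1} = A x_t + B e_t``.

    ``A_retention`` is the retention (forgetting) factor and
    ``B_adaptation`` the adaptation rate; with the error convention
    ``e = p - x``, ``B > 0`` means the command moves to reduce the error.
    """

    A_retention: float
    B_adaptation: float
    rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class AffineScale:
    """Affine map ``data ~ m * model + n`` with goodness of fit."""

    m: float
    n: float
    r_squared: float
    degenerate: bool = False


@dataclass(frozen=True)
class ResampleResult:
    """Bootstrap distribution of a learning speed."""

    speeds: np.ndarray
    mean: float
    n_boot: int


@dataclass(frozen=True)
class Stage1Fit:
    """Error-correction stage: identified sigma/alpha ratio and data scale."""

    ratio: float
    scale: AffineScale


@dataclass(frozen=True)
class Stage2Fit:
    """Learning-curve stage: full parameter set on the alpha grid."""

    params: ModelParams
    rss: float
    rss_by_alpha: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary fits


def _exp_profile_rss(b: float, t: np.ndarray, y: np.ndarray):
    """Least-squares (a, c) and residual for fixed decay rate b."""
    E = np.exp(-b * t)
    X = np.column_stack([E, np.ones_like(E)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = X @ coef - y
    return float(r @ r), float(coef[0]), float(coef[1])


def exp_fit(series, t0: int = 0, b_max: float = 3.0) -> ExpFit:
    """Fit ``y_t = a exp(-b t) + c`` by profiled least squares.

    For fixed ``b`` the model is linear in ``(a, c)``, so the fit reduces to
    a 1-D search over ``b``: a dense multi-start grid followed by local
    refinement.  ``t0`` shifts the trial origin.  Raises on fewer than 4
    points; a constant series is returned with ``a ~ 0`` and flagged
    degenerate.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("need a 1-D series of at least 4 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    t = np.arange(t0, t0 + y.size, dtype=float)
    if np.ptp(y) < 1e-12:
        return ExpFit(a=0.0, b=0.0, c=float(y.mean()), rss=0.0, degenerate=True)

    grid = np.linspace(1e-3, b_max, 120)
    rss = np.array([_exp_profile_rss(b, t, y)[0] for b in grid])
    k = int(np.argmin(rss))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda b: _exp_profile_rss(b, t, y)[0], bounds=(lo, hi),
        method="bounded", options={"xatol": 1e-10},
    )
    b = float(res.x)
    r, a, c = _exp_profile_rss(b, t, y)
    degenerate = abs(a) < 1e-8 * max(1.0, abs(c))
    return ExpFit(a=a, b=b, c=c, rss=r, degenerate=degenerate)


def state_space_fit(x_series, e_series) -> StateSpaceFit:
    """Ordinary least squares on ``x_{t+1} = A x_t + B e_t``.

    ``B`` is reported so that positive values mean adaptation under the
    ``e = p - x`` error convention.  An all-zero error series leaves ``B``
    unidentifiable: the retention factor is fit alone and the result is
    flagged.  A genuinely singular design raises.
    """
    x = np.asarray(x_series, dtype=float)
    e = np.asarray(e_series, dtype=float)
    if x.shape != e.shape or x.ndim != 1:
        raise ValueError("x_series and e_series must be aligned 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 trials")
    y = x[1:]
    if np.allclose(e, 0.0):
        xx = float(x[:-1] @ x[:-1])
        if xx == 0.0:
            return StateSpaceFit(0.0, np.nan, 0.0, degenerate=True)
        A = float(x[:-1] @ y) / xx
        r = y - A * x[:-1]
        return StateSpaceFit(A, np.nan, float(r @ r), degenerate=True)
    X = np.column_stack([x[:-1], e[:-1]])
    if np.linalg.matrix_rank(X) < 2:
        raise np.linalg.LinAlgError("singular design in state-space fit")
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = X @ coef - y
    return StateSpaceFit(float(coef[0]), float(coef[1]), float(r @ r))


def affine_fit(model_curve, data_curve) -> AffineScale:
    """Closed-form least-squares affine scaling of a model curve onto data.

    Returns gain ``m``, offset ``n`` and ``R^2 = 1 - SSE/SST``.  Data with
    zero variance leave ``R^2`` undefined (NaN, flagged); a constant model
    curve gets ``m = 0``.
    """
    f = np.asarray(model_curve, dtype=float)
    d = np.asarray(data_curve, dtype=float)
    if f.shape != d.shape or f.ndim != 1:
        raise ValueError("model and data curves must be aligned 1-D arrays")
    sst = float(((d - d.mean()) ** 2).sum())
    var_f = float(((f - f.mean()) ** 2).sum())
    if var_f == 0.0:
        m = 0.0
        n = float(d.mean())
    else:
        m = float(((f - f.mean()) * (d - d.mean())).sum() / var_f)
        n = float(d.mean() - m * f.mean())
    sse = float(((m * f + n - d) ** 2).sum())
    if sst == 0.0:
        return AffineScale(m=m, n=n, r_squared=np.nan, degenerate=True)
    return AffineScale(m=m, n=n, r_squared=1.0 - sse / sst)


# ---------------------------------------------------------------------------
# model-parameter identification


def _correction_shape(e: np.ndarray, ratio: float) -> np.ndarray:
    """Error-correction shape ``e exp(-e^2 / (4 ratio^2))`` with
    ``ratio = sigma / alpha`` (scale absorbed by the affine fit)."""
    return e * np.exp(-(e * e) / (4.0 * ratio**2))


def fit_error_correction(e_obs, f_next, ratio_bounds=(2.0, 120.0)) -> Stage1Fit:
    """Identify ``sigma/alpha`` from (error, next-trial correction) pairs.

    Under the naive-state assumption (weights and PE at 0) the corrective
    response is ``f(e) = m e exp(-e^2 / (4 (sigma/alpha)^2)) + n`` — only the
    ratio ``sigma/alpha`` is identifiable, with the affine pair ``(m, n)``
    absorbing the units of the measured response (e.g. channel force).  The
    ratio is found by profiled least squares: for each candidate ratio the
    affine map is solved in closed form.
    """
    e = np.asarray(e_obs, dtype=float)
    f = np.asarray(f_next, dtype=float)
    if e.shape != f.shape or e.size < 4:
        raise ValueError("need aligned error/correction pairs (>= 4)")

    def rss(r: float) -> float:
        fit = affine_fit(_correction_shape(e, r), f)
        return float(((fit.m * _correction_shape(e, r) + fit.n - f) ** 2).sum())

    grid = np.geomspace(ratio_bounds[0], ratio_bounds[1], 80)
    vals = np.array([rss(r) for r in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(rss, bounds=(lo, hi), method="bounded")
    ratio = float(res.x)
    scale = affine_fit(_correction_shape(e, ratio), f)
    return Stage1Fit(ratio=ratio, scale=scale)


def _simulated_test_curve(lam, eta, alpha, sigma, p, n_trials, n_primitives):
    params = ModelParams(lam=lam, eta=eta, alpha=alpha, sigma=sigma,
                         n_primitives=n_primitives)
    sched = constant_schedule(p, n_trials, mode="normal", phase="test")
    return run_schedule(params, sched).x


def _batch_group_sim(lam, eta, alpha, sigma, P, modes, test_cols, n_primitives=256):
    """Noiseless batch simulation of several subjects' recorded schedules.

    ``P`` is (n_subjects, n_trials) of perturbations, ``modes`` the shared
    per-trial mode sequence; returns the across-subject mean command over
    the ``test_cols`` trial range.  Vectorised over subjects so the fitting
    objective stays cheap.
    """
    from .core import REFERENCE_DENSITY

    n_subj, n_trials = P.shape
    span = 360.0
    mu = -180.0 + (np.arange(n_primitives) + 0.5) * span / n_primitives
    rho = n_primitives / span
    eta_step = eta * REFERENCE_DENSITY / (2.0 * np.pi * sigma**2 * rho)
    W = np.zeros((n_subj, n_primitives))
    pe = np.zeros(n_subj)
    xs = np.zeros((n_subj, n_trials))
    for t in range(n_trials):
        A = np.exp(-((pe[:, None] - mu) ** 2) / (2.0 * sigma**2))
        x_raw = np.einsum("ij,ij->i", W, A)
        mode = modes[t]
        if mode == "channel":
            x = np.zeros(n_subj)
            e = P[:, t].copy()
        elif mode == "error_clamp":
            x = x_raw
            e = np.zeros(n_subj)
        else:
            x = x_raw
            e = P[:, t] - x
        W = lam * W + eta_step * e[:, None] * A
        pe = pe + alpha * (e - pe)
        xs[:, t] = x
    return xs[:, test_cols].mean(axis=0)


def fit_learning_curve(
    curve,
    ratio: float,
    p: float = 30.0,
    alpha_grid=ALPHA_GRID,
    n_primitives: int = 512,
) -> Stage2Fit:
    """Identify ``(lam, eta, alpha, sigma)`` from a test-phase learning curve.

    ``curve`` is the per-trial compensatory movement angle under a constant
    perturbation ``p``, starting from the naive state.  ``sigma`` is tied to
    ``alpha`` through the stage-1 ratio (``sigma = ratio * alpha``); for each
    ``alpha`` on the grid, ``(lam, eta)`` are fit by nonlinear least squares
    against the deterministic model simulation, and the grid point with the
    smallest residual wins.
    """
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("need a 1-D learning curve of at least 5 trials")
    n = y.size
    best = None
    rss_by_alpha: dict[float, float] = {}
    for alpha in alpha_grid:
        sigma = ratio * alpha

        def resid(theta, alpha=alpha, sigma=sigma):
            lam = 1.0 / (1.0 + np.exp(-theta[0]))  # (0, 1)
            eta = np.exp(theta[1])
            return _simulated_test_curve(lam, eta, alpha, sigma, p, n,
                                         n_primitives) - y

        theta0 = np.array([np.log(0.95 / 0.05), np.log(1.0)])
        sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-10)
        rss = float(sol.fun @ sol.fun)
        rss_by_alpha[float(alpha)] = rss
        lam = float(1.0 / (1.0 + np.exp(-sol.x[0])))
        eta = float(np.exp(sol.x[1]))
        if best is None or rss < best[0]:
            best = (rss, lam, eta, float(alpha), float(sigma))
    rss, lam, eta, alpha, sigma = best
    params = ModelParams(lam=lam, eta=eta, alpha=alpha, sigma=sigma,
                         n_primitives=n_primitives)
    return Stage2Fit(params=params, rss=rss, rss_by_alpha=rss_by_alpha)


def fit_model_params(trial_table: pd.DataFrame, stage: str = "full"):
    """Fit model parameters from a trial table (see :mod:`pemotor.io`).

    stage ``"error-correction"``
        Uses channel-phase (error, next-trial force) pairs; returns a
        :class:`Stage1Fit` with the ``sigma/alpha`` ratio and affine scale.
    stage ``"learning-curve"``
        Runs stage 1, then fits the across-subject mean test-phase movement
        angle; returns a :class:`Stage2Fit` whose ``params`` is the full
        :class:`~pemotor.core.ModelParams`.
    stage ``"full"``
        Returns ``(Stage1Fit, Stage2Fit)``.
    """
    if stage not in ("error-correction", "learning-curve", "full"):
        raise ValueError(f"unknown stage {stage!r}")
    tbl = trial_table
    if "excluded" in tbl.columns:
        tbl = tbl[~tbl["excluded"].astype(bool)]
    # pool clockwise and counter-clockwise subjects on a common sign
    tbl = tbl.copy()
    signed_cols = [c for c in ("p_deg", "x_deg", "e_deg", "pe_hat_deg",
                               "angle_deg", "force_au") if c in tbl.columns]
    for sid, sub in tbl[tbl["phase"] == "test"].groupby("subject_id"):
        if float(sub["p_deg"].median()) < 0:
            m = tbl["subject_id"] == sid
            tbl.loc[m, signed_cols] = -tbl.loc[m, signed_cols]

    chan = tbl[tbl["mode"] == "channel"]
    if chan.empty:
        raise ValueError("trial table has no channel trials for stage 1")
    pairs_e, pairs_f = [], []
    for _, sub in chan.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial")
        e = sub["e_deg"].to_numpy()
        f = sub["force_au"].to_numpy()
        trial = sub["trial"].to_numpy()
        consec = np.diff(trial) == 1
        pairs_e.append(e[:-1][consec])
        pairs_f.append(f[1:][consec])
    stage1 = fit_error_correction(np.concatenate(pairs_e), np.concatenate(pairs_f))
    if stage == "error-correction":
        return stage1

    test = tbl[(tbl["phase"] == "test") & (tbl["mode"] == "normal")]
    if test.empty:
        raise ValueError("trial table has no test trials for stage 2")
    curve = test.groupby("trial")["angle_deg"].mean().sort_index().to_numpy()

    # re-simulate each subject's recorded perturbation schedule, so the
    # fit accounts for whatever memory the training phase left behind
    subjects = sorted(tbl["subject_id"].unique())
    P = np.stack([
        tbl[tbl["subject_id"] == s].sort_values("trial")["p_deg"].to_numpy()
        for s in subjects
    ])
    first = tbl[tbl["subject_id"] == subjects[0]].sort_values("trial")
    modes = first["mode"].tolist()
    trials = first["trial"].to_numpy()
    test_trials = np.sort(test["trial"].unique())
    test_cols = np.searchsorted(trials, test_trials)

    best = None
    rss_by_alpha: dict[float, float] = {}
    for alpha in ALPHA_GRID:
        sigma_a = stage1.ratio * alpha

        def resid(theta, alpha=alpha, sigma_a=sigma_a):
            lam = 1.0 / (1.0 + np.exp(-theta[0]))
            eta = np.exp(theta[1])
            return _batch_group_sim(lam, eta, alpha, sigma_a, P, modes,
                                    test_cols) - curve

        theta0 = np.array([np.log(0.95 / 0.05), np.log(1.0)])
        sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-10)
        rss = float(sol.fun @ sol.fun)
        rss_by_alpha[float(alpha)] = rss
        if best is None or rss < best[0]:
            best = (rss, float(1.0 / (1.0 + np.exp(-sol.x[0]))),
                    float(np.exp(sol.x[1])), float(alpha), float(sigma_a))
    rss, lam, eta, alpha, sigma = best
    stage2 = Stage2Fit(
        params=ModelParams(lam=lam, eta=eta, alpha=alpha, sigma=sigma),
        rss=rss, rss_by_alpha=rss_by_alpha)
    if stage == "learning-curve":
        return stage2
    return stage1, stage2


# ---------------------------------------------------------------------------
# resampling and screening


def bootstrap_learning_speed(
    subject_curves, n_boot: int = 3000, rng: np.random.Generator | None = None,
    t0: int = 0,
) -> ResampleResult:
    """Bootstrap the learning speed over subjects.

    ``subject_curves`` is (n_subjects, n_trials).  Each resample draws
    subjects with replacement, averages their curves, and fits the
    exponential learning model; the distribution of the fitted ``b`` is
    returned with its mean.
    """
    curves = np.asarray(subject_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_trials) array")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_subj = curves.shape[0]
    speeds = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        speeds[i] = exp_fit(curves[idx].mean(axis=0), t0=t0).b
    return ResampleResult(speeds=speeds, mean=float(speeds.mean()), n_boot=n_boot)


def randomization_test(
    speeds_a,
    speeds_b,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> float:
    """Permutation test on the difference of group means.

    The two samples are pooled and repeatedly split at random into groups of
    the original sizes; the p-value is the fraction of splits whose mean
    difference is at least as extreme as the observed one, with an add-one
    correction so p is never exactly 0.  ``alternative`` is ``"greater"``
    (mean(a) > mean(b)), ``"less"``, or ``"two-sided"`` (|difference|).
    """
    a = np.asarray(speeds_a, dtype=float)
    b = np.asarray(speeds_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if rng is None:
        rng = np.random.default_rng()
    # sorting the pool makes the resampling depend only on the pooled
    # multiset, so two-sided p-values are exactly label-swap invariant
    pooled = np.sort(np.concatenate([a, b]))
    na = a.size
    obs = a.mean() - b.mean()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:na].mean() - perm[na:].mean()
        if alternative == "greater":
            extreme = d >= obs
        elif alternative == "less":
            extreme = d <= obs
        else:
            extreme = abs(d) >= abs(obs)
        count += bool(extreme)
    return (1 + count) / (1 + n_perm)


def exclude_outliers(values):
    """One-pass mean +/- 3 sd screen.

    Mean and sd are computed once on the full sample; values outside the
    band are removed.  Returns ``(kept, removed)`` arrays.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    mu = v.mean()
    sd = v.std(ddof=1)
    mask = np.abs(v - mu) <= 3.0 * sd
    return v[mask], v[~mask]


def moving_average(series, window: int = 16):
    """Uniform trailing moving average.

    Output ``t`` is the mean of the window ending at ``t``; the result has
    ``len(series) - window + 1`` points (aligned to window ends).
    """
    y = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if y.size < window:
        raise ValueError(f"series shorter than window ({y.size} < {window})")
    return np.convolve(y, np.ones(window) / window, mode="valid")
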