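import numpy as np
import pytest
from scipy import stats

from cvdfusion.leecarter import (
    aggregate_projection,
    annualized_change,
    fit_lee_carter,
    fit_rwd,
    fit_strata,
    project,
    project_series,
)

A, T = 8, 17
YEARS = np.arange(2003, 2020)


def make_rank1(seed=0, kappa_drift=-0.3, kappa_sd=0.4):
    """A surface that satisfies the model exactly, with valid constraints."""
    rng = np.random.default_rng(seed)
    ax = np.linspace(-8.0, -5.0, A) + rng.normal(0, 0.1, A)
    b = np.abs(rng.normal(1.0, 0.3, A))
    b /= b.sum()
    kappa = np.cumsum(kappa_drift + kappa_sd * rng.standard_normal(T))
    kappa -= kappa.mean()
    return ax, b, kappa, ax[:, None] + b[:, None] * kappa[None, :]


def test_noiseless_rank1_recovery():
    """Exact rank-1 input built from known (a, b, kappa): all three factors
    recovered to 1e-8."""
    ax, b, kappa, log_m = make_rank1(seed=1)
    fit = fit_lee_carter(log_m, YEARS)
    assert not fit.degenerate
    np.testing.assert_allclose(fit.ax, ax, atol=1e-8)
    np.testing.assert_allclose(fit.bx, b, atol=1e-8)
    np.testing.assert_allclose(fit.kappa, kappa, atol=1e-8)
    assert fit.explained_ratio == pytest.approx(1.0, abs=1e-10)


def test_constant_surface_degenerate():
    log_m = np.tile(np.linspace(-8, -5, A)[:, None], (1, T))
    fit = fit_lee_carter(log_m, YEARS)
    assert fit.degenerate
    np.testing.assert_allclose(fit.ax, log_m[:, 0])
    np.testing.assert_allclose(fit.kappa, 0.0)
    np.testing.assert_allclose(fit.bx, 1.0 / A)


@pytest.mark.parametrize("seed", range(8))
def test_constraints_on_noisy_fits(seed):
    """Sum(b)=1 and sum(kappa)=0 to 1e-10 on every fit, noisy or not."""
    _, _, _, log_m = make_rank1(seed=seed)
    noisy = log_m + np.random.default_rng(seed + 100).normal(0, 0.05, (A, T))
    fit = fit_lee_carter(noisy, YEARS)
    assert abs(fit.bx.sum() - 1.0) < 1e-10
    assert abs(fit.kappa.sum()) < 1e-10


def test_noisy_recovery_bounded_by_noise_scale():
    """With residual sd 0.02, the reconstructed rank-1 surface stays within
    3x the noise sd of the true surface (RMSE), across 100 seeds."""
    rmses = []
    for seed in range(100):
        _, _, _, log_m = make_rank1(seed=seed)
        noisy = log_m + np.random.default_rng(seed + 500).normal(0, 0.02, (A, T))
        fit = fit_lee_carter(noisy, YEARS)
        rmses.append(np.sqrt(np.mean((fit.fitted_log - log_m) ** 2)))
    assert max(rmses) < 3 * 0.02


def test_translation_equivariance():
    """Adding a constant to the log surface shifts a_x only."""
    _, _, _, log_m = make_rank1(seed=3)
    noisy = log_m + np.random.default_rng(7).normal(0, 0.05, (A, T))
    f0, f1 = fit_lee_carter(noisy, YEARS), fit_lee_carter(noisy + 1.7, YEARS)
    np.testing.assert_allclose(f1.ax, f0.ax + 1.7, atol=1e-10)
    np.testing.assert_allclose(f1.bx, f0.bx, atol=1e-12)
    np.testing.assert_allclose(f1.kappa, f0.kappa, atol=1e-10)
    assert f1.drift == pytest.approx(f0.drift, abs=1e-12)
    assert f1.sigma == pytest.approx(f0.sigma, abs=1e-12)


def test_drift_sign_matches_mean_trend():
    """The fitted drift carries the sign of the mean per-year change of the
    age-averaged log rate (the sum-to-one normalization fixes the SVD sign
    ambiguity)."""
    for seed, drift in [(2, -0.5), (4, 0.4)]:
        _, _, _, log_m = make_rank1(seed=seed, kappa_drift=drift)
        noisy = log_m + np.random.default_rng(seed).normal(0, 0.03, (A, T))
        fit = fit_lee_carter(noisy, YEARS)
        mean_change = np.mean(noisy[:, -1] - noisy[:, 0]) / (T - 1)
        assert np.sign(fit.drift) == np.sign(mean_change)


# -- random walk with drift -------------------------------------------------


def test_rwd_exact_line():
    d, s = fit_rwd(np.array([0.0, 1.0, 2.0, 3.0]))
    assert d == 1.0 and s == 0.0
    d0, _ = fit_rwd(np.zeros(5))
    assert d0 == 0.0
    with pytest.raises(ValueError):
        fit_rwd(np.array([0.0, 1.0]))


def test_rwd_sigma_denominator():
    """sigma uses denominator T-2."""
    k = np.array([0.0, 1.0, 1.0, 2.0])       # diffs 1, 0, 1 -> d = 2/3
    d, s = fit_rwd(k)
    diffs = np.diff(k)
    assert s == pytest.approx(np.sqrt(((diffs - d) ** 2).sum() / 2))


# -- projection -------------------------------------------------------------


def test_projection_zero_sigma_exact_line():
    ax, b, kappa, log_m = make_rank1(seed=5)
    # force an exact linear kappa so sigma == 0
    kappa_lin = np.linspace(-4, 4, T) * 1.0
    log_m = ax[:, None] + b[:, None] * kappa_lin[None, :]
    fit = fit_lee_carter(log_m, YEARS)
    assert fit.sigma == pytest.approx(0.0, abs=1e-9)
    pr = project(fit, 10)
    np.testing.assert_allclose(pr.log_upper, pr.log_lower, atol=1e-7)
    # central continues the exact line
    step = kappa_lin[1] - kappa_lin[0]
    expect = ax[:, None] + b[:, None] * (kappa_lin[-1] + step * np.arange(1, 11))[None, :]
    np.testing.assert_allclose(pr.log_central, expect, atol=1e-7)


def test_projection_continuous_at_jumpoff():
    """Central forecast at h=1 differs from the fitted final-year value by
    exactly b_x * d under the fitted jump-off."""
    _, _, _, log_m = make_rank1(seed=6)
    noisy = log_m + np.random.default_rng(11).normal(0, 0.05, (A, T))
    fit = fit_lee_carter(noisy, YEARS)
    pr = project(fit, 5)
    np.testing.assert_allclose(
        pr.log_central[:, 0] - fit.fitted_log[:, -1], fit.bx * fit.drift, atol=1e-12
    )


def test_projection_observed_jumpoff():
    _, _, _, log_m = make_rank1(seed=8)
    noisy = log_m + np.random.default_rng(12).normal(0, 0.05, (A, T))
    fit = fit_lee_carter(noisy, YEARS)
    pr = project(fit, 5, jumpoff="observed", observed_last_log=noisy[:, -1])
    np.testing.assert_allclose(
        pr.log_central[:, 0] - noisy[:, -1], fit.bx * fit.drift, atol=1e-12
    )


def test_degenerate_projection_flat():
    log_m = np.tile(np.linspace(-8, -5, A)[:, None], (1, T))
    fit = fit_lee_carter(log_m, YEARS)
    pr = project(fit, 10)
    np.testing.assert_allclose(pr.log_central, log_m[:, :1] * np.ones((1, 10)))
    np.testing.assert_allclose(pr.log_upper - pr.log_lower, 0.0)


def test_projection_interval_widens_and_orders():
    _, _, _, log_m = make_rank1(seed=9)
    noisy = log_m + np.random.default_rng(13).normal(0, 0.05, (A, T))
    pr = project(fit_lee_carter(noisy, YEARS), 10)
    assert (pr.log_lower <= pr.log_central).all() and (pr.log_central <= pr.log_upper).all()
    widths = pr.log_upper - pr.log_lower
    assert (np.diff(widths, axis=1) >= -1e-12).all()
    with pytest.raises(ValueError):
        project(fit_lee_carter(noisy, YEARS), 0)


def test_aggregate_projection_weighted_mean():
    _, _, _, log_m = make_rank1(seed=10)
    fit = fit_lee_carter(log_m + np.random.default_rng(3).normal(0, 0.02, (A, T)), YEARS)
    pr = project(fit, 4)
    w = np.arange(1.0, A + 1.0)
    agg = aggregate_projection(pr, w)
    expect = (w / w.sum()) @ pr.central
    np.testing.assert_allclose(agg["prob"], expect, rtol=1e-12)
    assert (agg["lower"] <= agg["prob"]).all() and (agg["prob"] <= agg["upper"]).all()


def test_project_series_matches_rwd_math():
    series = np.log(np.array([3e-3 * 1.02**t for t in range(10)]))
    out = project_series(series, np.arange(2010, 2020), horizon=3)
    np.testing.assert_allclose(out["prob"], 3e-3 * 1.02 ** np.arange(10, 13), rtol=1e-9)


# -- annualized change ------------------------------------------------------


def test_annualized_change_closed_forms():
    years = np.arange(2003, 2020)
    expo = np.full(years.size, 1e9)
    flat = annualized_change(0.002 * expo, expo, years)
    assert flat[0] == pytest.approx(0.0, abs=1e-8)
    growth = annualized_change(0.002 * 1.02 ** np.arange(years.size) * expo, expo, years)
    assert growth[0] == pytest.approx(2.0, abs=1e-6)
    # rates exactly halving over the span
    g = 0.5 ** (1.0 / (years.size - 1))
    halving = annualized_change(0.002 * g ** np.arange(years.size) * expo, expo, years)
    assert halving[0] == pytest.approx(100 * (g - 1), abs=1e-6)


def test_annualized_change_errors():
    with pytest.raises(ValueError):
        annualized_change(np.zeros(5), np.full(5, 1e6), np.arange(5))
    with pytest.raises(ValueError):
        annualized_change(np.array([3.0]), np.array([1e6]), np.array([2003]))


def test_fit_strata_runs_per_stratum(small_run):
    fits = fit_strata(small_run["surface"])
    assert len(fits) == 12
    for fit in fits.values():
        assert abs(fit.bx.sum() - 1.0) < 1e-10
        assert abs(fit.kappa.sum()) < 1e-10
        assert fit.kappa.size == 17
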