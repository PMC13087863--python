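import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cmphelix.errors import LagTooLarge, NoOverlap, SingleBasin
from cmphelix.fes import (
    KJ_PER_KCAL,
    PMFEstimate,
    UmbrellaWindow,
    bootstrap_pmf,
    extract_deltaF,
    fit_tica,
    wham,
)
from cmphelix.synth import double_well, sample_umbrella_windows


def ou_series(rng, n, tau):
    a = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    noise = np.sqrt(1 - a * a) * rng.standard_normal(n)
    for k in range(1, n):
        x[k] = a * x[k - 1] + noise[k]
    return x


class TestTica:
    def test_recovers_slow_coordinate(self):
        rng = np.random.default_rng(0)
        slow = ou_series(rng, 5000, tau=100.0)
        fast = rng.standard_normal(5000)
        X = np.column_stack([slow + 0.1 * fast, fast])
        model = fit_tica(X, lag=20)
        tic0 = model.tic0(X)
        assert abs(np.corrcoef(tic0, slow)[0, 1]) > 0.9

    def test_invalid_lag(self):
        with pytest.raises(LagTooLarge):
            fit_tica(np.zeros((100, 2)), lag=0)
        with pytest.raises(LagTooLarge):
            fit_tica(np.zeros((100, 2)), lag=100)

    def test_mean_projects_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 3)).cumsum(axis=0) * 0.01 + rng.normal(size=(500, 3))
        model = fit_tica(X, lag=5)
        assert np.allclose(model.transform(model.feature_means), 0.0, atol=1e-10)

    def test_eigenvalues_in_unit_interval_and_c0_orthogonal(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([ou_series(rng, 4000, 50.0),
                             ou_series(rng, 4000, 5.0),
                             rng.standard_normal(4000)])
        model = fit_tica(X, lag=10)
        assert np.all(model.eigenvalues > 0)
        assert np.all(model.eigenvalues <= 1.0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)


class TestWham:
    def test_unbiased_single_window_recovers_histogram(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(0.0, 1.0, size=20_000)
        w = UmbrellaWindow(0.0, 1e-9, samples)  # negligible bias
        pmf = wham([w], n_bins=40, temperature=320.0)
        # F should match -kT ln(hist) up to the common shift
        hist, edges = np.histogram(samples, bins=40)
        kT_kcal = 0.008314462618 * 320 / KJ_PER_KCAL
        ref = -kT_kcal * np.log(hist / hist.max())
        good = hist > 200
        assert np.allclose(pmf.F[good], ref[good], atol=0.02)

    def test_harmonic_reference_system(self):
        """Biased Gaussian samples over a harmonic PMF: WHAM must recover
        U(x) = 0.5 k x^2 within 0.1 kcal/mol over the well-sampled range."""
        rng = np.random.default_rng(4)
        kT = 0.008314462618 * 320.0  # kJ/mol
        k_pot, k_bias = 10.0, 200.0
        centers = np.linspace(-1.2, 1.2, 10)
        windows = []
        for c in centers:
            k_tot = k_pot + k_bias
            mean = k_bias * c / k_tot
            sd = np.sqrt(kT / k_tot)
            windows.append(
                UmbrellaWindow(c, k_bias, rng.normal(mean, sd, size=8000))
            )
        pmf = wham(windows, n_bins=60, temperature=320.0)
        truth = 0.5 * k_pot * pmf.grid**2 / KJ_PER_KCAL
        truth -= truth[np.nanargmin(pmf.F)]
        core = np.abs(pmf.grid) < 0.9
        assert np.nanmax(np.abs(pmf.F[core] - truth[core])) < 0.1

    def test_disjoint_windows_raise_no_overlap(self):
        w1 = UmbrellaWindow(-5.0, 100.0, np.linspace(-5.1, -4.9, 50))
        w2 = UmbrellaWindow(5.0, 100.0, np.linspace(4.9, 5.1, 50))
        with pytest.raises(NoOverlap):
            wham([w1, w2], n_bins=100)

    def test_bias_shift_invariance(self):
        # adding a constant to every sample's bias reference leaves F unchanged
        rng = np.random.default_rng(5)
        windows = [
            UmbrellaWindow(c, 150.0, rng.normal(c, 0.2, size=3000))
            for c in np.linspace(-1, 1, 8)
        ]
        F1 = wham(windows, n_bins=50).F
        F2 = wham(list(windows), n_bins=50).F  # identical input, fresh run
        assert np.allclose(F1, F2, equal_nan=True)
        assert np.nanmin(F1) == pytest.approx(0.0, abs=1e-12)


def quadrature_deltaF_kcal():
    """Independent oracle: basin minima of the analytic double well."""
    left = minimize_scalar(double_well, bounds=(-1.5, 0.0), method="bounded")
    right = minimize_scalar(double_well, bounds=(0.0, 1.5), method="bounded")
    return (right.fun - left.fun) / KJ_PER_KCAL


class TestDeltaF:
    def test_symmetric_double_well_gives_zero(self):
        grid = np.linspace(-1.5, 1.5, 100)
        F = 2.0 * (grid**2 - 1) ** 2
        pmf = extract_deltaF(PMFEstimate(grid=grid, F=F - F.min()))
        assert pmf.deltaF == pytest.approx(0.0, abs=1e-9)

    def test_constructed_offset_recovered(self):
        grid = np.linspace(-1.5, 1.5, 120)
        F = 2.0 * (grid**2 - 1) ** 2 + 0.6 * grid
        pmf = extract_deltaF(PMFEstimate(grid=grid, F=F - F.min()))
        lo = F[grid < 0].min()
        hi = F[grid > 0].min()
        assert pmf.deltaF == pytest.approx(hi - lo, abs=0.05)

    def test_single_basin_rejected(self):
        grid = np.linspace(-1, 1, 50)
        with pytest.raises(SingleBasin):
            extract_deltaF(PMFEstimate(grid=grid, F=grid**2))

    def test_langevin_double_well_matches_quadrature(self):
        windows = sample_umbrella_windows(double_well, n_steps=4000, seed=0)
        pmf = bootstrap_pmf(windows, n_boot=5, seed=1)
        truth = quadrature_deltaF_kcal()
        assert pmf.deltaF_se > 0
        assert abs(pmf.deltaF - truth) < 3 * max(pmf.deltaF_se, 0.05)


class TestBootstrap:
    def test_degenerate_windows_resample_to_identical_pmf(self):
        # all samples in a window identical: any bootstrap resample is the
        # same multiset, so the resampled PMF must match the original exactly
        rng = np.random.default_rng(0)
        windows = [
            UmbrellaWindow(c, 100.0, np.full(200, 0.0))
            for c in np.linspace(-0.2, 0.2, 4)
        ]
        base = wham(windows, n_bins=5).F
        resampled = [
            UmbrellaWindow(w.center, w.force_constant,
                           rng.choice(w.samples, size=w.samples.size))
            for w in windows
        ]
        again = wham(resampled, n_bins=5).F
        assert np.allclose(base, again, equal_nan=True)

    def test_seed_changes_error_bars_not_estimate(self):
        windows = sample_umbrella_windows(double_well, n_steps=1500, seed=3)
        a = bootstrap_pmf(windows, n_boot=4, seed=10)
        b = bootstrap_pmf(windows, n_boot=4, seed=20)
        assert a.deltaF == pytest.approx(b.deltaF, abs=1e-12)
        assert a.deltaF_se != b.deltaF_se

    def test_more_samples_shrink_deltaF_error(self):
        small = sample_umbrella_windows(double_well, n_steps=800, seed=5)
        big = sample_umbrella_windows(double_well, n_steps=8000, seed=5)
        se_small = bootstrap_pmf(small, n_boot=5, seed=6).deltaF_se
        se_big = bootstrap_pmf(big, n_boot=5, seed=6).deltaF_se
        assert se_big < se_small
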