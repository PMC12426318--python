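import subprocess

import numpy as np
import pandas as pd
import pytest

import zerolux as zl
from zerolux.gam import (LAMBDA_GRID, CyclicSplineBasis, _design,
                         _gcv_gaussian, _whiten, estimate_ar1)
from zerolux.simulate import SimConfig, diurnal_mu, simulate_tweedie_series

PERIOD = 86400.0


def make_series(n=2016, groups=("participant",), interval=300):
    ts = pd.date_range("2024-05-06", periods=n, freq=f"{interval}s")
    if len(groups) == 1:
        return zl.LightTimeSeries(ts, np.ones(n), groups[0], interval)
    idx = ts.append(ts)
    src = np.repeat(groups, n)
    return zl.LightTimeSeries(idx, np.ones(2 * n), src, interval)


@pytest.fixture(scope="module")
def basis():
    return CyclicSplineBasis(k=24, period=PERIOD)


class TestCyclicBasis:

    @pytest.mark.parametrize("deriv", [0, 1, 2])
    def test_periodic_in_value_and_two_derivatives(self, basis, deriv):
        at0 = basis.evaluate([0.0], deriv)
        at_end = basis.evaluate([PERIOD - 1e-7], deriv)
        np.testing.assert_allclose(at0, at_end, atol=1e-10)

    def test_constant_coefficients_give_constant_curve_zero_penalty(self, basis):
        ones = np.ones(basis.k)
        t = np.linspace(0, PERIOD, 257)
        np.testing.assert_allclose(basis.evaluate(t) @ ones, 1.0, atol=1e-12)
        assert abs(ones @ basis.penalty @ ones) < 1e-20

    def test_row_sums_constant_everywhere(self, basis):
        t = np.linspace(0, PERIOD, 1001)
        np.testing.assert_allclose(basis.evaluate(t).sum(axis=1), 1.0, atol=1e-12)

    def test_penalty_symmetric_psd_null_space_constants(self, basis):
        S = basis.penalty
        np.testing.assert_allclose(S, S.T)
        eig = np.linalg.eigvalsh(S)
        scale = np.abs(eig).max()
        assert eig.min() > -1e-12 * scale
        assert np.sum(np.abs(eig) < 1e-10 * scale) == 1  # constants only

    def test_periodic_for_random_coefficients(self, basis):
        rng = np.random.default_rng(0)
        coef = rng.normal(size=basis.k)
        f = basis.evaluate(np.array([0.0, PERIOD - 1e-8, PERIOD + 5.0, 5.0])) @ coef
        assert f[0] == pytest.approx(f[1], abs=1e-8)
        assert f[2] == pytest.approx(f[3], abs=1e-10)  # wraps modulo period

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="k >= 4"):
            CyclicSplineBasis(k=3)


class TestGaussianFit:
    def test_noiseless_cyclic_signal_recovered(self):
        s = make_series()
        t = s.seconds_from_midnight()
        y = np.sin(2 * np.pi * t / PERIOD)
        f = zl.fit(zl.GamSpec(family="gaussian"), s, values=y)
        pred = zl.predict(f, t, "participant", scale="link")
        assert np.max(np.abs(pred - y)) < 1e-3

    def test_group_offset_recovered(self):
        s = make_series(groups=("environment", "participant"))
        t = s.seconds_from_midnight()
        rng = np.random.default_rng(1)
        signal = np.sin(2 * np.pi * t / PERIOD)
        y = signal + 2.5 * (s.source == "participant") + rng.normal(0, 0.1, len(s))
        f = zl.fit(zl.GamSpec(family="gaussian"), s, values=y)
        assert f.coef[1] == pytest.approx(2.5, abs=0.05)

    def test_gcv_grid_optimality(self):
        s = make_series(n=288)
        t = s.seconds_from_midnight()
        rng = np.random.default_rng(2)
        y = np.sin(2 * np.pi * t / PERIOD) + rng.normal(0, 0.3, len(s))
        f = zl.fit(zl.GamSpec(family="gaussian"), s, values=y)
        X, penalties, slices, _, _ = _design(
            f._times, f._group_idx, f.groups, f.basis, f.spec.by_group)
        w = np.ones(len(f.y))
        chosen = _gcv_gaussian(X, f.y, w, penalties, slices, f.lambdas)[0]
        i = int(np.argmin(np.abs(LAMBDA_GRID - f.lambdas[0])))
        for j in (i - 1, i + 1):
            if 0 <= j < len(LAMBDA_GRID):
                other = _gcv_gaussian(X, f.y, w, penalties, slices,
                                      np.array([LAMBDA_GRID[j]]))[0]
                assert chosen <= other + 1e-12

    def test_edf_between_fixed_effects_and_coef_count(self):
        s = make_series(groups=("environment", "participant"))
        t = s.seconds_from_midnight()
        rng = np.random.default_rng(3)
        y = np.cos(2 * np.pi * t / PERIOD) + rng.normal(0, 0.5, len(s))
        f = zl.fit(zl.GamSpec(family="gaussian"), s, values=y)
        assert 2 <= f.edf <= len(f.coef)

    def test_log10_family_requires_positive_response(self):
        s = make_series(n=48)
        with pytest.raises(ValueError, match="positive"):
            zl.fit(zl.GamSpec(family="gaussian_log10"), s,
                   values=np.zeros(len(s)))

    def test_agrees_with_mgcv_on_shared_fixture(self, tmp_path):
        # independent oracle: mgcv's cyclic cubic regression spline fit
        rng = np.random.default_rng(3)
        n = 240
        s = make_series(n=n, interval=int(PERIOD / n))
        t = s.seconds_from_midnight()
        y = (np.sin(2 * np.pi * t / PERIOD)
             + 0.5 * np.cos(4 * np.pi * t / PERIOD) + rng.normal(0, 0.2, n))
        data = tmp_path / "d.csv"
        pd.DataFrame({"t": t, "y": y}).to_csv(data, index=False)
        rfit = tmp_path / "rfit.csv"
        subprocess.run(
            ["Rscript", "-e",
             f"suppressMessages(library(mgcv));"
             f"d <- read.csv('{data}');"
             f"m <- gam(y ~ s(t, bs='cc', k=12), data=d,"
             f"         knots=list(t=c(0, 86400)));"
             f"write.csv(data.frame(fit=fitted(m)), '{rfit}', row.names=FALSE)"],
            capture_output=True, text=True, check=True)
        reference = pd.read_csv(rfit)["fit"].to_numpy()
        f = zl.fit(zl.GamSpec(family="gaussian", k=12), s, values=y)
        rmse = np.sqrt(np.mean((f.fitted_response - reference) ** 2))
        assert rmse < 0.05 * np.std(y)   # same curve up to smoothing criterion


class TestAr1:
    def simulate_ar1(self, n, rho, seed=0):
        rng = np.random.default_rng(seed)
        e = np.zeros(n)
        z = rng.normal(0, 1, n)
        for i in range(1, n):
            e[i] = rho * e[i - 1] + z[i]
        return e

    def test_white_noise_rho_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(estimate_ar1(rng.normal(0, 1, 10 ** 4))) < 0.05

    def test_recovery_of_rho(self):
        e = self.simulate_ar1(10 ** 4, 0.8, seed=5)
        assert 0.75 < estimate_ar1(e) < 0.85

    def test_whitening_with_true_rho_removes_autocorrelation(self):
        e = self.simulate_ar1(10 ** 4, 0.8, seed=6)
        _, ew = _whiten(np.zeros((len(e), 1)), e, np.zeros(len(e), int),
                        np.arange(float(len(e))), 1.0, 0.8)
        assert abs(estimate_ar1(ew)) < 0.05

    def test_short_or_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_ar1([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            estimate_ar1(np.ones(10))

    def test_ar1_fit_whitens_model_residuals(self):
        s = make_series()
        t = s.seconds_from_midnight()
        noise = self.simulate_ar1(len(s), 0.8, seed=7) * 0.2
        y = 10.0 ** (np.sin(2 * np.pi * t / PERIOD) + noise + 2.0)
        f = zl.fit(zl.GamSpec(family="gaussian_log10", ar1=True), s, values=y)
        assert f.rho is not None and 0.5 < f.rho < 0.95


@pytest.fixture(scope="module")
def recovery_fit():
    s = simulate_tweedie_series(diurnal_mu, 1.73, 1.5, SimConfig(seed=11))
    return s, zl.fit(zl.GamSpec(family="tweedie"), s)


class TestTweedieFit:

    def test_power_and_dispersion_recovered(self, recovery_fit):
        _, f = recovery_fit
        assert abs(f.p_hat - 1.73) <= 0.1
        assert f.phi_hat == pytest.approx(1.5, rel=0.2)

    def test_mean_curve_recovered_on_log_scale(self, recovery_fit):
        s, f = recovery_fit
        t = s.seconds_from_midnight()
        mu_hat = zl.predict(f, t, "participant")
        rmse = np.sqrt(np.mean((np.log10(mu_hat) - np.log10(diurnal_mu(t))) ** 2))
        # noise bound: smooth's share of the working-residual variance
        wr = (s.medi - f.fitted_response) / f.fitted_response
        bound = 2 * np.std(wr) * np.sqrt(f.edf / f.n) / np.log(10)
        assert rmse < bound

    def test_predictions_nonnegative_and_periodic(self, recovery_fit):
        _, f = recovery_fit
        t = np.linspace(0, PERIOD, 97)
        pred = zl.predict(f, t, "participant")
        assert np.all(pred >= 0)
        np.testing.assert_allclose(zl.predict(f, t + PERIOD, "participant"), pred)

    def test_fitted_values_match_predict_at_observed_times(self, recovery_fit):
        s, f = recovery_fit
        pred = zl.predict(f, f._times, "participant")
        np.testing.assert_allclose(pred, f.fitted_response, rtol=1e-10)

    def test_ar1_with_tweedie_rejected(self):
        with pytest.raises(ValueError, match="AR1"):
            zl.GamSpec(family="tweedie", ar1=True)


@pytest.fixture(scope="module")
def gaussian_fit():
    s = make_series(n=288)
    t = s.seconds_from_midnight()
    rng = np.random.default_rng(8)
    y = np.sin(2 * np.pi * t / PERIOD) + rng.normal(0, 0.2, len(s))
    return zl.fit(zl.GamSpec(family="gaussian"), s, values=y)


class TestDiagnostics:

    def test_r2_of_good_fit_high_but_below_one(self, gaussian_fit):
        r2 = zl.r2_adjusted(gaussian_fit)
        assert 0.8 < r2 < 1.0

    def test_r2_perfect_fit(self):
        s = make_series(n=96)
        t = s.seconds_from_midnight()
        y = np.sin(2 * np.pi * t / PERIOD)
        f = zl.fit(zl.GamSpec(family="gaussian"), s, values=y)
        assert zl.r2_adjusted(f) == pytest.approx(1.0, abs=1e-6)

    def test_r2_can_be_negative_for_bad_fit(self, gaussian_fit):
        # score an anti-correlated "observation" vector against the fit
        bad = -gaussian_fit.y
        assert zl.r2_adjusted(gaussian_fit, observed=bad) < 0

    def test_gaussian_pearson_residuals_are_scaled_raw_residuals(self, gaussian_fit):
        resid = zl.scaled_pearson_residuals(gaussian_fit)
        raw = gaussian_fit.y - gaussian_fit.fitted_response
        np.testing.assert_allclose(resid, raw / np.sqrt(gaussian_fit.phi_hat))

    def test_tweedie_residuals_calibrated_on_well_specified_sim(self):
        s = simulate_tweedie_series(diurnal_mu, 1.5, 1.0, SimConfig(seed=21))
        f = zl.fit(zl.GamSpec(family="tweedie"), s)
        resid = zl.scaled_pearson_residuals(f)
        assert abs(np.mean(resid)) < 0.1
        assert 0.8 < np.var(resid) < 1.2

    def test_exact_fit_gives_zero_residual(self, gaussian_fit):
        resid = zl.scaled_pearson_residuals(
            gaussian_fit, observed=gaussian_fit.fitted_response)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_unknown_group_rejected(self, gaussian_fit):
        with pytest.raises(KeyError, match="unknown group"):
            zl.predict(gaussian_fit, [0.0], "rooftop")
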