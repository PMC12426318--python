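import subprocess

import numpy as np
import pytest
from scipy import integrate, special, stats

import zerolux as zl
from zerolux import tweedie as tw


P_MU_PHI = [(p, mu, phi) for p in (1.2, 1.5, 1.73, 1.9)
            for mu in (1.0, 10.0, 100.0) for phi in (0.5, 1.5)]


class TestToCpg:
    def test_reference_conversion(self):
        cpg = zl.to_cpg(zl.TweedieParams(1, 1.5, 1))
        assert (cpg.lam, cpg.alpha, cpg.gamma_scale) == (2.0, 1.0, 0.5)

    @pytest.mark.parametrize("p,mu,phi", P_MU_PHI)
    def test_moment_identities(self, p, mu, phi):
        cpg = zl.to_cpg(zl.TweedieParams(mu, p, phi))
        assert cpg.lam > 0 and cpg.alpha > 0 and cpg.gamma_scale > 0
        mean = cpg.lam * cpg.alpha * cpg.gamma_scale
        var = cpg.lam * cpg.alpha * (cpg.alpha + 1) * cpg.gamma_scale ** 2
        assert mean == pytest.approx(mu, rel=1e-12)
        assert var == pytest.approx(phi * mu ** p, rel=1e-12)

    def test_monte_carlo_confirms_conversion(self):
        # independent oracle: simulate the compound sum explicitly
        rng = np.random.default_rng(123)
        n = 10 ** 6
        counts = rng.poisson(2.0, n)
        draws = np.zeros(n)
        pos = counts > 0
        draws[pos] = rng.gamma(counts[pos] * 1.0, 0.5)
        assert draws.mean() == pytest.approx(1.0, abs=0.005)
        assert draws.var() == pytest.approx(1.0, abs=0.01)

    def test_boundaries_rejected_with_pointer(self):
        with pytest.raises(ValueError, match="Poisson"):
            zl.to_cpg(zl.TweedieParams(1, 1.0, 1))


class TestRvs:
    def test_calibration_at_paper_sample_size(self):
        params = zl.TweedieParams(mu=1.0, p=1.5, phi=1.0)
        n = 10 ** 5
        d = zl.rvs(params, n, seed=7)
        se = np.sqrt(params.variance / n)
        assert abs(d.mean() - params.mu) < 3 * se
        assert abs(d.var() - params.variance) < 0.05 * params.variance
        p0 = np.exp(-zl.to_cpg(params).lam)
        se0 = np.sqrt(p0 * (1 - p0) / n)
        assert abs((d == 0).mean() - p0) < 3 * se0

    def test_reproducible_under_seed(self):
        params = zl.TweedieParams(5, 1.73, 1.5)
        np.testing.assert_array_equal(zl.rvs(params, 100, 3), zl.rvs(params, 100, 3))

    def test_gamma_boundary_has_no_zeros(self):
        d = zl.rvs(zl.TweedieParams(10, 2.0, 0.5), 10 ** 4, seed=1)
        assert np.all(d > 0)
        # matches a Gamma(1/phi, phi*mu) sampler in distribution
        ref = stats.gamma(a=2.0, scale=5.0)
        ks = stats.kstest(d, ref.cdf)
        assert ks.pvalue > 0.001


class TestPdf:
    def test_zero_mass_reference(self):
        assert zl.pdf(0.0, zl.TweedieParams(1, 1.5, 1)) == pytest.approx(
            np.exp(-2), rel=1e-12)

    @pytest.mark.parametrize("p,mu,phi", P_MU_PHI)
    def test_normalization(self, p, mu, phi):
        params = zl.TweedieParams(mu, p, phi)
        # split at mu: the density can be near-singular at 0+ for p -> 2
        v1, _ = integrate.quad(lambda y: zl.pdf(y, params), 0, mu, limit=300)
        v2, _ = integrate.quad(lambda y: zl.pdf(y, params), mu, np.inf, limit=300)
        assert v1 + v2 + zl.pdf(0.0, params) == pytest.approx(1.0, abs=1e-6)

    def test_matches_histogram_of_draws(self):
        params = zl.TweedieParams(2.0, 1.5, 1.0)
        n = 10 ** 6
        d = zl.rvs(params, n, seed=42)
        edges = np.arange(0.25, 5.25, 0.5)
        for lo, hi in zip(edges[:-1], edges[1:]):
            prob, _ = integrate.quad(lambda y: zl.pdf(y, params), lo, hi)
            observed = np.mean((d > lo) & (d <= hi))
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(observed - prob) < 4 * se, (lo, hi)

    def test_poisson_boundary_pointwise(self):
        mu = 3.7
        params = zl.TweedieParams(mu, 1.0, 1.0)
        y = np.arange(0, 20, dtype=float)
        ours = zl.pdf(y, params)
        # independent closed form, written out
        expected = np.exp(-mu) * mu ** y / special.factorial(y)
        np.testing.assert_allclose(ours, expected, atol=1e-10, rtol=1e-10)

    def test_gamma_boundary_pointwise(self):
        mu, phi = 4.0, 0.5
        params = zl.TweedieParams(mu, 2.0, phi)
        y = np.linspace(0.01, 30, 50)
        a, s = 1 / phi, phi * mu
        expected = y ** (a - 1) * np.exp(-y / s) / (special.gamma(a) * s ** a)
        np.testing.assert_allclose(zl.pdf(y, params), expected, rtol=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            zl.pdf(-0.1, zl.TweedieParams(1, 1.5, 1))

    def test_agrees_with_mgcv_ldtweedie(self, tmp_path):
        # independent oracle: mgcv's series evaluation of the same density
        y = [0.0, 0.5, 1.0, 2.5, 10.0, 50.0]
        out = subprocess.run(
            ["Rscript", "-e",
             "suppressMessages(library(mgcv));"
             "cat(ldTweedie(c(0,0.5,1,2.5,10,50), mu=5, p=1.73, phi=1.5)[,1],"
             " sep='\\n')"],
            capture_output=True, text=True, check=True)
        reference = np.array([float(v) for v in out.stdout.split()])
        ours = tw.logpdf(np.array(y), zl.TweedieParams(5, 1.73, 1.5))
        np.testing.assert_allclose(ours, reference, rtol=1e-5)


class TestLoglik:
    def test_zero_datum_reference(self):
        assert zl.loglik([0.0], zl.TweedieParams(1, 1.5, 1)) == pytest.approx(-2.0)

    def test_additive_over_concatenation(self):
        params = zl.TweedieParams(3, 1.6, 1.2)
        a = zl.rvs(params, 50, 1)
        b = zl.rvs(params, 30, 2)
        total = zl.loglik(np.concatenate([a, b]), params)
        assert total == pytest.approx(zl.loglik(a, params) + zl.loglik(b, params))

    def test_mu_maximizer_near_truth(self):
        d = zl.rvs(zl.TweedieParams(5.0, 1.5, 1.0), 10 ** 4, seed=9)
        grid = np.linspace(3, 8, 101)
        lls = [zl.loglik(d, zl.TweedieParams(m, 1.5, 1.0)) for m in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(5.0, abs=0.3)

    def test_zeros_never_give_minus_inf(self):
        ll = zl.loglik([0.0, 0.0, 1.0], zl.TweedieParams(2, 1.9, 0.5))
        assert np.isfinite(ll)


class TestProfilePower:
    @pytest.mark.parametrize("p_true", [1.3, 1.5, 1.73])
    def test_recovery_within_tolerance(self, p_true):
        d = zl.rvs(zl.TweedieParams(50, p_true, 1.5), 2016, seed=7)
        p_hat, phi_hat, table = zl.profile_power(d)
        assert abs(p_hat - p_true) <= 0.1
        assert phi_hat == pytest.approx(1.5, rel=0.3)

    def test_low_power_data_ranked_correctly(self):
        d = zl.rvs(zl.TweedieParams(50, 1.2, 1.5), 2016, seed=11)
        p_hat, _, _ = zl.profile_power(d)
        assert abs(p_hat - 1.2) < abs(p_hat - 1.8)

    def test_profile_is_unimodal_on_recovery_data(self):
        d = zl.rvs(zl.TweedieParams(50, 1.73, 1.5), 2016, seed=7)
        _, _, table = zl.profile_power(d)
        ll = table["loglik"].to_numpy()
        peak = int(np.argmax(ll))
        assert np.all(np.diff(ll[:peak + 1]) > 0)
        assert np.all(np.diff(ll[peak:]) < 0)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            zl.profile_power(np.zeros(100))

    def test_export_columns(self, tmp_path):
        d = zl.rvs(zl.TweedieParams(5, 1.5, 1.0), 200, seed=0)
        _, _, table = zl.profile_power(d, grid=[1.4, 1.5, 1.6])
        path = tmp_path / "profile.csv"
        table.to_csv(path, index=False)
        assert path.read_text().splitlines()[0] == "p,phi,loglik"


class TestComparisonFamilies:
    def test_degenerate_mixture_all_zero(self):
        d = zl.comparison_rvs("zi_poisson", {"weight": 1.0, "mean": 4}, 100, 0)
        assert np.all(d == 0)

    def test_negative_binomial_is_integer_valued(self):
        d = zl.comparison_rvs("zi_negbinomial",
                              {"weight": 0.3, "mean": 4, "size": 2}, 1000, 1)
        np.testing.assert_array_equal(d, np.round(d))
        assert (d == 0).mean() > 0.3    # inflated beyond the base law

    def test_gamma_has_no_zeros(self):
        d = zl.comparison_rvs("gamma", {"shape": 2.0, "scale": 1.5}, 1000, 2)
        assert np.all(d > 0)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            zl.comparison_rvs("zi_poisson", {"weight": 1.5, "mean": 4}, 10, 0)
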