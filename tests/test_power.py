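"""Covariance fitting, the power generative model, expected R² and
univariate power."""

import numpy as np
import pytest
from scipy import stats

import fcora
from fcora.power import CovModel, EffectSpec, _screen_single_covariate


def ledoit_wolf_2004(y):
    """Independent oracle: the original shrinkage-to-scaled-identity formulas.

    Sample covariance S (1/n), target m*I with m = tr(S)/p, squared distance
    d2 = ||S - mI||_F^2 / p, dispersion b2 = min(d2, mean_k ||x_k x_k' - S||^2/p/n),
    shrunk estimate (b2/d2) m I + (1 - b2/d2) S.
    """
    y = np.asarray(y, float)
    n, p = y.shape
    xc = y - y.mean(axis=0)
    S = xc.T @ xc / n
    m = np.trace(S) / p
    d2 = ((S - m * np.eye(p)) ** 2).sum() / p
    b2bar = 0.0
    for i in range(n):
        outer = np.outer(xc[i], xc[i])
        b2bar += ((outer - S) ** 2).sum() / p
    b2bar /= n**2
    b2 = min(b2bar, d2)
    shrinkage = b2 / d2 if d2 > 0 else 0.0
    return shrinkage * m * np.eye(p) + (1 - shrinkage) * S, shrinkage


class TestFitCovModel:
    def test_single_column_gives_sample_variance(self, rng):
        y = rng.standard_normal((50, 1)) * 2.0
        cov = fcora.fit_cov_model(y)
        # shrinkage toward the scaled identity is degenerate at R=1
        assert cov.omega[0, 0] == pytest.approx(y.var(), rel=1e-10)
        assert cov.chol[0, 0] == pytest.approx(np.sqrt(y.var()), rel=1e-10)

    def test_consistency_toward_identity(self, rng):
        y = rng.standard_normal((20_000, 4))
        cov = fcora.fit_cov_model(y)
        np.testing.assert_allclose(cov.omega, np.eye(4), atol=0.05)

    def test_constant_column_raises_naming_position(self, rng):
        y = rng.standard_normal((20, 3))
        y[:, 1] = 2.5
        with pytest.raises(ValueError, match=r"\[1\]"):
            fcora.fit_cov_model(y)

    def test_matches_ledoit_wolf_2004_oracle(self, rng):
        y = rng.standard_normal((10, 5)) @ np.diag([1.0, 2.0, 0.5, 1.5, 1.0])
        cov = fcora.fit_cov_model(y)
        omega_oracle, shrink_oracle = ledoit_wolf_2004(y)
        np.testing.assert_allclose(cov.omega, omega_oracle, rtol=1e-8)
        assert cov.shrinkage == pytest.approx(shrink_oracle, rel=1e-8)
        assert 0.0 <= cov.shrinkage <= 1.0

    def test_cholesky_reconstructs_omega(self, rng):
        y = rng.standard_normal((15, 8))
        cov = fcora.fit_cov_model(y)
        recon = cov.chol @ cov.chol.T
        assert np.abs(recon - cov.omega).max() <= 1e-8 * np.abs(cov.omega).max()


class TestSimulateDataset:
    def test_null_effect_recovers_omega(self, rng):
        omega = np.array([[1.0, 0.4], [0.4, 2.0]])
        cov = CovModel.from_matrix(omega)
        sim = fcora.simulate_dataset(cov, 40_000, EffectSpec(0.0, 0.0), rng)
        assert np.allclose(sim.b, 0.0)
        emp = np.cov(sim.f.T)
        np.testing.assert_allclose(emp, omega, atol=0.06)

    def test_sigma_zero_fixes_all_coefficients_at_mu(self, rng):
        cov = CovModel.from_matrix(np.eye(5))
        sim = fcora.simulate_dataset(cov, 10, EffectSpec(0.7, 0.0), rng)
        assert np.allclose(sim.b, 0.7)

    def test_ols_recovers_unit_slopes(self, rng):
        """Parameter recovery: per-pair OLS slopes hit B within 3 s.e."""
        n, R = 10_000, 20
        cov = CovModel.from_matrix(np.eye(R))
        sim = fcora.simulate_dataset(cov, n, EffectSpec(1.0, 0.0), rng)
        xc = sim.x - sim.x.mean()
        slopes = xc @ (sim.f - sim.f.mean(0)) / (xc @ xc)
        se = 1.0 / np.sqrt(xc @ xc)
        assert np.all(np.abs(slopes - 1.0) < 3 * se + 1e-12)

    def test_residual_correlations_reproduce_omega(self, rng):
        """Correlations among f residuals match the generating covariance."""
        omega = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 1.0]])
        cov = CovModel.from_matrix(omega)
        sim = fcora.simulate_dataset(cov, 30_000, EffectSpec(0.8, 0.3), rng)
        xc = sim.x - sim.x.mean()
        slopes = xc @ (sim.f - sim.f.mean(0)) / (xc @ xc)
        resid = sim.f - sim.f.mean(0) - np.outer(xc, slopes)
        np.testing.assert_allclose(np.corrcoef(resid.T), omega, atol=0.03)

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError):
            fcora.simulate_dataset(CovModel.from_matrix(np.eye(2)), 2,
                                   EffectSpec(), rng)


class TestEstimatePower:
    @staticmethod
    def run(cov, grid, cutoffs, reps=200, seed=0):
        return fcora.estimate_power(cov, grid, cutoffs, n_reps=reps, seed=seed)

    def test_null_power_is_near_cutoff_tail(self, rng):
        S, alpha = 20, 0.5
        cov = CovModel.from_matrix(np.eye(S))
        grid = [(40, 0.0, 0.0, alpha)]
        out = self.run(cov, grid, {alpha: 15}, reps=2000)
        # Binomial(20, .5) tail at 15 is 0.0207
        assert out.table.power.iloc[0] < 0.05

    def test_saturated_effect_has_power_one(self, rng):
        S, alpha = 55, 0.5
        cov = CovModel.from_matrix(np.eye(S))
        out = self.run(cov, [(100, 5.0, 0.0, alpha)], {alpha: 40}, reps=100)
        assert out.table.power.iloc[0] == 1.0

    def test_unattainable_cells_are_skipped_with_reason(self):
        cov = CovModel.from_matrix(np.eye(6))
        out = self.run(cov, [(25, 0.5, 0.0, 0.5)], {0.5: 7}, reps=10)
        row = out.table.iloc[0]
        assert np.isnan(row.power) and row.skipped == "unattainable cutoff"

    def test_matches_semianalytic_oracle(self):
        """Identity covariance: power equals the Binomial tail of the
        per-pair hit probability from the noncentral t distribution,
        integrated over b ~ N(mu, sigma^2)."""
        S, n, alpha, mu, sigma, cutoff = 20, 30, 0.5, 0.3, 0.4, 15
        df = n - 2
        crit = stats.t.ppf(alpha, df)

        # oracle hit probability by numerical integration over b
        bs = np.linspace(mu - 6 * sigma, mu + 6 * sigma, 4001)
        w = stats.norm.pdf(bs, mu, sigma)
        # conditional variance of f given x is 1, noncentrality b*sqrt(n)
        hit = stats.nct.sf(crit, df, bs * np.sqrt(n))
        q = np.trapezoid(hit * w, bs)
        oracle_power = float(stats.binom.sf(cutoff - 1, S, q))

        cov = CovModel.from_matrix(np.eye(S))
        out = self.run(
            cov, [(n, mu, sigma, alpha)], {alpha: cutoff}, reps=4000, seed=4
        )
        est = out.table.power.iloc[0]
        se = max(out.table.se.iloc[0], np.sqrt(oracle_power * (1 - oracle_power) / 4000))
        assert abs(est - oracle_power) < 4 * se + 0.01


class TestExpectedR2:
    def test_zero_effect_gives_zero(self):
        cov = CovModel.from_matrix(np.eye(10))
        assert fcora.expected_r2(cov, EffectSpec(0.0, 0.0)) == 0.0

    def test_identity_closed_form(self):
        R, mu = 100, 0.2
        cov = CovModel.from_matrix(np.eye(R))
        g = R * mu**2
        assert fcora.expected_r2(cov, EffectSpec(mu, 0.0)) == pytest.approx(
            g / (1 + g), rel=1e-12
        )

    def test_matches_large_n_empirical_regression_oracle(self, rng):
        """Closed form g/(1+g) vs the R² of an actual OLS of x on f."""
        R, n = 6, 100_000
        A = rng.standard_normal((R, R)) / np.sqrt(R)
        omega = A @ A.T + 0.5 * np.eye(R)
        cov = CovModel.from_matrix(omega)
        b = rng.normal(0.2, 0.1, R)
        # closed form for this fixed b
        g = float(b @ np.linalg.solve(omega, b))
        closed = g / (1 + g)
        # empirical: simulate with sigma=0 trick by direct construction
        x = rng.standard_normal(n)
        f = np.outer(x, b) + rng.standard_normal((n, R)) @ cov.chol.T
        coef, res_ss, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), f]), x, rcond=None
        )
        r2 = 1 - res_ss[0] / ((x - x.mean()) ** 2).sum()
        assert closed == pytest.approx(r2, abs=3 * (1 - closed) / np.sqrt(n) * 2 + 0.004)

    def test_singular_omega_rejected(self):
        with pytest.raises(ValueError):
            CovModel.from_matrix(np.ones((3, 3)))


class TestUnivariatePower:
    def test_size_equals_level_at_zero_effect(self):
        for p in (1e-3, 0.05):
            assert fcora.univariate_power(0.0, 1.0, 50, p) == pytest.approx(p, rel=1e-6)

    def test_huge_effect_saturates(self):
        assert fcora.univariate_power(50.0, 1.0, 50, 1e-3) == pytest.approx(1.0, abs=1e-9)

    def test_p_level_validated(self):
        with pytest.raises(ValueError):
            fcora.univariate_power(0.5, 1.0, 50, 0.0)

    def test_matches_monte_carlo_oracle(self, rng):
        """Closed form vs 10^5 reps of the full simulate–regress–test loop."""
        b, n, p_level, reps = 0.5, 50, 1e-3, 100_000
        closed = fcora.univariate_power(b, 1.0, n, p_level)
        # sanity band from the normal approximation
        approx = stats.norm.cdf(b * np.sqrt(n) - stats.norm.ppf(1 - p_level))
        assert abs(closed - approx) < 0.1
        # vectorized Monte-Carlo of the exact test; the covariate is held
        # fixed and standardized so sum(xc^2) = n, matching the closed form's
        # noncentrality b*sqrt(n) exactly
        x = rng.standard_normal(n)
        xc = x - x.mean()
        xc *= np.sqrt(n / (xc @ xc))
        y = b * xc[None, :] + rng.standard_normal((reps, n))
        yc = y - y.mean(1, keepdims=True)
        sxx = float(xc @ xc)
        slope = (yc @ xc) / sxx
        rss = (yc**2).sum(1) - slope**2 * sxx
        tstat = slope * np.sqrt(sxx) / np.sqrt(rss / (n - 2))
        crit = stats.t.ppf(1 - p_level, n - 2)
        mc = (tstat > crit).mean()
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(closed - mc) < 3 * se + 1e-4


def test_screen_single_covariate_matches_full_screen(rng):
    f = rng.standard_normal((30, 7))
    x = rng.standard_normal(30)
    t_fast, df = _screen_single_covariate(f, x)
    res = fcora.mass_univariate_screen(f, np.ones((30, 1)), x[:, None])
    assert df == res.df
    np.testing.assert_allclose(t_fast, res.tstats[:, 0], rtol=1e-9)


def test_power_seed_reproducibility():
    cov = CovModel.from_matrix(np.eye(10))
    grid = [(25, 0.5, 0.5, 0.5)]
    a = fcora.estimate_power(cov, grid, {0.5: 9}, n_reps=50, seed=3)
    b = fcora.estimate_power(cov, grid, {0.5: 9}, n_reps=50, seed=3)
    assert a.table.equals(b.table)
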