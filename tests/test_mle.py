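"""GEG maximum-likelihood machinery: likelihood identities, analytic
score vs finite differences, recovery, equivariance, information-based
standard errors and multi-family comparison."""

import numpy as np
import pytest
from scipy import stats

from gegdist import GEGParams, compare_families, fit_geg, geg_rvs
from gegdist.geg import _geg_nll_grad, _geg_score_obs
from gegdist.model import FamilyModel


def nll(data, theta):
    from gegdist.geg import _geg_logpdf

    return -float(np.sum(_geg_logpdf(np.asarray(data, dtype=float), *theta)))


class TestNegativeLogLikelihood:
    def test_alpha_one_equals_eg_negloglik(self, rng):
        x = rng.normal(1.0, 1.0, 50) + rng.exponential(0.5, 50)
        eg = FamilyModel(x, "EG").nloglik((0.5, 1.0, 1.0))
        geg = nll(x, (0.5, 1.0, 1.0, 1.0))
        assert geg == pytest.approx(eg, abs=1e-10)

    def test_single_point_matches_hand_formula(self):
        """One observation at x = mu with tau = sigma = alpha = 1:
        -log f = -( -(0)/1 + 1/2 + log Phi(-1) ) + log 1."""
        x = np.array([2.0])
        expected = -(0.5 + stats.norm.logcdf(-1.0) - np.log(1.0))
        assert nll(x, (1.0, 2.0, 1.0, 1.0)) == pytest.approx(expected, abs=1e-12)

    def test_duplicated_observation_doubles_contribution(self):
        theta = (0.6, 0.1, 0.9, 1.4)
        one = nll(np.array([1.3]), theta)
        two = nll(np.array([1.3, 1.3]), theta)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_finite_for_extreme_observations(self):
        """The clamped log-CDF keeps the objective finite even for data
        far into the left tail."""
        val = nll(np.array([-35.0, 0.0, 2.0]), (0.5, 0.0, 1.0, 2.0))
        assert np.isfinite(val)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            FamilyModel(np.array([]), "GEG")


class TestAnalyticScore:
    def test_score_matches_central_differences(self, rng):
        x = np.asarray(geg_rvs(80, GEGParams(0.5, 0.0, 1.0, 0.75), seed=rng))
        theta = np.array([0.7, 0.2, 0.8, 1.3])
        s = _geg_score_obs(x, *theta).sum(axis=0)
        from gegdist.geg import _geg_logpdf

        fd = np.empty(4)
        for j in range(4):
            e = np.zeros(4)
            e[j] = 1e-6 * max(1.0, abs(theta[j]))
            fd[j] = (
                _geg_logpdf(x, *(theta + e)).sum()
                - _geg_logpdf(x, *(theta - e)).sum()
            ) / (2 * e[j])
        np.testing.assert_allclose(s, fd, rtol=1e-5, atol=1e-5)

    def test_fused_objective_matches_kernel_sum(self, rng):
        from gegdist.geg import _geg_logpdf

        x = np.asarray(geg_rvs(60, GEGParams(1.25, 0.0, 1.0, 1.75), seed=rng))
        psi = np.array([np.log(0.9), -0.1, np.log(1.2), np.log(0.6)])
        f, _ = _geg_nll_grad(psi, x)
        direct = -_geg_logpdf(x, 0.9, -0.1, 1.2, 0.6).sum()
        assert f == pytest.approx(direct, rel=1e-12)


class TestFitGeg:
    def test_parameter_recovery_large_sample(self):
        truth = GEGParams(0.5, 0.0, 1.0, 0.75)
        x = geg_rvs(100_000, truth, seed=42)
        fr = fit_geg(x)
        assert fr.converged
        target = np.array([truth.tau, truth.mu, truth.sigma, truth.alpha])
        assert np.all(np.abs(fr.estimates - target) < 3 * fr.std_errors)

    def test_score_near_zero_at_optimum(self):
        truth = GEGParams(0.5, 0.0, 1.0, 1.75)
        x = np.asarray(geg_rvs(2000, truth, seed=5))
        fr = fit_geg(x)
        score = _geg_score_obs(x, *fr.estimates).sum(axis=0)
        assert np.max(np.abs(score)) < 1e-3 * x.size

    def test_refit_from_optimum_is_fixed_point(self):
        x = geg_rvs(2000, GEGParams(0.5, 0.0, 1.0, 1.75), seed=6)
        fr1 = fit_geg(x)
        fr2 = fit_geg(x, init=tuple(fr1.estimates))
        assert fr2.loglik == pytest.approx(fr1.loglik, abs=1e-6)

    def test_location_scale_equivariance(self):
        """Rescaling data by c and shifting by d maps (tau, mu, sigma)
        to (c tau, c mu + d, c sigma) with alpha unchanged -- the
        divide-by-100 convention is a pure reparameterization."""
        x = np.asarray(geg_rvs(3000, GEGParams(0.5, 0.0, 1.0, 1.75), seed=9))
        c, d = 100.0, 7.0
        fr = fit_geg(x)
        fr_cd = fit_geg(c * x + d)
        assert fr_cd.converged and fr.converged
        np.testing.assert_allclose(fr_cd.estimates[0], c * fr.estimates[0], rtol=1e-3)
        np.testing.assert_allclose(
            fr_cd.estimates[1], c * fr.estimates[1] + d, atol=2e-2 * c
        )
        np.testing.assert_allclose(fr_cd.estimates[2], c * fr.estimates[2], rtol=1e-3)
        np.testing.assert_allclose(fr_cd.estimates[3], fr.estimates[3], rtol=1e-3)

    def test_normal_data_approaches_gaussian_loglik(self, rng):
        """The GEG nests the Normal (tau -> 0, alpha = 1); its loglik
        must come within 2 units of the Normal fit."""
        x = rng.normal(0.0, 1.0, 5000)
        fr = fit_geg(x)
        no = FamilyModel(x, "NO").fit()
        assert fr.loglik >= no.loglik - 2.0

    def test_se_scales_with_sqrt_n(self):
        """Doubling the sample by replicating it doubles the observed
        information, so every SE shrinks by sqrt(2)."""
        truth = GEGParams(0.5, 0.0, 1.0, 1.75)
        x = np.asarray(geg_rvs(4000, truth, seed=3))
        f1 = fit_geg(x)
        f2 = fit_geg(np.concatenate([x, x]))
        ratio = f1.std_errors / f2.std_errors
        assert np.all(np.abs(ratio - np.sqrt(2)) < 0.2 * np.sqrt(2))

    def test_aic_bic_identities(self):
        x = geg_rvs(500, GEGParams(0.5, 0.0, 1.0, 0.75), seed=10)
        fr = fit_geg(x)
        assert fr.aic == pytest.approx(2 * 4 - 2 * fr.loglik, abs=1e-9)
        assert fr.bic == pytest.approx(4 * np.log(500) - 2 * fr.loglik, abs=1e-9)

    def test_wald_interval_geometry(self):
        x = geg_rvs(1000, GEGParams(0.5, 0.0, 1.0, 0.75), seed=11)
        fr = fit_geg(x, ci_level=0.9)
        z = stats.norm.ppf(0.95)
        np.testing.assert_allclose(
            fr.ci_upper - fr.ci_lower, 2 * z * fr.std_errors, rtol=1e-10
        )
        ci = fr.conf_int()
        assert ci.shape == (4, 2)


class TestCompareFamilies:
    def test_skewed_geg_data_beats_normal(self):
        x = np.asarray(geg_rvs(2000, GEGParams(0.835, 2.471, 0.253, 0.486), seed=21))
        table = compare_families(x, ["NO", "GEG"])
        results = table.attrs["results"]
        assert results["GEG"].aic < results["NO"].aic

    def test_normal_data_keeps_normal_competitive(self, rng):
        """On Gaussian data the 2-parameter Normal must sit within 2 AIC
        of the best fit (extra shape parameters cannot buy more than the
        parsimony penalty returns)."""
        x = rng.normal(5.0, 1.0, 3000)
        table = compare_families(x, ["NO", "EG", "GEG"])
        best = table["aic"].min()
        no_aic = table.loc[table.family == "NO", "aic"].iloc[0]
        assert no_aic <= best + 2.0 + 1e-6

    def test_rows_sorted_and_identities_hold(self, rng):
        x = rng.normal(3.0, 1.0, 400) + rng.exponential(1.0, 400)
        table = compare_families(x, ["NO", "EG", "G", "LN"])
        aics = table["aic"].to_numpy()
        assert np.all(np.diff(aics[np.isfinite(aics)]) >= 0)
        for _, row in table.iterrows():
            if np.isfinite(row.aic):
                assert row.aic == pytest.approx(2 * row.k - 2 * row.loglik, abs=1e-8)
                assert row.bic == pytest.approx(
                    row.k * np.log(400) - 2 * row.loglik, abs=1e-8
                )

    def test_unsupported_family_recorded_not_raised(self, rng):
        x = rng.normal(0.0, 1.0, 100)  # not positive: EXP/G/LN unfittable
        table = compare_families(x, ["EXP", "NO"])
        exp_row = table.loc[table.family == "EXP"].iloc[0]
        assert not exp_row.converged and np.isnan(exp_row.aic)
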