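"""Core EG/GEG kernels: densities, distribution functions, quantiles,
sampling, survival/hazard; checked against independent oracles
(quadrature, central differences, scipy's exponentially modified normal,
and a convolution sampler)."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from gegdist import (
    EGParams,
    GEGParams,
    eg_cdf,
    eg_inverse_risk,
    eg_logpdf,
    eg_pdf,
    geg_cdf,
    geg_hazard,
    geg_inverse_risk,
    geg_logpdf,
    geg_pdf,
    geg_quantile,
    geg_rvs,
    geg_survival,
)

XGRID = np.array([-6.0, -2.5, -1.0, -0.3, 0.0, 0.4, 1.2, 2.5, 4.0, 8.0])


class TestParameterDomains:
    @pytest.mark.parametrize(
        "bad",
        [(-0.5, 0.0, 1.0, 1.0), (0.5, 0.0, -1.0, 1.0), (0.5, 0.0, 1.0, 0.0),
         (0.0, 0.0, 1.0, 1.0), (0.5, np.inf, 1.0, 1.0)],
    )
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            GEGParams(*bad)

    def test_eg_invalid(self):
        with pytest.raises(ValueError):
            EGParams(1.0, 0.0, 0.0)


class TestEgKernel:
    def test_matches_exponentially_modified_normal(self):
        """scipy.stats.exponnorm is an independent implementation of the
        same convolution; pdf/cdf must agree to near machine precision."""
        p = EGParams(0.7, 0.3, 1.4)
        ref = stats.exponnorm(K=p.tau / p.sigma, loc=p.mu, scale=p.sigma)
        np.testing.assert_allclose(eg_pdf(XGRID, p), ref.pdf(XGRID), rtol=1e-12)
        np.testing.assert_allclose(eg_cdf(XGRID, p), ref.cdf(XGRID), atol=1e-13)

    def test_gaussian_limit_of_density_at_mode(self):
        """As tau -> 0 the EG collapses onto N(mu, sigma^2)."""
        p = EGParams(1e-6, 0.0, 1.0)
        assert np.exp(eg_logpdf(0.0, p)) == pytest.approx(
            stats.norm.pdf(0.0), abs=1e-3
        )

    def test_gaussian_limit_of_cdf(self):
        p = EGParams(1e-4, 0.0, 1.0)
        x = np.linspace(-4, 4, 41)
        np.testing.assert_allclose(eg_cdf(x, p), stats.norm.cdf(x), atol=1e-4)

    @pytest.mark.parametrize("tau", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("sigma", [0.1, 1.0, 10.0])
    def test_density_normalizes(self, tau, sigma):
        p = EGParams(tau, 0.0, sigma)
        val, _ = integrate.quad(lambda x: eg_pdf(x, p), -np.inf, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_cdf_equals_quadrature_of_pdf(self):
        p = EGParams(0.5, 0.2, 0.8)
        for x in [-2.0, 0.0, 1.5, 4.0]:
            q, _ = integrate.quad(lambda t: eg_pdf(t, p), -np.inf, x, limit=300)
            assert eg_cdf(x, p) == pytest.approx(q, abs=1e-8)

    def test_no_overflow_for_extreme_scale_ratios(self):
        """Finite log density/CDF for sigma/tau across six orders of
        magnitude and standardized x in [-40, 40]."""
        z = np.linspace(-40.0, 40.0, 161)
        for ratio in [1e-3, 1.0, 1e3]:
            p = EGParams(1.0 / ratio, 0.0, 1.0)
            lp = eg_logpdf(z, p)
            lc = np.log(np.maximum(eg_cdf(z, p), 1e-320))
            assert np.all(np.isfinite(lp))
            assert not np.any(np.isnan(lc))


class TestGegDensityAndCdf:
    def test_alpha_one_reduces_to_eg(self):
        p = GEGParams(0.8, -0.2, 1.1, 1.0)
        np.testing.assert_allclose(
            geg_logpdf(XGRID, p), eg_logpdf(XGRID, p.eg), rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            geg_cdf(XGRID, p), eg_cdf(XGRID, p.eg), rtol=0, atol=1e-14
        )

    def test_density_normalizes_on_study_grid(self, study_params):
        for p in study_params:
            val, _ = integrate.quad(
                lambda x: geg_pdf(x, p), -np.inf, np.inf, limit=300
            )
            assert val == pytest.approx(1.0, abs=1e-6), p

    @pytest.mark.parametrize("alpha", [0.1, 50.0])
    def test_density_normalizes_extreme_shapes(self, alpha):
        p = GEGParams(0.5, 0.0, 1.0, alpha)
        val, _ = integrate.quad(lambda x: geg_pdf(x, p), -np.inf, np.inf, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_is_derivative_of_cdf(self, study_params):
        """Central-difference oracle for dF/dx = f."""
        h = 1e-6
        for p in study_params[:3]:
            num = (geg_cdf(XGRID + h, p) - geg_cdf(XGRID - h, p)) / (2 * h)
            np.testing.assert_allclose(geg_pdf(XGRID, p), num, atol=1e-6)

    def test_cdf_is_eg_cdf_to_the_alpha(self):
        p = GEGParams(0.6, 0.1, 0.9, 2.0)
        np.testing.assert_allclose(
            geg_cdf(XGRID, p), eg_cdf(XGRID, p.eg) ** 2, rtol=0, atol=1e-14
        )

    def test_cdf_matches_quadrature_of_density(self, study_params):
        for p in study_params:
            for x in [-1.0, 0.5, 2.0]:
                q, _ = integrate.quad(
                    lambda t: geg_pdf(t, p), -np.inf, x, limit=400
                )
                assert geg_cdf(x, p) == pytest.approx(q, abs=1e-6)

    def test_cdf_monotone_with_limits(self):
        p = GEGParams(0.5, 0.0, 1.0, 1.75)
        x = np.linspace(-30, 30, 601)
        F = geg_cdf(x, p)
        assert np.all(np.diff(F) >= 0)
        assert F[0] == pytest.approx(0.0, abs=1e-12)
        assert F[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all((F >= 0) & (F <= 1))

    def test_left_tail_log_density_diverges_gracefully_for_alpha_below_one(self):
        p = GEGParams(0.5, 0.0, 1.0, 0.5)
        vals = geg_logpdf(np.array([-50.0, -200.0]), p)
        assert np.all(np.isfinite(vals) | (vals == np.inf))

    def test_deep_left_tail_underflows_to_zero_density_for_alpha_above_one(self):
        p = GEGParams(0.5, 0.0, 1.0, 3.0)
        lp = geg_logpdf(-500.0, p)
        assert lp < -700.0  # exp underflows to exactly 0
        assert np.exp(lp) == 0.0


class TestQuantileAndSampling:
    def test_quantile_cdf_roundtrip(self, study_params):
        u = np.array([1e-6, 1e-3, 0.05, 0.5, 0.9, 0.999, 1 - 1e-6])
        for p in study_params:
            x = geg_quantile(u, p)
            assert np.all(np.diff(x) > 0)
            np.testing.assert_allclose(geg_cdf(x, p), u, rtol=1e-8, atol=1e-12)

    def test_cdf_quantile_roundtrip_in_x(self):
        p = GEGParams(0.5, 0.0, 1.0, 1.75)
        xs = np.array([-2.0, -0.5, 0.0, 1.0, 3.0, 6.0])
        back = geg_quantile(geg_cdf(xs, p), p)
        np.testing.assert_allclose(back, xs, atol=1e-8)

    def test_eg_median_against_independent_root_finder(self):
        """alpha = 1 median cross-checked by brentq on the EG CDF."""
        p = GEGParams(0.9, 0.4, 1.2, 1.0)
        med = geg_quantile(0.5, p)
        ref = optimize.brentq(
            lambda x: eg_cdf(x, p.eg) - 0.5, -20.0, 30.0, xtol=1e-12
        )
        assert med == pytest.approx(ref, abs=1e-9)

    def test_normal_limit_median(self):
        p = GEGParams(1e-4, 3.0, 1.0, 1.0)
        assert geg_quantile(0.5, p) == pytest.approx(3.0, abs=1e-3)

    def test_quantile_domain_errors(self):
        p = GEGParams(0.5, 0.0, 1.0, 1.0)
        for u in (0.0, 1.0, -0.1, 1.1, np.nan):
            with pytest.raises(ValueError):
                geg_quantile(u, p)

    def test_sampler_reproducible_and_valid(self):
        p = GEGParams(0.5, 0.0, 1.0, 0.75)
        a = geg_rvs(500, p, seed=123)
        b = geg_rvs(500, p, seed=123)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            geg_rvs(0, p, seed=1)

    def test_sampler_one_sample_ks(self):
        """KS test of 1e4 draws against the model CDF at the 1% level."""
        p = GEGParams(0.5, 0.0, 1.0, 0.75)
        x = geg_rvs(10_000, p, seed=2024)
        stat = stats.kstest(x, lambda q: geg_cdf(q, p)).statistic
        crit_1pct = 1.6276 / np.sqrt(10_000)
        assert stat < crit_1pct

    def test_alpha_one_sampler_matches_convolution(self):
        """EG draws via inverse CDF vs an independent Normal+Exponential
        convolution sampler (two-sample KS)."""
        p = GEGParams(0.6, 0.3, 1.1, 1.0)
        x = geg_rvs(10_000, p, seed=7)
        rng = np.random.default_rng(8)
        y = rng.normal(p.mu, p.sigma, 10_000) + rng.exponential(p.tau, 10_000)
        assert stats.ks_2samp(x, y).pvalue > 0.01


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        tau=st.floats(0.05, 5.0),
        mu=st.floats(-3.0, 3.0),
        sigma=st.floats(0.1, 4.0),
        alpha=st.floats(0.2, 8.0),
        u=st.floats(1e-4, 1.0 - 1e-4),
    )
    def test_quantile_cdf_inverse_property(tau, mu, sigma, alpha, u):
        """geg_cdf(geg_quantile(u)) == u over random parameter boxes."""
        p = GEGParams(tau, mu, sigma, alpha)
        assert geg_cdf(geg_quantile(u, p), p) == pytest.approx(u, rel=1e-8, abs=1e-10)

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


class TestSurvivalHazard:
    @pytest.mark.parametrize("alpha", [0.75, 1.75, 2.75])
    def test_inverse_risk_proportionality(self, alpha):
        """r_GEG = alpha * r_EG pointwise."""
        p = GEGParams(0.5, 0.0, 1.0, alpha)
        ratio = geg_inverse_risk(XGRID, p) / eg_inverse_risk(XGRID, p.eg)
        np.testing.assert_allclose(ratio, alpha, rtol=1e-10)

    def test_hazard_survival_density_identity(self):
        p = GEGParams(0.5, 0.2, 0.9, 1.75)
        x = XGRID[:-1]  # keep survival well away from 0
        np.testing.assert_allclose(
            geg_hazard(x, p) * geg_survival(x, p), geg_pdf(x, p), rtol=1e-12
        )

    def test_survival_limits_and_sign(self):
        p = GEGParams(0.5, 0.0, 1.0, 2.75)
        assert geg_survival(-1e3, p) == pytest.approx(1.0, abs=1e-12)
        assert geg_survival(1e3, p) == pytest.approx(0.0, abs=1e-12)
        assert np.all(geg_survival(XGRID, p) >= 0)
        assert np.all(geg_hazard(XGRID, p) >= 0)
        assert np.all(geg_inverse_risk(XGRID, p) >= 0)
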