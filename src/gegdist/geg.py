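"""Numerically stable kernels for the exponential-Gaussian (EG) and
generalised exponential-Gaussian (GEG) distributions.

The EG (ex-Gaussian, exponentially modified Gaussian) random variable is
the sum of a Normal(mu, sigma^2) and an independent Exponential with mean
tau; it is the canonical model for reaction times.  The GEG family raises
the EG distribution function to a positive power alpha (a fractional order
statistic / Lehmann alternative),

    F_GEG(x; tau, mu, sigma, alpha) = [F_EG(x; tau, mu, sigma)]^alpha,

which frees the family to take symmetric and even negatively skewed
shapes while keeping the EG as the alpha = 1 slice.

All evaluation is done in log space.  The textbook EG density

    f_EG(x) = (1/tau) exp(-(x-mu)/tau + sigma^2/(2 tau^2)) Phi(z - sigma/tau)

overflows naively once sigma/tau is large, so both the density and the
distribution function are rewritten through the Mills-type ratio
R(t) = Phi(t)/phi(t) (computed with the scaled complementary error
function), using the identity e^a Phi(b) = phi(z) R(b) with
z = (x-mu)/sigma, b = z - sigma/tau:

    f_EG(x) = phi(z) R(b) / tau
    F_EG(x) = phi(z) [R(z) - R(b)]        (z below the right-tail switch)

The second form subtracts two well-scaled ratios instead of two
exponentials, which keeps log F_EG accurate far into the left tail --
exactly where the GEG log-likelihood needs it when alpha < 1.

Functions accept scalars or arrays and broadcast; parameters may
themselves be arrays (used by the distributional-regression layer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, log_ndtr, ndtr, ndtri_exp

__all__ = [
    "EGParams",
    "GEGParams",
    "eg_logpdf",
    "eg_pdf",
    "eg_cdf",
    "eg_logcdf",
    "eg_inverse_risk",
    "geg_logpdf",
    "geg_pdf",
    "geg_cdf",
    "geg_logcdf",
    "geg_quantile",
    "geg_rvs",
    "geg_survival",
    "geg_inverse_risk",
    "geg_hazard",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_SQRT_HALF_PI = np.sqrt(0.5 * np.pi)
# Right-tail switch: below this standardized value the subtractive Mills
# form of F_EG is used; above it F_EG is within ~1e-137 of 1 and is formed
# in linear space.  Keeps R(t) = sqrt(pi/2)*erfcx(-t/sqrt(2)) < 1e308.
_Z_SWITCH = 25.0
_TINY = 1e-300


@dataclass(frozen=True)
class EGParams:
    """Ex-Gaussian parameters: exponential mean ``tau``, Normal location
    ``mu`` and Normal scale ``sigma`` (all in data units)."""

    tau: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be finite and > 0, got {self.tau}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma}")


@dataclass(frozen=True)
class GEGParams:
    """GEG parameters ``(tau, mu, sigma, alpha)``.

    ``alpha`` is the dimensionless exponentiation (shape) parameter
    controlling skewness; ``tau`` regulates kurtosis; ``mu`` and ``sigma``
    are location and Gaussian scale in data units.  ``alpha = 1``
    reproduces the EG sub-family exactly.
    """

    tau: float
    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        EGParams(self.tau, self.mu, self.sigma)
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")

    @property
    def eg(self) -> EGParams:
        return EGParams(self.tau, self.mu, self.sigma)


def _mills(t):
    """R(t) = Phi(t)/phi(t) = sqrt(pi/2) * erfcx(-t/sqrt(2)).

    Exact for all t; overflows only beyond t ~ 26.6 (callers stay below
    ``_Z_SWITCH``)."""
    return _SQRT_HALF_PI * erfcx(-t / np.sqrt(2.0))


def _log_mills(t):
    """log R(t), valid for all t including large positive values."""
    t = np.asarray(t, dtype=float)
    small = t < _Z_SWITCH
    out = np.empty_like(t)
    out[small] = np.log(_mills(t[small]))
    tl = t[~small]
    out[~small] = log_ndtr(tl) + 0.5 * tl * tl + _LOG_SQRT_2PI
    return out


def _eg_logpdf(x, tau, mu, sigma):
    x, tau, mu, sigma = np.broadcast_arrays(
        *map(np.asarray, (x, tau, mu, sigma))
    )
    z = (x - mu) / sigma
    b = z - sigma / tau
    return -np.log(tau) - 0.5 * z * z - _LOG_SQRT_2PI + _log_mills(b)


def _eg_logcdf(x, tau, mu, sigma):
    x, tau, mu, sigma = np.broadcast_arrays(
        *map(lambda v: np.asarray(v, dtype=float), (x, tau, mu, sigma))
    )
    z = (x - mu) / sigma
    b = z - sigma / tau
    out = np.empty_like(z)

    # Below the median of the Gaussian part the subtractive Mills form
    # keeps full relative accuracy deep into the left tail; above it the
    # linear form is exact (the Mills form would lose ~eps*z^2/2 of
    # absolute log-accuracy exactly where F approaches 1).
    left = z < 0.0
    if np.any(left):
        zl, bl = z[left], b[left]
        diff = np.maximum(_mills(zl) - _mills(bl), _TINY)
        out[left] = -0.5 * zl * zl - _LOG_SQRT_2PI + np.log(diff)
    if np.any(~left):
        zr, br = z[~left], b[~left]
        a = -(zr - br) * (zr + br) / 2.0  # == -(x-mu)/tau + sigma^2/(2 tau^2)
        second = np.exp(np.minimum(a + log_ndtr(br), 0.0))
        lin = np.clip(ndtr(zr) - second, _TINY, 1.0)
        out[~left] = np.log(lin)
    return out


def _check(p, cls):
    if isinstance(p, cls):
        return p
    if isinstance(p, (tuple, list, np.ndarray)):
        return cls(*p)
    raise TypeError(f"expected {cls.__name__} or a parameter tuple, got {p!r}")


def eg_logpdf(x, p: EGParams):
    """Log density of the EG distribution; finite for |z| up to +-40 and
    sigma/tau up to 1e3."""
    p = _check(p, EGParams)
    return _eg_logpdf(x, p.tau, p.mu, p.sigma)


def eg_pdf(x, p: EGParams):
    return np.exp(eg_logpdf(x, p))


def eg_logcdf(x, p: EGParams):
    p = _check(p, EGParams)
    return _eg_logcdf(x, p.tau, p.mu, p.sigma)


def eg_cdf(x, p: EGParams):
    """EG distribution function, monotone in x with limits 0 and 1."""
    return np.exp(eg_logcdf(x, p))


def eg_inverse_risk(x, p: EGParams):
    """Inverse risk (reversed hazard) r_EG = f_EG / F_EG."""
    p = _check(p, EGParams)
    return np.exp(
        _eg_logpdf(x, p.tau, p.mu, p.sigma) - _eg_logcdf(x, p.tau, p.mu, p.sigma)
    )


def _geg_logpdf(x, tau, mu, sigma, alpha):
    return (
        np.log(alpha)
        + _eg_logpdf(x, tau, mu, sigma)
        + (np.asarray(alpha) - 1.0) * _eg_logcdf(x, tau, mu, sigma)
    )


def geg_logpdf(x, p: GEGParams):
    """Log density of the GEG distribution,
    log alpha + log f_EG + (alpha-1) log F_EG.

    For alpha > 1 the value tends to -inf in the deep left tail (the
    log-CDF underflow is clamped); for alpha < 1 the mathematical value is
    returned without raising even where the density is very large.
    """
    p = _check(p, GEGParams)
    return _geg_logpdf(x, p.tau, p.mu, p.sigma, p.alpha)


def geg_pdf(x, p: GEGParams):
    return np.exp(geg_logpdf(x, p))


def geg_logcdf(x, p: GEGParams):
    p = _check(p, GEGParams)
    return p.alpha * _eg_logcdf(x, p.tau, p.mu, p.sigma)


def geg_cdf(x, p: GEGParams):
    """F_GEG(x) = [F_EG(x)]^alpha, formed as exp(alpha * log F_EG)."""
    return np.exp(geg_logcdf(x, p))


def geg_survival(x, p: GEGParams):
    """S_GEG = 1 - F_GEG, formed with expm1 so the right tail keeps
    relative precision."""
    return -np.expm1(geg_logcdf(x, p))


def geg_inverse_risk(x, p: GEGParams):
    """Inverse risk r_GEG = f_GEG / F_GEG; satisfies r_GEG = alpha r_EG."""
    p = _check(p, GEGParams)
    return np.exp(
        _geg_logpdf(x, p.tau, p.mu, p.sigma, p.alpha)
        - p.alpha * _eg_logcdf(x, p.tau, p.mu, p.sigma)
    )


def geg_hazard(x, p: GEGParams):
    """Hazard h_GEG = f_GEG / S_GEG (nonnegative; +inf where S = 0)."""
    s = geg_survival(x, p)
    f = geg_pdf(x, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0.0, f / np.where(s > 0.0, s, 1.0), np.inf)
    return out


# ---------------------------------------------------------------------------
# Quantiles and random generation
# ---------------------------------------------------------------------------

def _eg_ppf_from_logcdf(logv, tau, mu, sigma, iters: int = 100):
    """Vectorized EG quantile: solve log F_EG(x) = logv by bracketed
    bisection.  Working on the log-CDF scale keeps extreme levels (from
    u^(1/alpha) with large alpha) well conditioned."""
    logv = np.minimum(np.asarray(logv, dtype=float), -1e-300)
    shape = np.broadcast_shapes(logv.shape, np.shape(tau))
    logv = np.broadcast_to(logv, shape).astype(float)

    # Normal-part anchor for the level, padded in both directions.
    zg = ndtri_exp(np.maximum(logv, log_ndtr(37.0)))
    zg = np.clip(zg, -1e9, 38.0)
    step = sigma + tau
    lo = mu + sigma * zg - step
    # Right tail is exponential with mean tau.
    with np.errstate(divide="ignore"):
        s = -np.log(np.maximum(-np.expm1(logv), _TINY))
    hi = mu + sigma * (zg + 1.0) + tau * (s + 1.0)

    lo = np.array(np.broadcast_to(lo, shape), dtype=float)
    hi = np.array(np.broadcast_to(hi, shape), dtype=float)
    width = np.broadcast_to(np.asarray(step, dtype=float), shape)

    grow = np.ones(shape)
    for _ in range(200):
        bad = _eg_logcdf(lo, tau, mu, sigma) > logv
        if not np.any(bad):
            break
        lo = np.where(bad, lo - grow * width, lo)
        grow = np.where(bad, 2.0 * grow, grow)
    grow = np.ones(shape)
    for _ in range(200):
        bad = _eg_logcdf(hi, tau, mu, sigma) < logv
        if not np.any(bad):
            break
        hi = np.where(bad, hi + grow * width, hi)
        grow = np.where(bad, 2.0 * grow, grow)

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = _eg_logcdf(mid, tau, mu, sigma) < logv
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.max(hi - lo) <= 1e-14 * (1.0 + np.max(np.abs(mid))):
            break
    return 0.5 * (lo + hi)


def geg_quantile(u, p: GEGParams):
    """Quantile function of the GEG: x = F_EG^{-1}(u^{1/alpha}).

    ``u`` must lie strictly inside (0, 1); raises ValueError otherwise.
    """
    p = _check(p, GEGParams)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)) or not np.all(np.isfinite(u)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    logv = np.log(u) / p.alpha
    out = _eg_ppf_from_logcdf(logv, p.tau, p.mu, p.sigma)
    if np.ndim(u) == 0:
        return float(out)
    return out


def geg_rvs(n: int, p: GEGParams, seed=None):
    """Draw ``n`` iid GEG variates by inverse-CDF sampling of uniforms.

    ``seed`` may be an int or a numpy Generator; the same seed always
    yields the identical vector.
    """
    p = _check(p, GEGParams)
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(int(n))
    # Guard the open-interval contract (probability ~0 events).
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    return np.asarray(geg_quantile(u, p))


# ---------------------------------------------------------------------------
# Analytic score (used by the fitters; derived by chain rule from the
# density and the Mills-ratio form of F_EG, and validated against central
# finite differences in the test suite)
# ---------------------------------------------------------------------------

def _geg_score_obs(x, tau, mu, sigma, alpha):
    """Per-observation score of the GEG log-likelihood.

    Returns an (n, 4) array of d log f_GEG(x_i)/d(tau, mu, sigma, alpha)
    evaluated in the ORIGINAL parameterization.  Parameters broadcast
    against x (vector parameters are used by the regression layer).
    """
    x, tau, mu, sigma, alpha = np.broadcast_arrays(
        *map(lambda v: np.asarray(v, dtype=float), (x, tau, mu, sigma, alpha))
    )
    z = (x - mu) / sigma
    b = z - sigma / tau
    w = np.exp(-_log_mills(b))  # phi(b)/Phi(b), inverse Mills ratio

    dlf_mu = 1.0 / tau - w / sigma
    dlf_sigma = sigma / tau**2 + w * (-z / sigma - 1.0 / tau)
    dlf_tau = -1.0 / tau + (x - mu) / tau**2 - sigma**2 / tau**3 + w * sigma / tau**2

    # (dF/dtheta)/F, stable in both tails.
    g_mu = np.empty_like(z)
    g_sigma = np.empty_like(z)
    g_tau = np.empty_like(z)
    left = z < 0.0
    if np.any(left):
        zl, bl = z[left], b[left]
        taul, sigl, xl, mul = tau[left], sigma[left], x[left], mu[left]
        rb = _mills(bl)
        d = np.maximum(_mills(zl) - rb, _TINY)
        g_mu[left] = -rb / (taul * d)
        g_sigma[left] = (1.0 / taul - rb * sigl / taul**2) / d
        g_tau[left] = (
            -rb * ((xl - mul) / taul**2 - sigl**2 / taul**3) - sigl / taul**2
        ) / d
    if np.any(~left):
        r = ~left
        zr, br = z[r], b[r]
        taur, sigr, xr, mur = tau[r], sigma[r], x[r], mu[r]
        a = -(zr - br) * (zr + br) / 2.0
        t2 = np.exp(np.minimum(a + log_ndtr(br), 0.0))
        phiz = np.exp(-0.5 * zr * zr - _LOG_SQRT_2PI)
        f_lin = np.clip(ndtr(zr) - t2, _TINY, 1.0)
        g_mu[r] = -t2 / (taur * f_lin)
        g_sigma[r] = (phiz / taur - t2 * sigr / taur**2) / f_lin
        g_tau[r] = (
            -t2 * ((xr - mur) / taur**2 - sigr**2 / taur**3) - phiz * sigr / taur**2
        ) / f_lin

    am1 = alpha - 1.0
    lF = _eg_logcdf(x, tau, mu, sigma)
    return np.stack(
        [
            dlf_tau + am1 * g_tau,
            dlf_mu + am1 * g_mu,
            dlf_sigma + am1 * g_sigma,
            1.0 / alpha + lF,
        ],
        axis=-1,
    )


def _geg_nll_grad(psi, x):
    """Negative log-likelihood and its gradient in the unconstrained
    parameterization psi = (log tau, mu, log sigma, log alpha).

    A fused fast path handles the overwhelmingly common case where all
    standardized residuals sit below the right-tail switch; otherwise the
    general (branching) kernels are used.
    """
    ltau, mu, lsig, lalp = psi
    with np.errstate(over="ignore"):
        tau, sigma, alpha = np.exp(ltau), np.exp(lsig), np.exp(lalp)
    if not np.all(np.isfinite([tau, mu, sigma, alpha])) or sigma == 0 or tau == 0:
        return np.inf, np.zeros(4)

    with np.errstate(all="ignore"):
        return _geg_nll_grad_impl(x, ltau, mu, lsig, lalp, tau, sigma, alpha)


def _geg_nll_grad_impl(x, ltau, mu, lsig, lalp, tau, sigma, alpha):
    xm = x - mu
    z = xm / sigma
    if np.max(z) < _Z_SWITCH and np.min(z) > -1e154:
        b = z - sigma / tau
        rb = _mills(b)
        rz = _mills(z)
        d = np.maximum(rz - rb, _TINY)
        zz = 0.5 * z * z
        lF = -zz - _LOG_SQRT_2PI + np.log(d)
        logf = -ltau - zz - _LOG_SQRT_2PI + np.log(rb)
        am1 = alpha - 1.0
        n = x.size
        ll_sum = n * lalp + np.sum(logf) + am1 * np.sum(lF)
        if not np.isfinite(ll_sum):
            return np.inf, np.zeros(4)

        w = 1.0 / rb
        it = 1.0 / tau
        it2 = it * it
        sig_it2 = sigma * it2
        dF_tau_core = (xm - sigma * sigma * it) * it2  # (x-mu)/tau^2 - sigma^2/tau^3
        s_mu = np.sum(it - w / sigma + am1 * (-rb / (tau * d)))
        s_sigma = np.sum(
            sig_it2 + w * (-z / sigma - it) + am1 * ((it - rb * sig_it2) / d)
        )
        s_tau = np.sum(
            -it + dF_tau_core + w * sig_it2
            + am1 * ((-rb * dF_tau_core - sig_it2) / d)
        )
        s_alpha = n / alpha + np.sum(lF)
        grad = -np.array([s_tau * tau, s_mu, s_sigma * sigma, s_alpha * alpha])
        return -float(ll_sum), grad

    ll = _geg_logpdf(x, tau, mu, sigma, alpha)
    ll_sum = np.sum(ll)
    if not np.isfinite(ll_sum):
        return np.inf, np.zeros(4)
    score = _geg_score_obs(x, tau, mu, sigma, alpha).sum(axis=0)
    grad = -score * np.array([tau, 1.0, sigma, alpha])
    return -float(ll_sum), grad


def _eg_nll_grad(psi, x):
    """EG negative log-likelihood and gradient in (log tau, mu, log sigma)."""
    nll, grad = _geg_nll_grad(np.array([psi[0], psi[1], psi[2], 0.0]), x)
    return nll, grad[:3]
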