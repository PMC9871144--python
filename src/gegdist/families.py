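"""Reference distribution families used for model comparison.

Besides the GEG/EG kernels this module provides the skew-normal (SN),
power-normal (PN) and skew-normal alpha-power (SNAP) families and the
classical families Exponential, Normal, t, Gamma and Log-Normal in their
GAMLSS parameterizations (Gamma as mean/dispersion, Log-Normal as
mean/sd of the log, t as location/scale/df, Exponential as mean).  A
registry keyed by the conventional abbreviations (EXP, NO, T, EG, G, LN,
SN, PN, SNAP, GEG) drives fitting and comparison.

SN with standardization z = (x-mu)/sigma:
    pdf  (2/sigma) phi(z) Phi(lambda z)
    cdf  Phi(z) - 2 T(z; lambda)            (T = Owen's T function)
PN:
    pdf  (alpha/sigma) phi(z) Phi(z)^(alpha-1)
    cdf  Phi(z)^alpha
SNAP exponentiates the SN the same way PN exponentiates the Normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtr, owens_t

from . import geg

__all__ = [
    "SNParams",
    "PNParams",
    "SNAPParams",
    "sn_pdf",
    "sn_cdf",
    "sn_logpdf",
    "pn_pdf",
    "pn_cdf",
    "pn_logpdf",
    "snap_pdf",
    "snap_cdf",
    "snap_logpdf",
    "Family",
    "FAMILIES",
    "get_family",
]

_TINY = 1e-300


@dataclass(frozen=True)
class SNParams:
    """Skew-normal location mu, scale sigma > 0 and real skewness lambda."""

    mu: float
    sigma: float
    lam: float

    def __post_init__(self):
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (np.isfinite(self.mu) and np.isfinite(self.lam)):
            raise ValueError("mu and lambda must be finite")


@dataclass(frozen=True)
class PNParams:
    """Power-normal location mu, scale sigma > 0 and exponent alpha > 0."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self):
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


@dataclass(frozen=True)
class SNAPParams:
    """Skew-normal alpha-power parameters (mu, sigma, lambda, alpha)."""

    mu: float
    sigma: float
    lam: float
    alpha: float

    def __post_init__(self):
        SNParams(self.mu, self.sigma, self.lam)
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


def _z(x, mu, sigma):
    return (np.asarray(x, dtype=float) - mu) / sigma


def sn_logpdf(x, p: SNParams):
    z = _z(x, p.mu, p.sigma)
    return (
        np.log(2.0) - np.log(p.sigma) + stats.norm.logpdf(z) + log_ndtr(p.lam * z)
    )


def sn_pdf(x, p: SNParams):
    return np.exp(sn_logpdf(x, p))


def sn_cdf(x, p: SNParams):
    """Phi(z) - 2*T(z; lambda) with Owen's T (Patefield-Tandy)."""
    z = _z(x, p.mu, p.sigma)
    return np.clip(ndtr(z) - 2.0 * owens_t(z, p.lam), 0.0, 1.0)


def pn_logpdf(x, p: PNParams):
    z = _z(x, p.mu, p.sigma)
    return (
        np.log(p.alpha)
        - np.log(p.sigma)
        + stats.norm.logpdf(z)
        + (p.alpha - 1.0) * log_ndtr(z)
    )


def pn_pdf(x, p: PNParams):
    return np.exp(pn_logpdf(x, p))


def pn_cdf(x, p: PNParams):
    z = _z(x, p.mu, p.sigma)
    return np.exp(p.alpha * log_ndtr(z))


def _sn_logcdf_std(z, lam):
    return np.log(np.clip(ndtr(z) - 2.0 * owens_t(z, lam), _TINY, 1.0))


def snap_logpdf(x, p: SNAPParams):
    z = _z(x, p.mu, p.sigma)
    return (
        np.log(p.alpha)
        + sn_logpdf(x, SNParams(p.mu, p.sigma, p.lam))
        + (p.alpha - 1.0) * _sn_logcdf_std(z, p.lam)
    )


def snap_pdf(x, p: SNAPParams):
    return np.exp(snap_logpdf(x, p))


def snap_cdf(x, p: SNAPParams):
    z = _z(x, p.mu, p.sigma)
    return np.exp(p.alpha * _sn_logcdf_std(z, p.lam))


# ---------------------------------------------------------------------------
# Family registry
# ---------------------------------------------------------------------------

def _moment_eg_start(x):
    """Moment-based EG start: tau from the skewness, then mu and sigma.

    tau0 is kept strictly inside (0, sd) -- the cube-root rule exceeds
    the sample sd once the skewness passes 2, which would start sigma at
    (numerically) zero, a degenerate basin the optimizer cannot leave.
    """
    m, v = float(np.mean(x)), float(np.var(x))
    sd = np.sqrt(v)
    skew = max(float(stats.skew(x)), 1e-6)
    tau0 = float(np.clip(sd * (skew / 2.0) ** (1.0 / 3.0), 1e-3 * sd, 0.95 * sd))
    mu0 = m - tau0
    sig0 = np.sqrt(max(v - tau0**2, 1e-6 * v))
    return tau0, mu0, sig0


@dataclass
class Family:
    """One entry of the family registry.

    ``logpdf``/``cdf`` take (theta, x) with ``theta`` the parameter vector
    in the family's own order; ``starts`` returns one or more initial
    parameter vectors for MLE; ``transforms`` marks which coordinates are
    optimized on the log scale; ``positive_support`` requires positive
    data.  ``score`` (optional) returns the (n, k) per-observation score
    in the original parameterization.
    """

    key: str
    name: str
    param_names: Sequence[str]
    logpdf: Callable
    cdf: Callable
    starts: Callable
    transforms: Sequence[str]
    positive_support: bool = False
    score: Callable | None = None
    # fused (nll, grad) in the transformed parameterization, optional
    nll_grad_psi: Callable | None = None

    @property
    def k(self) -> int:
        return len(self.param_names)


def _geg_starts(x):
    tau0, mu0, sig0 = _moment_eg_start(x)
    return [(tau0, mu0, sig0, a0) for a0 in (0.5, 1.0, 2.0)]


def _eg_starts(x):
    # second start leans Gaussian (small tau) to cover low-skew samples
    m, sd = float(np.mean(x)), float(np.std(x))
    return [_moment_eg_start(x), (0.3 * sd, m - 0.3 * sd, 0.95 * sd)]


def _sn_starts(x):
    m, sd = float(np.mean(x)), float(np.std(x))
    sgn = 1.0 if stats.skew(x) >= 0 else -1.0
    return [(m, sd, sgn), (m, sd, 3.0 * sgn)]


def _pn_starts(x):
    m, sd = float(np.mean(x)), float(np.std(x))
    return [(m, sd, 1.0), (m - sd, sd, 3.0), (m + sd, sd, 0.4)]


def _snap_starts(x):
    m, sd = float(np.mean(x)), float(np.std(x))
    sgn = 1.0 if stats.skew(x) >= 0 else -1.0
    return [(m, sd, sgn, 1.0), (m, sd, 2.0 * sgn, 0.5), (m - sd, sd, sgn, 2.0)]


def _t_starts(x):
    df, loc, scale = stats.t.fit(x)
    return [(loc, max(scale, 1e-8), float(np.clip(df, 0.5, 1e3)))]


FAMILIES: dict[str, Family] = {}


def _register(fam: Family) -> Family:
    FAMILIES[fam.key] = fam
    return fam


_register(
    Family(
        key="GEG",
        name="Generalised Exponential-Gaussian",
        param_names=("tau", "mu", "sigma", "alpha"),
        logpdf=lambda th, x: geg._geg_logpdf(x, *th),
        cdf=lambda th, x: np.exp(th[3] * geg._eg_logcdf(x, th[0], th[1], th[2])),
        starts=_geg_starts,
        transforms=("log", "id", "log", "log"),
        score=lambda th, x: geg._geg_score_obs(x, *th),
        nll_grad_psi=geg._geg_nll_grad,
    )
)

_register(
    Family(
        key="EG",
        name="Ex-Gaussian",
        param_names=("tau", "mu", "sigma"),
        logpdf=lambda th, x: geg._eg_logpdf(x, *th),
        cdf=lambda th, x: np.exp(geg._eg_logcdf(x, *th)),
        starts=_eg_starts,
        transforms=("log", "id", "log"),
        score=lambda th, x: geg._geg_score_obs(x, th[0], th[1], th[2], 1.0)[:, :3],
        nll_grad_psi=geg._eg_nll_grad,
    )
)

_register(
    Family(
        key="EXP",
        name="Exponential (mean mu)",
        param_names=("mu",),
        logpdf=lambda th, x: stats.expon.logpdf(x, scale=th[0]),
        cdf=lambda th, x: stats.expon.cdf(x, scale=th[0]),
        starts=lambda x: [(float(np.mean(x)),)],
        transforms=("log",),
        positive_support=True,
    )
)

_register(
    Family(
        key="NO",
        name="Normal",
        param_names=("mu", "sigma"),
        logpdf=lambda th, x: stats.norm.logpdf(x, loc=th[0], scale=th[1]),
        cdf=lambda th, x: stats.norm.cdf(x, loc=th[0], scale=th[1]),
        starts=lambda x: [(float(np.mean(x)), float(np.std(x)))],
        transforms=("id", "log"),
    )
)

_register(
    Family(
        key="T",
        name="t (location, scale, df)",
        param_names=("mu", "sigma", "nu"),
        logpdf=lambda th, x: stats.t.logpdf(x, df=th[2], loc=th[0], scale=th[1]),
        cdf=lambda th, x: stats.t.cdf(x, df=th[2], loc=th[0], scale=th[1]),
        starts=_t_starts,
        transforms=("id", "log", "log"),
    )
)

# GAMLSS GA: mean mu, dispersion sigma; shape = 1/sigma^2, scale = mu*sigma^2
_register(
    Family(
        key="G",
        name="Gamma (mean, dispersion)",
        param_names=("mu", "sigma"),
        logpdf=lambda th, x: stats.gamma.logpdf(
            x, a=1.0 / th[1] ** 2, scale=th[0] * th[1] ** 2
        ),
        cdf=lambda th, x: stats.gamma.cdf(
            x, a=1.0 / th[1] ** 2, scale=th[0] * th[1] ** 2
        ),
        starts=lambda x: [
            (float(np.mean(x)), float(np.std(x) / max(np.mean(x), 1e-12)))
        ],
        transforms=("log", "log"),
        positive_support=True,
    )
)

# LN: mu, sigma are mean and sd of log(x)
_register(
    Family(
        key="LN",
        name="Log-Normal (log-location, log-scale)",
        param_names=("mu", "sigma"),
        logpdf=lambda th, x: stats.lognorm.logpdf(x, s=th[1], scale=np.exp(th[0])),
        cdf=lambda th, x: stats.lognorm.cdf(x, s=th[1], scale=np.exp(th[0])),
        starts=lambda x: [
            (float(np.mean(np.log(x))), float(np.std(np.log(x))))
        ],
        transforms=("id", "log"),
        positive_support=True,
    )
)

_register(
    Family(
        key="SN",
        name="Skew-Normal",
        param_names=("mu", "sigma", "lambda"),
        logpdf=lambda th, x: sn_logpdf(x, SNParams(*th)),
        cdf=lambda th, x: sn_cdf(x, SNParams(*th)),
        starts=_sn_starts,
        transforms=("id", "log", "id"),
    )
)

_register(
    Family(
        key="PN",
        name="Power-Normal",
        param_names=("mu", "sigma", "alpha"),
        logpdf=lambda th, x: pn_logpdf(x, PNParams(*th)),
        cdf=lambda th, x: pn_cdf(x, PNParams(*th)),
        starts=_pn_starts,
        transforms=("id", "log", "log"),
    )
)

_register(
    Family(
        key="SNAP",
        name="Skew-Normal Alpha-Power",
        param_names=("mu", "sigma", "lambda", "alpha"),
        logpdf=lambda th, x: snap_logpdf(x, SNAPParams(*th)),
        cdf=lambda th, x: snap_cdf(x, SNAPParams(*th)),
        starts=_snap_starts,
        transforms=("id", "log", "id", "log"),
    )
)


def get_family(key: str) -> Family:
    try:
        return FAMILIES[key.upper()]
    except KeyError:
        raise KeyError(
            f"unknown family {key!r}; registered: {sorted(FAMILIES)}"
        ) from None
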