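"""Moments, skewness and kurtosis by quadrature; shape-range scans.

No closed forms are used for the GEG's standardized moments: the k-th raw
moment is integrated adaptively between extreme quantiles of the family,
with interior quantiles as breakpoints so that sharply peaked members
(e.g. the skew-normal at |lambda| in the thousands, or the power-normal
at alpha in the thousands, whose mass sits in a narrow band far from the
location parameter) are not missed.

Kurtosis uses the raw standardized fourth moment (Normal = 3).

``shape_range`` scans a family's shape parameter(s) over a log-spaced
grid, refines each extremum locally, and reports the attainable skewness
and kurtosis intervals.  ``verify_limits`` quantifies the sub-family
limits: GEG -> EG at alpha = 1, GEG -> PN as tau -> 0, and
GEG -> Normal as tau -> 0 with alpha = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from . import families, geg
from .families import get_family

__all__ = [
    "ShapeSummary",
    "shape_of",
    "shape_range",
    "verify_limits",
    "sn_halfnormal_limit",
]

_ULEVELS = np.array(
    [1e-12, 1e-8, 1e-5, 1e-3, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99, 1 - 1e-3,
     1 - 1e-5, 1 - 1e-8, 1 - 1e-12]
)


@dataclass(frozen=True)
class ShapeSummary:
    """Mean, variance and standardized third/fourth moments."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float

    def pearson_ok(self) -> bool:
        """Kurtosis >= 1 + skewness^2 for every real distribution."""
        return self.kurtosis >= 1.0 + self.skewness**2 - 1e-8


def _quantile_via_cdf(fam, theta, u):
    """Generic quantile by bracketed bisection on the family CDF."""
    u = np.asarray(u, dtype=float)
    lo = np.full(u.shape, -1.0)
    hi = np.full(u.shape, 1.0)
    width = 1.0
    for _ in range(400):
        bad = fam.cdf(theta, lo) > u
        if not np.any(bad):
            break
        lo = np.where(bad, lo - width, lo)
        width *= 2.0
    width = 1.0
    for _ in range(400):
        bad = fam.cdf(theta, hi) < u
        if not np.any(bad):
            break
        hi = np.where(bad, hi + width, hi)
        width *= 2.0
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        below = fam.cdf(theta, mid) < u
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def _raw_moments(fam, theta, kmax: int = 4, tol: float = 1e-10):
    qs = _quantile_via_cdf(fam, theta, _ULEVELS)
    lo, hi = qs[0], qs[-1]
    pts = [q for q in qs[1:-1] if lo < q < hi]
    moments = []
    for k in range(kmax + 1):
        val, err = integrate.quad(
            lambda x: x**k * np.exp(fam.logpdf(theta, x)),
            lo,
            hi,
            points=pts,
            limit=400,
            epsabs=tol,
            epsrel=tol,
        )
        moments.append(val)
    total = moments[0]
    if not (0.999 <= total <= 1.001):
        raise ArithmeticError(
            f"quadrature of {fam.key} pdf integrates to {total!r} "
            f"(theta={theta}); moments unreliable"
        )
    return [m / total for m in moments]


def shape_of(family, params) -> ShapeSummary:
    """Quadrature-based ShapeSummary for a registered family.

    ``params`` is the parameter vector in the family's own order (or the
    matching dataclass from :mod:`gegdist.geg` / :mod:`gegdist.families`).
    """
    fam = get_family(family) if isinstance(family, str) else family
    if hasattr(params, "__dataclass_fields__"):
        theta = np.array(
            [getattr(params, f) for f in params.__dataclass_fields__], dtype=float
        )
    else:
        theta = np.asarray(params, dtype=float)
    m0, m1, m2, m3, m4 = _raw_moments(fam, theta)
    mean = m1
    var = m2 - m1**2
    if var <= 0:
        raise ArithmeticError(f"non-positive quadrature variance {var}")
    mu3 = m3 - 3 * mean * m2 + 2 * mean**3
    mu4 = m4 - 4 * mean * m3 + 6 * mean**2 * m2 - 3 * mean**4
    return ShapeSummary(mean, var, mu3 / var**1.5, mu4 / var**2)


def sn_halfnormal_limit():
    """Exact skewness and kurtosis of the half-normal, the lambda -> inf
    limit of the skew-normal (and the supremum of its shape range)."""
    skew = np.sqrt(2.0) * (4.0 - np.pi) / (np.pi - 2.0) ** 1.5
    kurt = 3.0 + 8.0 * (np.pi - 3.0) / (np.pi - 2.0) ** 2
    return skew, kurt


def _std_shape(fam, shape_value, builder):
    return shape_of(fam, builder(shape_value))


def _refine(objective, grid, values, idx, minimize=True):
    """Golden-section polish of a grid extremum on the log scale."""
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, len(grid) - 1)]
    if lo == hi:
        return values[idx], grid[idx]
    sign = 1.0 if minimize else -1.0
    res = optimize.minimize_scalar(
        lambda lg: sign * objective(np.exp(lg)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best = sign * res.fun
    if (best < values[idx]) if minimize else (best > values[idx]):
        return best, float(np.exp(res.x))
    return values[idx], grid[idx]


def shape_range(family: str, grid=None, include_limits: bool = True):
    """Skewness/kurtosis extrema of SN, PN or SNAP over a shape grid.

    SN scans lambda over +-logspace(1e-2, 1e6) (plus 0 and, when
    ``include_limits``, the exact +-half-normal limit values); PN scans
    alpha over logspace(1e-3, 1e4); SNAP scans the (lambda, alpha)
    product grid.  Extrema of single-parameter families are polished by
    local search.  Returns a dict with skew_min/skew_max/kurt_min/
    kurt_max and the arg-extrema.
    """
    family = family.upper()
    fam = get_family(family)

    if family == "SN":
        lams = np.concatenate([[0.0], np.logspace(-2, 6, 81)]) if grid is None else np.asarray(grid)
        lams = np.unique(np.concatenate([lams, -lams]))
        build = lambda lam: (0.0, 1.0, lam)
        shapes = {lam: _std_shape(fam, lam, build) for lam in lams}
        sk = {lam: s.skewness for lam, s in shapes.items()}
        ku = {lam: s.kurtosis for lam, s in shapes.items()}
        out = _extrema_from_dicts(sk, ku)
        if include_limits:
            skew_hn, kurt_hn = sn_halfnormal_limit()
            if skew_hn > out["skew_max"]:
                out["skew_max"], out["skew_argmax"] = skew_hn, np.inf
            if -skew_hn < out["skew_min"]:
                out["skew_min"], out["skew_argmin"] = -skew_hn, -np.inf
            if kurt_hn > out["kurt_max"]:
                out["kurt_max"], out["kurt_argmax"] = kurt_hn, np.inf
        return out

    if family == "PN":
        alphas = np.logspace(-3, 4, 141) if grid is None else np.asarray(grid)
        build = lambda a: (0.0, 1.0, a)
        sk_obj = lambda a: _std_shape(fam, a, build).skewness
        ku_obj = lambda a: _std_shape(fam, a, build).kurtosis
        sk = np.array([sk_obj(a) for a in alphas])
        ku = np.array([ku_obj(a) for a in alphas])
        out = {}
        out["skew_min"], out["skew_argmin"] = _refine(sk_obj, alphas, sk, int(sk.argmin()), True)
        out["skew_max"], out["skew_argmax"] = _refine(sk_obj, alphas, sk, int(sk.argmax()), False)
        out["kurt_min"], out["kurt_argmin"] = _refine(ku_obj, alphas, ku, int(ku.argmin()), True)
        out["kurt_max"], out["kurt_argmax"] = _refine(ku_obj, alphas, ku, int(ku.argmax()), False)
        return out

    if family == "SNAP":
        lams = np.concatenate([[0.0], np.logspace(-1, 3, 9)]) if grid is None else np.asarray(grid[0])
        lams = np.unique(np.concatenate([lams, -lams]))
        alphas = np.logspace(-2, 3, 11) if grid is None else np.asarray(grid[1])
        sk, ku = {}, {}
        for lam in lams:
            for a in alphas:
                s = shape_of(fam, (0.0, 1.0, lam, a))
                sk[(lam, a)] = s.skewness
                ku[(lam, a)] = s.kurtosis
        return _extrema_from_dicts(sk, ku)

    raise ValueError(f"shape_range supports SN, PN, SNAP; got {family!r}")


def _extrema_from_dicts(sk: dict, ku: dict) -> dict:
    skew_argmin = min(sk, key=sk.get)
    skew_argmax = max(sk, key=sk.get)
    kurt_argmin = min(ku, key=ku.get)
    kurt_argmax = max(ku, key=ku.get)
    return {
        "skew_min": sk[skew_argmin],
        "skew_argmin": skew_argmin,
        "skew_max": sk[skew_argmax],
        "skew_argmax": skew_argmax,
        "kurt_min": ku[kurt_argmin],
        "kurt_argmin": kurt_argmin,
        "kurt_max": ku[kurt_argmax],
        "kurt_argmax": kurt_argmax,
    }


# ---------------------------------------------------------------------------
# Sub-family limits
# ---------------------------------------------------------------------------

def _sup_cdf_distance(cdf_a, cdf_b, xgrid):
    return float(np.max(np.abs(cdf_a(xgrid) - cdf_b(xgrid))))


def verify_limits(taus=(1e-2, 1e-3, 1e-4), alpha: float = 2.0, ngrid: int = 2001):
    """Sup-norm CDF distances demonstrating the sub-family limits.

    Returns a dict with:

    * ``eg``     -- sup |F_GEG - F_EG| at alpha = 1 (zero by construction),
    * ``pn``     -- sup |F_GEG(tau) - F_PN| for each tau (decreasing),
    * ``normal`` -- sup |F_GEG(tau, alpha=1) - Phi| for each tau.
    """
    xgrid = np.linspace(-8.0, 8.0, ngrid)
    out = {"alpha": alpha, "taus": tuple(taus)}

    p_eg = geg.GEGParams(0.7, 0.0, 1.0, 1.0)
    out["eg"] = _sup_cdf_distance(
        lambda x: geg.geg_cdf(x, p_eg),
        lambda x: geg.eg_cdf(x, p_eg.eg),
        xgrid,
    )

    pn_params = families.PNParams(0.0, 1.0, alpha)
    out["pn"] = tuple(
        _sup_cdf_distance(
            lambda x: geg.geg_cdf(x, geg.GEGParams(tau, 0.0, 1.0, alpha)),
            lambda x: families.pn_cdf(x, pn_params),
            xgrid,
        )
        for tau in taus
    )
    out["normal"] = tuple(
        _sup_cdf_distance(
            lambda x: geg.geg_cdf(x, geg.GEGParams(tau, 0.0, 1.0, 1.0)),
            lambda x: norm.cdf(x),
            xgrid,
        )
        for tau in taus
    )
    return out
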