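"""Maximum-likelihood fitting with Wald inference and model comparison.

The central objects follow the statsmodels convention: a ``FamilyModel``
is built from data and a registry family; its ``fit()`` returns a
``FitResult`` carrying estimates, standard errors from the inverse
observed Fisher information, Wald confidence intervals, log-likelihood
and AIC/BIC, plus a ``summary()`` table.

Optimization runs in an unconstrained reparameterization (positive
parameters on the log scale) with a quasi-Newton method; standard errors
are always computed from the Hessian of the negative log-likelihood in
the ORIGINAL parameterization, so Wald intervals live on the scale the
parameters are reported on.  When that Hessian is not positive definite
a delta-method fallback through the transformed-space Hessian is tried,
and the fit is flagged non-converged if both fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .families import Family, get_family

__all__ = ["FitResult", "FamilyModel", "fit_geg", "compare_families"]


# ---------------------------------------------------------------------------
# Finite-difference helpers (small dense problems only)
# ---------------------------------------------------------------------------

def fd_jacobian(func, x0, rel_step=None):
    """Central-difference Jacobian of a vector-valued function."""
    x0 = np.asarray(x0, dtype=float)
    f0 = np.atleast_1d(np.asarray(func(x0), dtype=float))
    h = (rel_step or np.finfo(float).eps ** (1.0 / 3.0)) * np.maximum(
        np.abs(x0), 1e-3
    )
    jac = np.empty((f0.size, x0.size))
    with np.errstate(all="ignore"):
        for j in range(x0.size):
            e = np.zeros_like(x0)
            e[j] = h[j]
            jac[:, j] = (np.asarray(func(x0 + e)) - np.asarray(func(x0 - e))) / (
                2.0 * h[j]
            )
    return jac


def fd_hessian(func, x0, rel_step=None):
    """Symmetrized central-difference Hessian of a scalar function."""
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    h = (rel_step or np.finfo(float).eps ** 0.25) * np.maximum(np.abs(x0), 1e-3)
    hess = np.empty((n, n))
    f0 = func(x0)

    def fp(i, s_i, j=None, s_j=0.0):
        x = x0.copy()
        x[i] += s_i * h[i]
        if j is not None:
            x[j] += s_j * h[j]
        return func(x)

    for i in range(n):
        hess[i, i] = (fp(i, 1.0) - 2.0 * f0 + fp(i, -1.0)) / h[i] ** 2
        for j in range(i + 1, n):
            hess[i, j] = hess[j, i] = (
                fp(i, 1.0, j, 1.0)
                - fp(i, 1.0, j, -1.0)
                - fp(i, -1.0, j, 1.0)
                + fp(i, -1.0, j, -1.0)
            ) / (4.0 * h[i] * h[j])
    return hess


def _safe_inverse(info):
    """Inverse of an observed-information matrix via Cholesky; returns
    None when the matrix is not positive definite."""
    try:
        chol = np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        return None
    eye = np.eye(info.shape[0])
    inv = np.linalg.solve(chol.T, np.linalg.solve(chol, eye))
    return inv


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """MLE output for one family on one sample.

    ``estimates``/``std_errors``/``ci_lower``/``ci_upper`` are in the
    family's parameter order; ``aic = 2k - 2 loglik`` and
    ``bic = k log(n) - 2 loglik`` with ``k`` free parameters.
    """

    family: str
    param_names: tuple
    estimates: np.ndarray
    std_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    aic: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    ci_level: float = 0.95
    message: str = ""

    # statsmodels-flavoured aliases -------------------------------------
    @property
    def params(self) -> np.ndarray:
        return self.estimates

    @property
    def bse(self) -> np.ndarray:
        return self.std_errors

    @property
    def llf(self) -> float:
        return self.loglik

    def conf_int(self) -> np.ndarray:
        return np.column_stack([self.ci_lower, self.ci_upper])

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "param_names": list(self.param_names),
            "estimates": list(map(float, self.estimates)),
            "std_errors": list(map(float, self.std_errors)),
            "ci_lower": list(map(float, self.ci_lower)),
            "ci_upper": list(map(float, self.ci_upper)),
            "ci_level": self.ci_level,
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n": int(self.n),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    def summary(self) -> str:
        lines = [
            f"{self.family} maximum-likelihood fit (n = {self.n})",
            f"loglik = {self.loglik:.4f}   AIC = {self.aic:.3f}   "
            f"BIC = {self.bic:.3f}   converged = {self.converged}",
            f"{'param':>8} {'estimate':>12} {'std err':>12} "
            f"{f'[{self.ci_level:.0%} Wald CI]':>28}",
        ]
        for name, est, se, lo, hi in zip(
            self.param_names,
            self.estimates,
            self.std_errors,
            self.ci_lower,
            self.ci_upper,
        ):
            lines.append(
                f"{name:>8} {est:>12.4f} {se:>12.4f} "
                f"[{lo:>12.4f}, {hi:>12.4f}]"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class FamilyModel:
    """Univariate distribution model for a data vector.

    Parameters
    ----------
    endog : array-like
        Observations (one numeric sample).
    family : str or Family
        Registry key (``"GEG"``, ``"EG"``, ``"NO"``, ...) or a Family.
    """

    def __init__(self, endog, family="GEG"):
        x = np.asarray(endog, dtype=float)
        if x.ndim != 1:
            x = x.ravel()
        if x.size == 0:
            raise ValueError("endog is empty")
        if not np.all(np.isfinite(x)):
            raise ValueError("endog contains non-finite values")
        if np.ptp(x) == 0.0:
            raise ValueError("endog is constant; no scale to estimate")
        self.endog = x
        self.family: Family = (
            family if isinstance(family, Family) else get_family(family)
        )
        if self.family.positive_support and np.any(x <= 0):
            raise ValueError(
                f"family {self.family.key} requires strictly positive data"
            )
        self.nobs = x.size

    # -- parameter transform ---------------------------------------------
    def _to_psi(self, theta):
        return np.array(
            [
                np.log(t) if tr == "log" else t
                for t, tr in zip(theta, self.family.transforms)
            ]
        )

    def _to_theta(self, psi):
        return np.array(
            [
                np.exp(p) if tr == "log" else p
                for p, tr in zip(psi, self.family.transforms)
            ]
        )

    def _jac_theta_psi(self, theta):
        """d theta / d psi, diagonal."""
        return np.diag(
            [
                t if tr == "log" else 1.0
                for t, tr in zip(theta, self.family.transforms)
            ]
        )

    def nloglik(self, theta):
        """Negative log-likelihood at an original-scale parameter vector."""
        with np.errstate(all="ignore"):
            ll = self.family.logpdf(np.asarray(theta, dtype=float), self.endog)
        total = np.sum(ll)
        return float(-total) if np.isfinite(total) else np.inf

    def _nll_psi(self, psi):
        return self.nloglik(self._to_theta(psi))

    def _nll_grad_psi(self, psi):
        if self.family.nll_grad_psi is not None:
            return self.family.nll_grad_psi(np.asarray(psi, dtype=float), self.endog)
        theta = self._to_theta(psi)
        score = self.family.score(theta, self.endog).sum(axis=0)
        grad = -score @ self._jac_theta_psi(theta)
        return self.nloglik(theta), grad

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start=None,
        ci_level: float = 0.95,
        maxiter: int = 500,
        gtol: float = 1e-8,
    ) -> FitResult:
        """Quasi-Newton MLE with Wald inference.

        ``start`` (original scale) overrides the family's moment-based
        multi-start.  Convergence failures are flagged in the result, not
        raised.
        """
        fam = self.family
        starts = [np.asarray(start, dtype=float)] if start is not None else [
            np.asarray(s, dtype=float) for s in fam.starts(self.endog)
        ]
        # The log-likelihood (and so its gradient) scales with n; an
        # absolute gtol would make the line search flail at large n.
        gtol_eff = gtol * max(1.0, float(self.nobs))

        best = None
        total_iter = 0
        for th0 in starts:
            psi0 = self._to_psi(th0)
            try:
                opts = {"maxiter": maxiter, "ftol": 1e-10, "gtol": gtol_eff}
                if fam.score is not None or fam.nll_grad_psi is not None:
                    res = optimize.minimize(
                        self._nll_grad_psi,
                        psi0,
                        jac=True,
                        method="L-BFGS-B",
                        options=opts,
                    )
                else:
                    res = optimize.minimize(
                        self._nll_psi,
                        psi0,
                        method="L-BFGS-B",
                        options=opts,
                    )
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
            total_iter += int(res.nit)
            if not np.isfinite(res.fun):
                continue
            # A line search stopping on precision loss at a stationary
            # point still counts as converged.
            res.grad_ok = bool(
                res.success
                or (
                    res.jac is not None
                    and np.max(np.abs(res.jac)) <= 1e-4 * max(1.0, self.nobs)
                )
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res

        if best is None:
            k = fam.k
            nan = np.full(k, np.nan)
            return FitResult(
                fam.key, tuple(fam.param_names), nan, nan, nan, nan,
                np.nan, np.nan, np.nan, self.nobs, False, total_iter,
                ci_level, "all optimizer starts failed",
            )

        theta = self._to_theta(best.x)
        loglik = -float(best.fun)
        k = fam.k
        aic = 2.0 * k - 2.0 * loglik
        bic = k * np.log(self.nobs) - 2.0 * loglik

        cov, msg = self._covariance(theta, best.x)
        ok = bool(best.grad_ok) and cov is not None
        if cov is None:
            se = np.full(k, np.nan)
        else:
            var = np.diag(cov)
            if np.any(var <= 0) or not np.all(np.isfinite(var)):
                se = np.full(k, np.nan)
                ok = False
            else:
                se = np.sqrt(var)
        zcrit = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
        lo, hi = theta - zcrit * se, theta + zcrit * se
        if not np.all(np.isfinite(se)):
            ok = False
        return FitResult(
            fam.key, tuple(fam.param_names), theta, se, lo, hi,
            loglik, aic, bic, self.nobs, ok, total_iter, ci_level,
            msg if not ok else best.message,
        )

    def _covariance(self, theta, psi):
        """Inverse observed information in the original parameterization,
        with a transformed-space + delta-method fallback."""
        fam = self.family
        if fam.score is not None:
            def neg_score(th):
                return -fam.score(np.asarray(th, dtype=float), self.endog).sum(axis=0)

            hess = fd_jacobian(neg_score, theta)
            hess = 0.5 * (hess + hess.T)
        else:
            hess = fd_hessian(self.nloglik, theta)
        if np.all(np.isfinite(hess)):
            inv = _safe_inverse(hess)
            if inv is not None:
                return inv, ""
        # Fallback: Hessian in psi space, delta method back to theta.
        hess_psi = fd_hessian(self._nll_psi, np.asarray(psi, dtype=float))
        if not np.all(np.isfinite(hess_psi)):
            return None, "observed information not computable"
        inv_psi = _safe_inverse(hess_psi)
        if inv_psi is None:
            return None, "observed information not positive definite"
        jac = self._jac_theta_psi(theta)
        return jac @ inv_psi @ jac.T, "delta-method covariance (psi-space)"


def fit_geg(data, init=None, ci_level: float = 0.95) -> FitResult:
    """Fit the GEG by maximum likelihood; see ``FamilyModel.fit``."""
    start = None
    if init is not None:
        start = (
            (init.tau, init.mu, init.sigma, init.alpha)
            if hasattr(init, "alpha")
            else tuple(init)
        )
    return FamilyModel(data, "GEG").fit(start=start, ci_level=ci_level)


def compare_families(data, families=None, ci_level: float = 0.95):
    """Fit several registry families to one sample and rank them by AIC
    (ties broken by BIC).  Non-convergent fits are retained and flagged;
    families whose support excludes the data are recorded as failed rows.

    Returns a pandas DataFrame with one row per family and a
    ``results`` attribute mapping family key to FitResult.
    """
    if families is None:
        families = ["EXP", "NO", "T", "EG", "G", "LN", "SNAP", "SN", "GEG"]
    rows = []
    results = {}
    for key in families:
        fam = get_family(key)
        try:
            fr = FamilyModel(data, fam).fit(ci_level=ci_level)
        except ValueError as exc:
            fr = FitResult(
                fam.key, tuple(fam.param_names),
                np.full(fam.k, np.nan), np.full(fam.k, np.nan),
                np.full(fam.k, np.nan), np.full(fam.k, np.nan),
                np.nan, np.nan, np.nan, len(np.asarray(data).ravel()),
                False, 0, ci_level, str(exc),
            )
        results[fam.key] = fr
        rows.append(
            {
                "family": fam.key,
                "k": fam.k,
                "loglik": fr.loglik,
                "aic": fr.aic,
                "bic": fr.bic,
                "converged": fr.converged,
                "estimates": tuple(map(float, fr.estimates)),
                "std_errors": tuple(map(float, fr.std_errors)),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["aic", "bic"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["results"] = results
    return table
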