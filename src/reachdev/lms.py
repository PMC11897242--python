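"""Age-conditional percentile reference curves via the LMS method.

The LMS method summarizes how a positive measure y is distributed at
each age by three smooth curves: the Box-Cox power lambda (skewness),
the median mu, and the coefficient of variation sigma.  Under the
Box-Cox Cole-Green (BCCG) family the transformed value

    z = ((y/mu)^lambda - 1) / (lambda * sigma)      (lambda != 0)
    z = log(y/mu) / sigma                           (lambda == 0)

is standard normal, and the alpha-percentile curve on the original
scale is

    C_alpha(t) = mu(t) * (1 + lambda(t) * sigma(t) * z_alpha)^(1/lambda(t))

(with the log-normal limit when lambda = 0).  The NO family is the
plain normal y ~ N(mu(t), sigma(t)^2) with lambda fixed at 1 and zero
degrees of freedom; it is the automatic fallback whenever y contains
zeros or negative values, which the Box-Cox transform cannot handle.

Each curve is a cubic regression spline in age with a stated number of
degrees of freedom (df = 0 means a constant); coefficients are
estimated by direct maximization of the log-likelihood from a
deterministic initialization, so fits are seed-free.  AIC
(-2 log L + 2 * total df) selects between families, and normalized
quantile residuals r = Phi^{-1}(F_fit(y | age)) — standard normal under
a correct model — drive the diagnostics: their first four moments are
z-scored against N(0, 1) within nine equal-count age groups.

The model is an sklearn-style estimator: ``LMSModel(...).fit(age, y)``
then ``.centiles(...)``, ``.quantile_residuals(...)``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

__all__ = [
    "LMSModel",
    "fit_lms",
    "select_family",
    "percentile_curve",
    "quantile_residuals",
    "bccg_rvs",
    "DEFAULT_LEVELS",
    "FAMILIES",
]

log = logging.getLogger(__name__)

FAMILIES = ("NO", "BCCG")
DEFAULT_LEVELS = (1, 5, 10, 25, 50, 75, 90, 95, 99)
_LAM_EPS = 1e-4


def _spline_basis(u: np.ndarray, df: int) -> np.ndarray:
    """Design matrix of a cubic regression spline with ``df`` flexible
    columns beyond the intercept, on u scaled to [0, 1].

    df = 0 is a constant; df 1-2 are polynomial; df >= 3 is a cubic
    B-spline with df - 3 equally spaced interior knots.  Bases are
    nested as df grows through 0, 1, 2, 3, 4.
    """
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    if df < 0:
        raise ValueError("df must be >= 0")
    if df <= 2:
        return np.column_stack([u**j for j in range(df + 1)])
    interior = np.linspace(0.0, 1.0, df - 1)[1:-1]  # df - 3 interior knots
    knots = np.concatenate([[0.0] * 4, interior, [1.0] * 4])
    dm = BSpline.design_matrix(u, knots, 3, extrapolate=False).toarray()
    return dm


class LMSModel(BaseEstimator):
    """Smooth lambda-mu-sigma percentile model of a measure against age.

    Parameters
    ----------
    family : "NO" or "BCCG"
    df_mu, df_sigma, df_lambda : spline degrees of freedom per curve
        (0 = constant; lambda is kept stiff by default).

    Fitted attributes include ``family_used_`` (may fall back to "NO"
    when y is not strictly positive), per-curve coefficient vectors,
    ``loglik_``, ``deviance_``, ``aic_``, ``edf_`` and ``n_``.
    """

    def __init__(
        self,
        family: str = "BCCG",
        df_mu: int = 3,
        df_sigma: int = 3,
        df_lambda: int = 1,
    ):
        self.family = family
        self.df_mu = df_mu
        self.df_sigma = df_sigma
        self.df_lambda = df_lambda

    # -- likelihood ----------------------------------------------------

    @staticmethod
    def _bccg_z(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray, lam: np.ndarray) -> np.ndarray:
        logr = np.log(y / mu)
        lz = np.clip(lam * logr, -60.0, 60.0)
        small = np.abs(lam) < _LAM_EPS
        lam_safe = np.where(small, 1.0, lam)
        z = np.where(small, logr / sigma, np.expm1(lz) / (lam_safe * sigma))
        return z

    def _unpack(self, theta: np.ndarray):
        k_mu = self._B_mu.shape[1]
        k_sig = self._B_sig.shape[1]
        b_mu = theta[:k_mu]
        b_sig = theta[k_mu : k_mu + k_sig]
        b_lam = theta[k_mu + k_sig :]
        return b_mu, b_sig, b_lam

    def _nll(self, theta: np.ndarray, y: np.ndarray) -> float:
        b_mu, b_sig, b_lam = self._unpack(theta)
        log_sig = np.clip(self._B_sig @ b_sig, -12.0, 12.0)
        sigma = np.exp(log_sig)
        if self.family_used_ == "NO":
            mu = self._B_mu @ b_mu
            z = (y - mu) / sigma
            ll = -log_sig - 0.5 * z**2
        else:
            log_mu = np.clip(self._B_mu @ b_mu, -20.0, 20.0)
            mu = np.exp(log_mu)
            lam = np.clip(self._B_lam @ b_lam, -5.0, 5.0)
            z = self._bccg_z(y, mu, sigma, lam)
            ll = (lam - 1.0) * np.log(y) - lam * log_mu - log_sig - 0.5 * z**2
        total = float(np.sum(ll)) - 0.5 * y.size * np.log(2.0 * np.pi)
        if not np.isfinite(total):
            return 1e12
        return -total

    # -- fitting -------------------------------------------------------

    def fit(self, X, y):
        age = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if age.shape != yv.shape:
            raise ValueError("age and y must have the same length")
        if age.size < 20:
            raise ValueError("LMS fitting needs at least 20 observations")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        self.family_used_ = self.family
        if self.family == "BCCG" and np.min(yv) <= 0.0:
            warnings.warn(
                "response contains zero/negative values; falling back to the NO family",
                UserWarning,
                stacklevel=2,
            )
            log.warning("BCCG requested with non-positive response; using NO family")
            self.family_used_ = "NO"

        self.age_min_, self.age_max_ = float(age.min()), float(age.max())
        span = max(self.age_max_ - self.age_min_, 1e-12)
        u = (age - self.age_min_) / span
        self._B_mu = _spline_basis(u, self.df_mu)
        self._B_sig = _spline_basis(u, self.df_sigma)
        if self.family_used_ == "BCCG":
            self._B_lam = _spline_basis(u, self.df_lambda)
        else:
            self._B_lam = np.zeros((age.size, 0))

        # deterministic initialization: least-squares mean curve, residual
        # spread for sigma, identity power for lambda
        if self.family_used_ == "NO":
            b_mu0, *_ = np.linalg.lstsq(self._B_mu, yv, rcond=None)
            resid = yv - self._B_mu @ b_mu0
            s0 = max(float(np.std(resid)), 1e-6)
            b_sig0 = np.zeros(self._B_sig.shape[1])
            b_sig0[0] = np.log(s0)
            theta0 = np.concatenate([b_mu0, b_sig0])
        else:
            ly = np.log(yv)
            b_mu0, *_ = np.linalg.lstsq(self._B_mu, ly, rcond=None)
            resid = ly - self._B_mu @ b_mu0
            s0 = max(float(np.std(resid)), 1e-6)
            b_sig0 = np.zeros(self._B_sig.shape[1])
            b_sig0[0] = np.log(s0)
            b_lam0 = np.zeros(self._B_lam.shape[1])
            b_lam0[0] = 1.0
            theta0 = np.concatenate([b_mu0, b_sig0, b_lam0])

        res = optimize.minimize(
            self._nll,
            theta0,
            args=(yv,),
            method="L-BFGS-B",
            options={"maxiter": 2000, "maxfun": 50000, "ftol": 1e-12, "gtol": 1e-8},
        )
        nll0 = self._nll(theta0, yv)
        if not np.isfinite(res.fun) or res.fun > nll0 + 1e-6:
            raise RuntimeError(
                f"LMS fit failed to converge ({self.family_used_}): {res.message}; "
                f"nit={res.nit}, nll {nll0:.3f} -> {res.fun:.3f}"
            )
        self._theta = res.x
        self.coef_mu_, self.coef_sigma_, self.coef_lambda_ = self._unpack(res.x)
        self.n_ = int(age.size)
        self.loglik_ = -float(res.fun)
        self.deviance_ = -2.0 * self.loglik_
        self.edf_ = int(res.x.size)  # NO: lambda fixed at 1 contributes 0 df
        self.aic_ = self.deviance_ + 2.0 * self.edf_
        self.opt_result_ = res
        return self

    # -- fitted curves and quantities ----------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "_theta"):
            raise RuntimeError("model is not fitted")

    def curves(self, age_mo) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lambda, mu, sigma) evaluated on an age grid within the fitted
        range."""
        self._check_fitted()
        age = np.asarray(age_mo, dtype=float).reshape(-1)
        tol = 1e-9 * max(1.0, abs(self.age_max_))
        if np.any(age < self.age_min_ - tol) or np.any(age > self.age_max_ + tol):
            raise ValueError(
                f"age grid outside fitted range [{self.age_min_:.1f}, {self.age_max_:.1f}]"
            )
        span = max(self.age_max_ - self.age_min_, 1e-12)
        u = (age - self.age_min_) / span
        B_mu = _spline_basis(u, self.df_mu)
        B_sig = _spline_basis(u, self.df_sigma)
        log_sig = np.clip(B_sig @ self.coef_sigma_, -12.0, 12.0)
        sigma = np.exp(log_sig)
        if self.family_used_ == "NO":
            mu = B_mu @ self.coef_mu_
            lam = np.ones_like(mu)
        else:
            mu = np.exp(np.clip(B_mu @ self.coef_mu_, -20.0, 20.0))
            lam = np.clip(_spline_basis(u, self.df_lambda) @ self.coef_lambda_, -5.0, 5.0)
        return lam, mu, sigma

    def centiles(self, age_grid_mo, levels: Sequence[float] = DEFAULT_LEVELS) -> pd.DataFrame:
        """Percentile table: one row per grid age, one ``p<level>`` column
        per requested level (strictly increasing across levels)."""
        self._check_fitted()
        levels = list(levels)
        for lv in levels:
            if not 0.0 < lv < 100.0:
                raise ValueError(f"percentile level {lv} outside (0, 100)")
        lam, mu, sigma = self.curves(age_grid_mo)
        out = {"age_mo": np.asarray(age_grid_mo, dtype=float).reshape(-1)}
        for lv in levels:
            z = stats.norm.ppf(lv / 100.0)
            if self.family_used_ == "NO":
                vals = mu + sigma * z
            else:
                small = np.abs(lam) < _LAM_EPS
                lam_safe = np.where(small, 1.0, lam)
                arg = np.maximum(1.0 + lam * sigma * z, 1e-10)
                vals = np.where(
                    small, mu * np.exp(sigma * z), mu * arg ** (1.0 / lam_safe)
                )
            out[f"p{lv:g}"] = vals
        return pd.DataFrame(out)

    def cdf(self, age_mo, y) -> np.ndarray:
        """Fitted conditional CDF F(y | age)."""
        self._check_fitted()
        yv = np.asarray(y, dtype=float).reshape(-1)
        lam, mu, sigma = self.curves(age_mo)
        if self.family_used_ == "NO":
            z = (yv - mu) / sigma
        else:
            z = self._bccg_z(yv, mu, sigma, lam)
        return stats.norm.cdf(z)

    def quantile_residuals(self, age_mo, y) -> np.ndarray:
        """Normalized quantile residuals Phi^{-1}(F(y | age)); standard
        normal when the model is correct."""
        p = np.clip(self.cdf(age_mo, y), 1e-12, 1.0 - 1e-12)
        return stats.norm.ppf(p)

    def residual_moments(self, age_mo, y, n_groups: int = 9) -> pd.DataFrame:
        """First four moments of the quantile residuals per equal-count age
        group, z-scored against the N(0, 1) reference moments."""
        age = np.asarray(age_mo, dtype=float).reshape(-1)
        r = self.quantile_residuals(age, y)
        order = np.argsort(age, kind="stable")
        rows = []
        for g, idx in enumerate(np.array_split(order, n_groups)):
            rg = r[idx]
            ag = age[idx]
            n = rg.size
            mean = float(rg.mean())
            var = float(rg.var(ddof=1)) if n > 1 else np.nan
            skew = float(stats.skew(rg, bias=False)) if n > 2 else np.nan
            kurt = float(stats.kurtosis(rg, bias=False)) if n > 3 else np.nan
            rows.append(
                {
                    "group": g + 1,
                    "age_lo_mo": float(ag.min()),
                    "age_hi_mo": float(ag.max()),
                    "n": n,
                    "mean": mean,
                    "variance": var,
                    "skewness": skew,
                    "kurtosis": kurt,
                    "z_mean": mean * np.sqrt(n),
                    "z_variance": (var - 1.0) / np.sqrt(2.0 / max(n - 1, 1)),
                    "z_skewness": skew / np.sqrt(6.0 / n),
                    "z_kurtosis": kurt / np.sqrt(24.0 / n),
                }
            )
        return pd.DataFrame(rows)


def fit_lms(age_mo, y, family: str = "BCCG", df: tuple[int, int, int] = (1, 3, 3)) -> LMSModel:
    """Fit one LMS model; ``df`` is (lambda, mu, sigma) degrees of freedom."""
    df_lam, df_mu, df_sig = df
    return LMSModel(family=family, df_mu=df_mu, df_sigma=df_sig, df_lambda=df_lam).fit(age_mo, y)


def select_family(
    age_mo,
    y,
    candidates: Sequence[str] = FAMILIES,
    df: tuple[int, int, int] = (1, 3, 3),
) -> tuple[LMSModel, pd.DataFrame]:
    """Fit each candidate family and return the lowest-AIC fit plus an AIC
    report for all candidates.

    When y contains zeros or negative values only the NO family is
    estimable and it is returned regardless of the candidate list.
    """
    yv = np.asarray(y, dtype=float).reshape(-1)
    for c in candidates:
        if c not in FAMILIES:
            raise ValueError(f"unknown family {c!r}")
    if np.min(yv) <= 0.0 and "NO" not in candidates:
        candidates = list(candidates) + ["NO"]
    rows = []
    fits: dict[str, LMSModel] = {}
    if np.min(yv) <= 0.0:
        warnings.warn(
            "response contains zero/negative values; only the NO family is fit",
            UserWarning,
            stacklevel=2,
        )
        candidates = ["NO"]
    for fam in candidates:
        try:
            m = fit_lms(age_mo, yv, family=fam, df=df)
            fits[fam] = m
            rows.append({"family": fam, "aic": m.aic_, "edf": m.edf_, "status": "ok"})
        except (RuntimeError, ValueError) as err:
            rows.append({"family": fam, "aic": np.nan, "edf": np.nan, "status": str(err)})
    report = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    if not fits:
        raise RuntimeError(f"all candidate families failed:\n{report}")
    best = min(fits.values(), key=lambda m: m.aic_)
    return best, report


def percentile_curve(fit: LMSModel, age_grid_mo, levels: Sequence[float] = DEFAULT_LEVELS) -> pd.DataFrame:
    """Functional wrapper over :meth:`LMSModel.centiles`."""
    return fit.centiles(age_grid_mo, levels)


def quantile_residuals(fit: LMSModel, age_mo, y) -> np.ndarray:
    """Functional wrapper over :meth:`LMSModel.quantile_residuals`."""
    return fit.quantile_residuals(age_mo, y)


def bccg_rvs(
    rng: np.random.Generator,
    n: int,
    lam: float,
    mu: float,
    sigma: float,
) -> np.ndarray:
    """Sample from the BCCG distribution with constant parameters (used by
    simulation tests; z draws with 1 + lam*sigma*z <= 0 are resampled,
    a negligible truncation for small sigma)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        z = rng.standard_normal(n - filled)
        if abs(lam) < _LAM_EPS:
            vals = mu * np.exp(sigma * z)
            ok = np.ones(vals.size, dtype=bool)
        else:
            arg = 1.0 + lam * sigma * z
            ok = arg > 0
            vals = np.where(ok, mu * np.abs(arg) ** (1.0 / lam), np.nan)
        good = vals[ok]
        out[filled : filled + good.size] = good
        filled += good.size
    return out
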