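"""Developmental curve models of a measure against age.

Three two-parameter families describe how a summary measure y changes
with age (in months):

* inverse:      y = a + b / age   — rises (b < 0) toward the plateau a,
  the biologically motivated default for learning measures;
* logarithmic:  y = a * log(age) + b;
* exponential:  y = a * exp(b * age) — used for measures that decay
  toward zero, such as trial-to-trial variability and the compensation
  angle.

The inverse and logarithmic models are linear in a transformed
predictor and are fit by OLS; the exponential model is fit by nonlinear
least squares from a deterministic start.  All models report 95% Wald
confidence intervals and adjusted R².  Adults are excluded from fits by
the caller (they anchor the plateau visually but are not part of the
developmental curve).

The models are sklearn-style estimators (``fit(X, y)`` with X the ages)
so they compose with sklearn model selection; ``fit_inverse`` /
``fit_log`` / ``fit_exponential`` are functional wrappers returning a
:class:`CurveFit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CurveFit",
    "InverseAgeModel",
    "LogAgeModel",
    "ExponentialAgeModel",
    "fit_inverse",
    "fit_log",
    "fit_exponential",
    "select_model",
]


@dataclass(frozen=True)
class CurveFit:
    """Fitted coefficients of one developmental model."""

    model: str
    a: float
    b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    adj_r2: float
    n: int

    def predict(self, age_mo) -> np.ndarray:
        age = np.asarray(age_mo, dtype=float)
        if self.model == "inverse":
            return self.a + self.b / age
        if self.model == "logarithmic":
            return self.a * np.log(age) + self.b
        return self.a * np.exp(self.b * age)


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    age = np.asarray(X, dtype=float).reshape(-1)
    yv = np.asarray(y, dtype=float).reshape(-1)
    if age.shape != yv.shape:
        raise ValueError("age and y must have the same length")
    if age.size < 3:
        raise ValueError("at least 3 points are required")
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    return age, yv


class _AgeModelBase(RegressorMixin, BaseEstimator):
    model_name = ""

    def fit(self, X, y):
        age, yv = _check_xy(X, y)
        self._fit(age, yv)
        self.n_ = int(age.size)
        return self

    def predict(self, X):
        age = np.asarray(X, dtype=float).reshape(-1)
        return self.curve_fit_.predict(age)

    @property
    def curve_fit_(self) -> CurveFit:
        return CurveFit(
            model=self.model_name,
            a=self.a_,
            b=self.b_,
            ci_a=self.ci_a_,
            ci_b=self.ci_b_,
            adj_r2=self.adj_r2_,
            n=self.n_,
        )


class _LinearizedAgeModel(_AgeModelBase):
    """OLS on a transformed predictor; subclasses define the transform and
    which coefficient is a vs b."""

    def _transform(self, age: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    #: (a, b) read from (intercept, slope)
    _ab_from_params = staticmethod(lambda intercept, slope: (intercept, slope))

    def _fit(self, age: np.ndarray, y: np.ndarray) -> None:
        Xd = sm.add_constant(self._transform(age))
        res = sm.OLS(y, Xd).fit()
        ci = res.conf_int(alpha=0.05)
        (a, b) = self._ab_from_params(res.params[0], res.params[1])
        (ci_a, ci_b) = self._ab_from_params(tuple(ci[0]), tuple(ci[1]))
        self.a_, self.b_ = float(a), float(b)
        self.ci_a_ = (float(ci_a[0]), float(ci_a[1]))
        self.ci_b_ = (float(ci_b[0]), float(ci_b[1]))
        self.adj_r2_ = float(res.rsquared_adj)
        self.ols_result_ = res


class InverseAgeModel(_LinearizedAgeModel):
    """y = a + b / age_mo (linear in 1/age)."""

    model_name = "inverse"

    def _transform(self, age):
        return 1.0 / age


class LogAgeModel(_LinearizedAgeModel):
    """y = a * log(age_mo) + b (linear in log age; the slope is a)."""

    model_name = "logarithmic"
    _ab_from_params = staticmethod(lambda intercept, slope: (slope, intercept))

    def _transform(self, age):
        return np.log(age)


class ExponentialAgeModel(_AgeModelBase):
    """y = a * exp(b * age_mo), fit by nonlinear least squares.

    Start values are deterministic: a0 is y at the youngest age and b0
    the slope of a log-linear regression of |y| on age (falling back to
    a small negative rate when y has non-positive values throughout).
    Confidence intervals are Wald intervals from the Jacobian-based
    covariance.
    """

    model_name = "exponential"

    def _fit(self, age: np.ndarray, y: np.ndarray) -> None:
        order = np.argsort(age)
        a0 = float(y[order[0]])
        mask = np.abs(y) > 1e-8
        if mask.sum() >= 3:
            slope = np.polyfit(age[mask], np.log(np.abs(y[mask])), 1)[0]
            b0 = float(np.clip(slope, -0.2, 0.2))
        else:
            b0 = -0.01
        if a0 == 0.0:
            a0 = float(np.mean(y)) or 1.0
        f = lambda t, a, b: a * np.exp(b * t)
        try:
            popt, pcov = optimize.curve_fit(f, age, y, p0=(a0, b0), maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(f"exponential fit did not converge: {err}") from err
        resid = y - f(age, *popt)
        n = age.size
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.adj_r2_ = 1.0 - (sse / max(n - 2, 1)) / (sst / (n - 1)) if sst > 0 else 0.0
        se = np.sqrt(np.diag(pcov))
        tcrit = stats.t.ppf(0.975, df=max(n - 2, 1))
        self.a_, self.b_ = float(popt[0]), float(popt[1])
        self.ci_a_ = (self.a_ - tcrit * se[0], self.a_ + tcrit * se[0])
        self.ci_b_ = (self.b_ - tcrit * se[1], self.b_ + tcrit * se[1])


def fit_inverse(age_mo, y) -> CurveFit:
    return InverseAgeModel().fit(age_mo, y).curve_fit_


def fit_log(age_mo, y) -> CurveFit:
    return LogAgeModel().fit(age_mo, y).curve_fit_


def fit_exponential(age_mo, y) -> CurveFit:
    return ExponentialAgeModel().fit(age_mo, y).curve_fit_


def select_model(fits) -> CurveFit:
    """The fit with the highest adjusted R²; exact ties go to the inverse
    model (the biologically preferred plateau form)."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("select_model needs at least 2 candidate fits")
    return max(fits, key=lambda f: (f.adj_r2, f.model == "inverse"))
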