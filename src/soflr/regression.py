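"""Driver-count estimation from an overlap-decay curve.

The model: among genes activated by a toxin-induced malignant
transformation, a fixed "driver" set of size d is active in every
independently derived isolate, while each of T "passenger" genes is active
in any one isolate independently with probability p.  The expected number
of genes active in all of k isolates is then

    E[y_k] = d + T p^k,

so log(y_k - d) = alpha + beta k with alpha = log T and beta = log p < 0.
For an unknown d the estimator sequentially tries every integer d below
min(y), fits ordinary least squares of log(y_k - d) on k,
and keeps the d maximizing adjusted R^2 (SOFLR: sequentially optimizing
the fitting of linear regression).  The asymptote d is the predicted
number of genes activated in common among arbitrarily many isolates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .activation import OverlapCurve

__all__ = [
    "RegressionSummary",
    "SoflrFit",
    "SampleSizePrediction",
    "FourPLParameters",
    "SOFLRRegressor",
    "FourParamLogistic",
    "fit_linear_given_d",
    "soflr_fit",
    "predict_common_genes",
    "required_isolates",
    "fit_4pl",
]


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summary of log(y - d) on the isolate count x.

    alpha is the intercept (log T at the true d), beta the slope (log p;
    negative for a decaying curve), residual_sd the usual unbiased
    estimate of the error SD with n - 2 df.
    """

    alpha: float
    beta: float
    r2: float
    adj_r2: float
    residual_sd: float
    n_points: int


@dataclass(frozen=True)
class SoflrFit:
    """Result of the sequential d grid search."""

    d_hat: int
    regression: RegressionSummary
    T_hat: float
    p_hat: float
    d_candidates: np.ndarray
    profile: np.ndarray
    curve: OverlapCurve

    def predict(self, x) -> np.ndarray:
        return predict_common_genes(self, x)


@dataclass(frozen=True)
class SampleSizePrediction:
    """Smallest isolate count at which the predicted common-gene count
    collapses onto d_hat (upper confidence bound within tol of d_hat)."""

    n_required: int
    ci_lower: float
    ci_upper: float
    confidence: float
    tol: float


@dataclass(frozen=True)
class FourPLParameters:
    """Four-parameter logistic y = D + (A - D) / (1 + (x/C)^B)."""

    lower_asymptote: float
    upper_asymptote: float
    inflection: float
    slope: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        A, D, C, B = self.upper_asymptote, self.lower_asymptote, self.inflection, self.slope
        return D + (A - D) / (1.0 + (x / C) ** B)


def _ols_log(x: np.ndarray, z: np.ndarray) -> RegressionSummary:
    """Closed-form simple OLS with R^2, adjusted R^2 and residual SD."""
    n = x.size
    xbar = x.mean()
    zbar = z.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxz = float(np.sum((x - xbar) * (z - zbar)))
    beta = sxz / sxx
    alpha = zbar - beta * xbar
    resid = z - alpha - beta * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((z - zbar) ** 2))
    if ss_tot <= 0:
        # flat response: R^2 defined as 1 when residuals vanish, else 0
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    residual_sd = math.sqrt(max(ss_res, 0.0) / (n - 2))
    return RegressionSummary(
        alpha=float(alpha),
        beta=float(beta),
        r2=float(r2),
        adj_r2=float(adj_r2),
        residual_sd=residual_sd,
        n_points=int(n),
    )


class SOFLRRegressor(RegressorMixin, BaseEstimator):
    """Estimate the driver-set size d from an overlap-decay curve.

    scikit-learn-style regressor: ``fit(X, y)`` takes the isolate counts
    k (one column) and the mean overlap counts y_k, runs the integer grid
    search over d maximizing the adjusted R^2 of the OLS fit of
    log(y - d) on k, and exposes the selected asymptote and the implied
    passenger parameters.  ``predict(X)`` returns d_hat + T_hat p_hat^x.

    Parameters
    ----------
    d_min : int, default 0
        Smallest candidate driver count.
    d_max : int or None
        Largest candidate; defaults to the largest integer strictly below
        min(y) so every log argument stays positive.
    tie_tol : float, default 1e-12
        Adjusted-R^2 ties within this tolerance resolve to the smallest d
        (the conservative reading: fewer drivers).

    Attributes
    ----------
    d_hat_ : int
        Selected driver count (argmax of the adjusted-R^2 profile).
    alpha_, beta_ : float
        Intercept and slope of the OLS fit at d_hat_ (natural log scale).
    T_hat_, p_hat_ : float
        exp(alpha_) and exp(beta_): implied passenger-set size and
        per-isolate activation probability.
    adj_r2_, r2_, residual_sd_ : float
        Fit quality at d_hat_.
    d_candidates_, adj_r2_profile_ : ndarray
        The candidate grid and its adjusted-R^2 profile.
    regression_ : RegressionSummary
        Full OLS summary at d_hat_.
    """

    def __init__(self, d_min: int = 0, d_max: Optional[int] = None, tie_tol: float = 1e-12):
        self.d_min = d_min
        self.d_max = d_max
        self.tie_tol = tie_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        x = X[:, 0].astype(float)
        if X.shape[1] != 1:
            raise ValueError("X must have a single column: the isolate count k")
        if np.any(y <= 0):
            raise ValueError("overlap counts must be strictly positive")
        if y.min() < 1:
            raise ValueError(
                f"empty candidate range: min(y) = {y.min()} is below 1, "
                "so no nonnegative integer d keeps y - d positive at scale"
            )
        d_max = self.d_max
        if d_max is None:
            # largest integer strictly below min(y): "d from 0 to y - 1"
            d_max = int(math.ceil(y.min())) - 1
        if d_max < self.d_min:
            raise ValueError(
                f"empty candidate range [{self.d_min}, {d_max}]; "
                "min(y) must be >= 1 and d_min <= d_max"
            )
        candidates = np.arange(self.d_min, d_max + 1)
        profile = np.empty(candidates.size, dtype=float)
        summaries = []
        for i, d in enumerate(candidates):
            if y.min() <= d:
                raise ValueError(f"candidate d={d} is not below min(y)={y.min()}")
            summ = _ols_log(x, np.log(y - d))
            summaries.append(summ)
            profile[i] = summ.adj_r2
        best = int(np.argmax(profile))
        # smallest d within tie_tol of the maximum
        ties = np.nonzero(profile >= profile[best] - self.tie_tol)[0]
        best = int(ties[0])
        summ = summaries[best]

        self.n_features_in_ = 1
        self.d_hat_ = int(candidates[best])
        self.regression_ = summ
        self.alpha_ = summ.alpha
        self.beta_ = summ.beta
        self.r2_ = summ.r2
        self.adj_r2_ = summ.adj_r2
        self.residual_sd_ = summ.residual_sd
        self.T_hat_ = math.exp(summ.alpha)
        self.p_hat_ = math.exp(summ.beta)
        self.d_candidates_ = candidates
        self.adj_r2_profile_ = profile
        self.x_ = x
        self.y_ = y.astype(float)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "d_hat_")
        X = check_array(X)
        x = X[:, 0].astype(float)
        if self.p_hat_ >= 1.0:
            warnings.warn(
                "fitted p_hat >= 1: the curve does not decay; predictions grow with x",
                RuntimeWarning,
                stacklevel=2,
            )
        return self.d_hat_ + self.T_hat_ * self.p_hat_**x

    def required_isolates(
        self, confidence: float = 0.95, tol: float = 0.5, x_max: int = 1000
    ) -> SampleSizePrediction:
        """Smallest isolate count whose predicted common-gene count has
        collapsed onto d_hat.

        At each hypothetical isolate count x the two-sided confidence
        interval for the mean response of the log-scale regression is
        computed with the Student-t quantile at n - 2 df, exponentiated,
        and shifted by d_hat; the first x whose upper bound exceeds d_hat
        by less than ``tol`` genes is returned.
        """
        check_is_fitted(self, "d_hat_")
        return _required_isolates(
            d_hat=self.d_hat_,
            summary=self.regression_,
            x=self.x_,
            confidence=confidence,
            tol=tol,
            x_max=x_max,
        )

    def to_fit(self, curve: Optional[OverlapCurve] = None) -> SoflrFit:
        check_is_fitted(self, "d_hat_")
        if curve is None:
            curve = OverlapCurve(y=self.y_)
        return SoflrFit(
            d_hat=self.d_hat_,
            regression=self.regression_,
            T_hat=self.T_hat_,
            p_hat=self.p_hat_,
            d_candidates=self.d_candidates_,
            profile=self.adj_r2_profile_,
            curve=curve,
        )


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Four-parameter logistic comparator, y = D + (A - D)/(1 + (x/C)^B).

    Fit by nonlinear least squares on the original count scale with the
    lower asymptote bounded at zero.  The lower asymptote D is an
    informational comparator for the driver count; it is never used as
    the estimate itself.  Initialization: A0 = y at the smallest x,
    D0 = y at the largest x, C0 = median x, B0 = 1.
    """

    def __init__(self, max_nfev: int = 20000):
        self.max_nfev = max_nfev

    @staticmethod
    def _model(x, A, D, C, B):
        return D + (A - D) / (1.0 + (x / C) ** B)

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        x = X[:, 0].astype(float)
        order = np.argsort(x)
        p0 = [float(y[order[0]]), float(y[order[-1]]), float(np.median(x)), 1.0]
        bounds = ([-np.inf, 0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf])
        try:
            popt, pcov = optimize.curve_fit(
                self._model, x, y, p0=p0, bounds=bounds, max_nfev=self.max_nfev
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"4PL fit did not converge from initialization {p0} "
                f"within {self.max_nfev} evaluations: {err}"
            ) from err
        self.n_features_in_ = 1
        self.upper_asymptote_ = float(popt[0])
        self.lower_asymptote_ = float(popt[1])
        self.inflection_ = float(popt[2])
        self.slope_ = float(popt[3])
        self.covariance_ = pcov
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "lower_asymptote_")
        X = check_array(X)
        return self._model(
            X[:, 0].astype(float),
            self.upper_asymptote_,
            self.lower_asymptote_,
            self.inflection_,
            self.slope_,
        )


def _required_isolates(
    d_hat: int,
    summary: RegressionSummary,
    x: np.ndarray,
    confidence: float,
    tol: float,
    x_max: int,
) -> SampleSizePrediction:
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if summary.beta >= 0:
        raise ValueError("required_isolates needs a decaying fit (beta < 0)")
    n = summary.n_points
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    tq = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    for xp in range(1, x_max + 1):
        mu = summary.alpha + summary.beta * xp
        se = summary.residual_sd * math.sqrt(1.0 / n + (xp - xbar) ** 2 / sxx)
        hi = d_hat + math.exp(mu + tq * se)
        lo = d_hat + math.exp(mu - tq * se)
        if hi - d_hat < tol:
            return SampleSizePrediction(
                n_required=xp, ci_lower=lo, ci_upper=hi, confidence=confidence, tol=tol
            )
    raise ValueError(
        f"no isolate count <= {x_max} brings the upper bound within "
        f"{tol} of d_hat={d_hat}; not achievable in the scanned range"
    )


# ---------------------------------------------------------------------------
# functional surface over the estimators


def _as_xy(curve: OverlapCurve) -> tuple[np.ndarray, np.ndarray]:
    return curve.x.reshape(-1, 1).astype(float), curve.y


def fit_linear_given_d(curve: OverlapCurve, d: int) -> RegressionSummary:
    """OLS of log(y_k - d) on k for a fixed candidate driver count d."""
    if d < 0:
        raise ValueError("d must be a nonnegative integer")
    if curve.n < 3:
        raise ValueError("need at least 3 points to fit the log-linear model")
    if curve.y.min() <= d:
        raise ValueError(f"every y_k must exceed d={d} (min y = {curve.y.min()})")
    return _ols_log(curve.x.astype(float), np.log(curve.y - d))


def soflr_fit(curve: OverlapCurve, d_min: int = 0, d_max: Optional[int] = None) -> SoflrFit:
    """Sequential grid search over integer d maximizing adjusted R^2."""
    est = SOFLRRegressor(d_min=d_min, d_max=d_max)
    est.fit(*_as_xy(curve))
    return est.to_fit(curve)


def predict_common_genes(fit: SoflrFit, x) -> np.ndarray | float:
    """Predicted common-gene count d_hat + T_hat p_hat^x at isolate count x."""
    if fit.p_hat >= 1.0:
        warnings.warn(
            "fitted p_hat >= 1: the curve does not decay; prediction is not an asymptote",
            RuntimeWarning,
            stacklevel=2,
        )
    xa = np.asarray(x, dtype=float)
    out = fit.d_hat + fit.T_hat * fit.p_hat**xa
    return float(out) if np.isscalar(x) else out


def required_isolates(
    fit: SoflrFit, confidence: float = 0.95, tol: float = 0.5, x_max: int = 1000
) -> SampleSizePrediction:
    """Smallest isolate count at which the common-gene prediction collapses
    onto d_hat; see SOFLRRegressor.required_isolates for the convention."""
    return _required_isolates(
        d_hat=fit.d_hat,
        summary=fit.regression,
        x=fit.curve.x.astype(float),
        confidence=confidence,
        tol=tol,
        x_max=x_max,
    )


def fit_4pl(curve: OverlapCurve) -> FourPLParameters:
    """Four-parameter logistic comparator fit on the count scale."""
    est = FourParamLogistic()
    est.fit(*_as_xy(curve))
    return FourPLParameters(
        lower_asymptote=est.lower_asymptote_,
        upper_asymptote=est.upper_asymptote_,
        inflection=est.inflection_,
        slope=est.slope_,
    )
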