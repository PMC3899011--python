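"""Driver-count regression: OLS core, d grid search, predictions."""

import math
import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from soflr import (
    FourParamLogistic,
    OverlapCurve,
    SOFLRRegressor,
    fit_4pl,
    fit_linear_given_d,
    predict_common_genes,
    required_isolates,
    soflr_fit,
)


def statsmodels_ols(x, z):
    """Independent OLS oracle (statsmodels), returning the same summary
    quantities the package computes in closed form."""
    res = sm.OLS(z, sm.add_constant(x)).fit()
    return {
        "alpha": res.params[0],
        "beta": res.params[1],
        "r2": res.rsquared,
        "adj_r2": res.rsquared_adj,
        "residual_sd": math.sqrt(res.mse_resid),
    }


class TestFitLinearGivenD:
    def test_agrees_with_statsmodels_for_every_candidate(self, cd_curve):
        """Closed-form OLS equals the normal-equation oracle to 1e-10
        across the entire candidate grid."""
        x = cd_curve.x.astype(float)
        for d in range(0, 285):
            summ = fit_linear_given_d(cd_curve, d)
            want = statsmodels_ols(x, np.log(cd_curve.y - d))
            assert summ.alpha == pytest.approx(want["alpha"], abs=1e-10)
            assert summ.beta == pytest.approx(want["beta"], abs=1e-10)
            assert summ.r2 == pytest.approx(want["r2"], abs=1e-10)
            assert summ.adj_r2 == pytest.approx(want["adj_r2"], abs=1e-10)
            assert summ.residual_sd == pytest.approx(want["residual_sd"], abs=1e-10)

    def test_three_point_closed_form(self):
        """(9, 5, 3) with d = 1 is exactly log-linear: points
        (1, log 8), (2, log 4), (3, log 2)."""
        curve = OverlapCurve(y=[9.0, 5.0, 3.0])
        summ = fit_linear_given_d(curve, 1)
        assert summ.beta == pytest.approx(math.log(0.5), abs=1e-12)
        assert summ.alpha == pytest.approx(math.log(16.0), abs=1e-12)
        assert summ.r2 == pytest.approx(1.0, abs=1e-12)
        assert summ.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_geometric(self):
        y = 1000.0 * 0.5 ** np.arange(1, 7)
        summ = fit_linear_given_d(OverlapCurve(y=y), 0)
        assert summ.r2 == pytest.approx(1.0, abs=1e-12)
        assert summ.beta == pytest.approx(math.log(0.5), abs=1e-10)

    def test_adj_r2_never_exceeds_r2(self, cd_curve):
        for d in (0, 100, 233):
            summ = fit_linear_given_d(cd_curve, d)
            assert summ.adj_r2 <= summ.r2

    def test_d_at_or_above_min_y_rejected(self, cd_curve):
        with pytest.raises(ValueError, match="exceed"):
            fit_linear_given_d(cd_curve, 285)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_linear_given_d(OverlapCurve(y=[10.0, 4.0]), 0)


class TestGridSearch:
    def test_cadmium_curve_profile(self, cd_curve):
        """On the printed (rounded) cadmium curve the adjusted-R^2 profile
        peaks at d = 234 with adjusted R^2 = 0.993 to three decimals; the
        profile value at 233 is within 1e-6 of the peak."""
        fit = soflr_fit(cd_curve)
        assert fit.d_hat == 234
        assert round(fit.regression.adj_r2, 3) == 0.993
        assert fit.d_candidates[0] == 0 and fit.d_candidates[-1] == 284
        assert fit.profile.argmax() == fit.d_hat
        assert fit.profile[233] == pytest.approx(fit.profile[234], abs=1e-6)

    def test_profile_matches_independent_refit(self, cd_curve):
        """Every profile entry equals a from-scratch statsmodels fit."""
        fit = soflr_fit(cd_curve)
        x = cd_curve.x.astype(float)
        for d in (0, 57, 233, 284):
            want = statsmodels_ols(x, np.log(cd_curve.y - d))["adj_r2"]
            assert fit.profile[d] == pytest.approx(want, abs=1e-10)

    def test_pure_geometric_selects_zero(self):
        fit = soflr_fit(OverlapCurve(y=[8.0, 4.0, 2.0]))
        assert fit.d_hat == 0
        assert fit.regression.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_curve_recovers_exact_parameters(self):
        y = 50.0 + 1000.0 * 0.3 ** np.arange(1, 7)
        fit = soflr_fit(OverlapCurve(y=y))
        assert fit.d_hat == 50
        assert fit.p_hat == pytest.approx(0.3, rel=1e-6)
        assert fit.T_hat == pytest.approx(1000.0, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        d=st.integers(0, 300),
        T=st.floats(50.0, 5000.0),
        p=st.floats(0.05, 0.9),
        n=st.integers(4, 10),
    )
    def test_exact_recovery_on_noiseless_curves(self, d, T, p, n):
        """For any noiseless d + T p^k curve the profile attains R^2 = 1
        at the true d and nowhere below it."""
        y = d + T * p ** np.arange(1, n + 1)
        if y[-1] < 1.0:  # outside the estimator's domain (no valid candidate)
            return
        if y[-1] - d < 1e-6:  # tail numerically indistinguishable from d
            return
        fit = soflr_fit(OverlapCurve(y=y))
        assert fit.d_hat == d
        assert fit.regression.r2 == pytest.approx(1.0, abs=1e-9)

    def test_log_base_invariance(self, cd_curve):
        """d_hat and R^2 are unchanged under base-10 logs (R^2 is
        affine-invariant); verified against a base-10 refit."""
        fit = soflr_fit(cd_curve)
        x = cd_curve.x.astype(float)
        profile10 = np.array(
            [
                statsmodels_ols(x, np.log10(cd_curve.y - d))["adj_r2"]
                for d in range(0, 285)
            ]
        )
        assert int(profile10.argmax()) == fit.d_hat
        np.testing.assert_allclose(profile10, fit.profile, atol=1e-9)

    def test_min_y_below_one_rejected(self):
        with pytest.raises(ValueError, match="candidate range"):
            soflr_fit(OverlapCurve(y=[0.9, 0.5, 0.4]))

    def test_tie_breaks_to_smallest_d(self):
        y = 5.0 + 20.0 * 0.5 ** np.arange(1, 6)
        X = np.arange(1, 6).reshape(-1, 1).astype(float)
        sharp = SOFLRRegressor().fit(X, y)
        assert sharp.d_hat_ > 0  # untied argmax is interior
        loose = SOFLRRegressor(tie_tol=1.0).fit(X, y)  # everything ties
        assert loose.d_hat_ == 0


class TestPrediction:
    def _fit(self, y):
        return soflr_fit(OverlapCurve(y=np.asarray(y, dtype=float)))

    def test_direct_formula(self):
        fit = self._fit(50.0 + 1000.0 * 0.3 ** np.arange(1, 7))
        assert predict_common_genes(fit, 3) == pytest.approx(
            fit.d_hat + fit.T_hat * fit.p_hat**3
        )

    def test_asymptote_is_d_hat(self, cd_curve):
        fit = soflr_fit(cd_curve)
        assert predict_common_genes(fit, 10**6) == pytest.approx(fit.d_hat, abs=1e-6)

    def test_strictly_decreasing_in_x(self, cd_curve):
        fit = soflr_fit(cd_curve)
        preds = predict_common_genes(fit, np.arange(1, 30))
        assert np.all(np.diff(preds) < 0)

    def test_in_sample_prediction_within_residual_scatter(self, cd_curve):
        """The fitted value at x = 6 sits within the largest log-scale
        residual of the observed y_6."""
        fit = soflr_fit(cd_curve)
        resid = np.abs(
            np.log(cd_curve.y - fit.d_hat)
            - (fit.regression.alpha + fit.regression.beta * cd_curve.x)
        )
        pred = predict_common_genes(fit, 6)
        log_err = abs(math.log(pred - fit.d_hat) - math.log(cd_curve.y[-1] - fit.d_hat))
        assert log_err <= resid.max() + 1e-12

    def test_non_decaying_fit_warns(self):
        y = np.asarray([10.0, 9.0, 8.5, 8.4], dtype=float)
        fit = soflr_fit(OverlapCurve(y=y))
        object.__setattr__(fit, "p_hat", 1.2)
        with pytest.warns(RuntimeWarning, match="p_hat"):
            predict_common_genes(fit, 3)


class TestRequiredIsolates:
    def test_noiseless_reduces_to_point_prediction(self):
        """With zero residual SD the interval has zero width, so the rule
        is T p^x < tol: for T = 1000, p = 0.5, tol = 0.5 that is x = 11."""
        y = 1000.0 * 0.5 ** np.arange(1, 7)
        fit = soflr_fit(OverlapCurve(y=y), d_max=0)
        pred = required_isolates(fit, tol=0.5)
        assert pred.n_required == 11
        assert pred.ci_upper - pred.ci_lower == pytest.approx(0.0, abs=1e-9)

    def test_cadmium_curve_neighbourhood(self, cd_curve):
        """On the printed cadmium curve the mean-response convention puts
        the required isolate count in the mid-teens."""
        pred = required_isolates(soflr_fit(cd_curve))
        assert 12 <= pred.n_required <= 17
        assert pred.ci_upper >= pred.ci_lower >= 234

    def test_stopping_rule_boundary(self, cd_curve):
        """n_required is the first x satisfying the criterion: the bound is
        within tol there and not at any smaller x."""
        fit = soflr_fit(cd_curve)
        pred = required_isolates(fit)
        assert pred.ci_upper - fit.d_hat < pred.tol
        with pytest.raises(ValueError, match="not achievable"):
            required_isolates(fit, tol=pred.tol, x_max=pred.n_required - 1)

    def test_monotone_in_tol_and_confidence(self, cd_curve):
        fit = soflr_fit(cd_curve)
        tols = [0.1, 0.5, 1.0, 5.0]
        ns = [required_isolates(fit, tol=t).n_required for t in tols]
        assert ns == sorted(ns, reverse=True)
        confs = [0.5, 0.8, 0.95, 0.99]
        ns = [required_isolates(fit, confidence=c).n_required for c in confs]
        assert ns == sorted(ns)

    def test_unreachable_range_reported(self, cd_curve):
        fit = soflr_fit(cd_curve)
        with pytest.raises(ValueError, match="not achievable"):
            required_isolates(fit, tol=0.5, x_max=5)

    def test_non_decaying_fit_rejected(self):
        fit = soflr_fit(OverlapCurve(y=[9.0, 5.0, 3.0]))
        object.__setattr__(
            fit, "regression", fit.regression.__class__(
                alpha=fit.regression.alpha, beta=0.1, r2=fit.regression.r2,
                adj_r2=fit.regression.adj_r2, residual_sd=fit.regression.residual_sd,
                n_points=fit.regression.n_points,
            )
        )
        with pytest.raises(ValueError, match="beta < 0"):
            required_isolates(fit)


class TestFourPL:
    def test_constant_curve_has_equal_asymptotes(self):
        params = fit_4pl(OverlapCurve(y=[40.0, 40.0, 40.0, 40.0]))
        assert params.lower_asymptote == pytest.approx(40.0, abs=1e-6)
        assert params.upper_asymptote == pytest.approx(40.0, abs=1e-6)

    def test_noiseless_self_recovery(self):
        x = np.arange(1, 9, dtype=float)
        A, D, C, B = 2000.0, 100.0, 2.0, 1.5
        y = D + (A - D) / (1 + (x / C) ** B)
        est = FourParamLogistic().fit(x.reshape(-1, 1), y)
        assert est.upper_asymptote_ == pytest.approx(A, rel=1e-4)
        assert est.lower_asymptote_ == pytest.approx(D, rel=1e-4)
        assert est.inflection_ == pytest.approx(C, rel=1e-4)
        assert est.slope_ == pytest.approx(B, rel=1e-4)

    def test_predict_interpolates_fit(self, cd_curve):
        est = FourParamLogistic().fit(cd_curve.x.reshape(-1, 1), cd_curve.y)
        pred = est.predict(cd_curve.x.reshape(-1, 1))
        assert np.sqrt(np.mean((pred - cd_curve.y) ** 2)) < 10.0


class TestSklearnContract:
    def test_clone_and_params_round_trip(self):
        from sklearn.base import clone

        est = SOFLRRegressor(d_min=5, d_max=100, tie_tol=1e-9)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fitted_attributes_and_score(self, cd_curve):
        X = cd_curve.x.reshape(-1, 1).astype(float)
        est = SOFLRRegressor().fit(X, cd_curve.y)
        for attr in ("d_hat_", "alpha_", "beta_", "T_hat_", "p_hat_", "adj_r2_profile_"):
            assert hasattr(est, attr)
        # count-scale R^2 of the plug-in prediction (the selection criterion
        # lives on the log scale, so this is looser than adj_r2_)
        assert est.score(X, cd_curve.y) > 0.95

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            SOFLRRegressor().predict(np.asarray([[1.0]]))
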