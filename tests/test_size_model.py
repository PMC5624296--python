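import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hgtenrich import size_model as sm
from hgtenrich.errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)
from hgtenrich.models import LogLogisticFit, ResidualMatrix


class TestLogLogisticCurve:
    def test_midpoint_identity(self):
        # at x = e the curve sits exactly halfway between the asymptotes
        assert sm.log_logistic(1000.0, b=-1.3, c=10.0, d=400.0, e=1000.0) == pytest.approx(205.0)

    def test_hand_evaluated_point(self):
        # c + (d-c)/(1+(x/e)^b) with b=-1: 100/(1 + 1000/9000) = 90
        assert sm.log_logistic(9000.0, b=-1.0, c=0.0, d=100.0, e=1000.0) == pytest.approx(90.0)

    def test_saturates_at_upper_asymptote(self):
        val = sm.log_logistic(1e12, b=-1.5, c=5.0, d=300.0, e=2000.0)
        assert val == pytest.approx(300.0, abs=1e-3)

    def test_rejects_nonpositive_x(self):
        with pytest.raises(DomainError):
            sm.log_logistic(0.0, b=-1.0, c=0.0, d=1.0, e=100.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        b=st.floats(-3, -0.2),
        c=st.floats(0, 50),
        dd=st.floats(1, 500),
        e=st.floats(100, 5000),
        x1=st.floats(1, 20000),
        x2=st.floats(1, 20000),
    )
    def test_monotone_increasing_for_negative_b(self, b, c, dd, e, x1, x2):
        lo, hi = sorted((x1, x2))
        y_lo = sm.log_logistic(lo, b, c, c + dd, e)
        y_hi = sm.log_logistic(hi, b, c, c + dd, e)
        assert y_lo <= y_hi + 1e-9


class TestFitLogLogistic:
    def test_noiseless_recovery_within_1e3_relative(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(500, 9500, 50)
        true = dict(b=-1.8, c=55.0, d=420.0, e=3000.0)
        y = sm.log_logistic(x, **true)
        f = sm.fit_log_logistic(x, y)
        for name in "bcde":
            assert abs(getattr(f, name) - true[name]) / abs(true[name]) < 1e-3
        assert f.converged
        assert f.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_constant_counts_degenerate(self):
        x = np.linspace(500, 5000, 20)
        f = sm.fit_log_logistic(x, np.full(20, 37.0))
        assert f.degenerate
        assert f.c == pytest.approx(f.d)
        assert f.residual_sd == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            sm.fit_log_logistic([1000, 2000, 3000, 4000], [1, 2, 3, 4])

    def test_noisy_recovery_single_archaeon(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(500, 9500, 400)
        true = dict(b=-1.6, c=60.0, d=380.0, e=2800.0)
        y = sm.log_logistic(x, **true) + rng.normal(0, 5, 400)
        f = sm.fit_log_logistic(x, y)
        for name in "bcde":
            assert abs(getattr(f, name) - true[name]) / abs(true[name]) < 0.10
        assert f.residual_sd == pytest.approx(5.0, rel=0.15)


class TestKorbel:
    def test_equal_sizes_give_maximum(self):
        assert sm.korbel_weight(3000, 3000) == pytest.approx(np.sqrt(2) / 2)

    def test_hand_value(self):
        # sqrt(2)*2000*4000 / (2000^2 + 4000^2) = 0.56569
        assert sm.korbel_weight(2000, 4000) == pytest.approx(0.56569, abs=1e-5)

    def test_symmetry(self):
        assert sm.korbel_weight(1234, 5678) == pytest.approx(sm.korbel_weight(5678, 1234))

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            sm.korbel_weight(0, 100)

    def test_scale_exact_recovery(self):
        rng = np.random.default_rng(1)
        pairs = rng.uniform(1000, 6000, (30, 2))
        w = sm.korbel_weight(pairs[:, 0], pairs[:, 1])
        s = sm.fit_korbel_scale(pairs, 321.5 * w)
        assert s == pytest.approx(321.5)

    def test_scale_single_pair_closed_form(self):
        # w(A, B) = 0.5 when B/A = 1 + sqrt(2); count 100 -> s = 200
        A = 1000.0
        B = A * (1 + np.sqrt(2))
        assert sm.korbel_weight(A, B) == pytest.approx(0.5)
        s = sm.fit_korbel_scale([(A, B), (A, B)], [100.0, 100.0])
        assert s == pytest.approx(200.0)

    def test_scale_unbiased_under_symmetric_noise(self):
        rng = np.random.default_rng(2)
        pairs = rng.uniform(1000, 6000, (200, 2))
        w = sm.korbel_weight(pairs[:, 0], pairs[:, 1])
        estimates = [
            sm.fit_korbel_scale(pairs, 300 * w + rng.normal(0, 10, len(w)))
            for _ in range(50)
        ]
        assert np.mean(estimates) == pytest.approx(300.0, rel=0.01)


class TestResiduals:
    @staticmethod
    def _fit(archaeon="A1", b=-1.5, c=50.0, d=400.0, e=2500.0, sd=5.0):
        return LogLogisticFit(archaeon=archaeon, b=b, c=c, d=d, e=e,
                              residual_sd=sd, converged=True, n_points=10)

    def test_subtraction_arithmetic(self):
        f = self._fit()
        sizes = pd.Series({"B1": 2500.0})
        rbh = pd.DataFrame({"A1": [500.0]}, index=["B1"])
        res = sm.residual_matrix(rbh, {"A1": f}, sizes)
        assert res.values.loc["B1", "A1"] == pytest.approx(500.0 - 225.0)

    def test_zero_when_prediction_equals_count(self):
        f = self._fit()
        sizes = pd.Series({"B1": 1000.0, "B2": 4000.0})
        rbh = pd.DataFrame({"A1": [f.predict(1000.0), f.predict(4000.0)]},
                           index=["B1", "B2"])
        res = sm.residual_matrix(rbh, {"A1": f}, sizes)
        assert np.allclose(res.values.to_numpy(), 0.0)

    def test_missing_fit_names_archaeon(self):
        sizes = pd.Series({"B1": 1000.0})
        rbh = pd.DataFrame({"A9": [10.0]}, index=["B1"])
        with pytest.raises(Exception, match="A9"):
            sm.residual_matrix(rbh, {}, sizes)

    def test_own_fit_residuals_center_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(500, 9500, 300)
        y = sm.log_logistic(x, -1.7, 50, 400, 3000) + rng.normal(0, 5, 300)
        f = sm.fit_log_logistic(x, y, archaeon="A1")
        sizes = pd.Series(x, index=[f"B{i}" for i in range(300)])
        rbh = pd.DataFrame({"A1": y}, index=sizes.index)
        res = sm.residual_matrix(rbh, {"A1": f}, sizes)
        col = res.values["A1"]
        assert abs(col.mean()) < 0.1 * f.residual_sd


class TestDecorrelation:
    def test_proper_fit_decorrelates(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(500, 9500, 400)
        y = sm.log_logistic(x, -1.7, 50, 400, 3000) + rng.normal(0, 5, 400)
        f = sm.fit_log_logistic(x, y)
        assert sm.decorrelation_check(y - f.predict(x), x) < 0.01

    def test_raw_counts_stay_correlated(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(500, 9500, 200)
        y = sm.log_logistic(x, -1.7, 50, 400, 3000) + rng.normal(0, 5, 200)
        assert sm.decorrelation_check(y, x) > 0.5

    def test_orthogonalized_residuals_give_zero(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(500, 9500, 100)
        y = rng.normal(0, 1, 100)
        xc = x - x.mean()
        resid = y - (y @ xc) / (xc @ xc) * xc  # exact projection removal
        assert sm.decorrelation_check(resid - resid.mean(), x) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        with pytest.warns(UserWarning):
            out = sm.decorrelation_check([1.0, 1.0, 1.0], [100.0, 200.0, 300.0])
        assert np.isnan(out)


class TestSecondaryResiduals:
    @staticmethod
    def _toy(n=300, gc_slope=0.0, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"B{i}" for i in range(n)]
        sizes = pd.Series(rng.uniform(500, 9500, n), index=idx)
        gc = pd.Series(rng.uniform(30, 70, n), index=idx)
        noise = rng.normal(0, 5, n)
        primary = pd.DataFrame({"A1": gc_slope * (gc - gc.mean()) + noise}, index=idx)
        res = ResidualMatrix(values=primary, residual_sd=pd.Series({"A1": 5.0}))
        return res, sizes, gc

    def test_exact_linear_gc_removed(self):
        res, sizes, gc = self._toy(gc_slope=0.26, seed=1)
        res.values["A1"] -= res.values["A1"] - 0.26 * (gc - gc.mean())  # pure GC signal
        out = sm.secondary_residuals(res, sizes, gc)
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-9)

    def test_no_gc_effect_leaves_residuals_alone(self):
        res, sizes, gc = self._toy(gc_slope=0.0, seed=2)
        out = sm.secondary_residuals(res, sizes, gc)
        diff = (out.values["A1"] - res.values["A1"]).abs().mean()
        assert diff < 0.5  # well below the noise SD of 5

    def test_gc_slope_recovered(self):
        # slope 2.6 residual RBHs per 10% GC = 0.26 per unit
        res, sizes, gc = self._toy(n=500, gc_slope=0.26, seed=3)
        import statsmodels.api as smapi

        X = smapi.add_constant(np.column_stack([gc.values, sizes.values]))
        fit = smapi.OLS(res.values["A1"].values, X).fit()
        assert fit.params[1] == pytest.approx(0.26, rel=0.15)
        out = sm.secondary_residuals(res, sizes, gc)
        # after adjustment the GC signal is gone
        fit2 = smapi.OLS(out.values["A1"].values, X).fit()
        assert abs(fit2.params[1]) < 0.05

    def test_collinear_design_rejected(self):
        res, sizes, gc = self._toy(seed=4)
        with pytest.raises(DegenerateDataError):
            sm.secondary_residuals(res, sizes, gc * 0 + 50.0)


def test_loglogistic_beats_korbel_for_large_genomes():
    """On saturating truth, the log-logistic fit predicts large genomes better."""
    rng = np.random.default_rng(9)
    x = rng.uniform(500, 9500, 300)
    A = 2500.0
    y = sm.log_logistic(x, -1.7, 60, 400, 2800) + rng.normal(0, 5, 300)
    f = sm.fit_log_logistic(x, y)
    s = sm.fit_korbel_scale(np.column_stack([np.full_like(x, A), x]), y)
    big = x > 5000
    rmse_ll = np.sqrt(np.mean((y[big] - f.predict(x[big])) ** 2))
    rmse_ko = np.sqrt(np.mean((y[big] - s * sm.korbel_weight(A, x[big])) ** 2))
    assert rmse_ll <= rmse_ko
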