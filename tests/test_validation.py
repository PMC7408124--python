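"""The validation battery: LOO, external predictivity, K index, scrambling,
applicability domain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from loxqsar.models import DescriptorMLR, ols_fit
from loxqsar.validation import (
    applicability_domain,
    build_validation_report,
    ccc,
    external_metrics,
    k_correlation,
    loo_predictions,
    q2_loo,
    r2m_metrics,
    y_scramble,
)


def explicit_loo(X, y):
    """Refit-n-times oracle for leave-one-out predictions."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        m = DescriptorMLR().fit(X[mask], y[mask])
        out[i] = m.predict(X[i : i + 1])[0]
    return out


class TestQ2LOO:
    def test_closed_form_equals_explicit_refits(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 30))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            np.testing.assert_allclose(
                loo_predictions(X, y), explicit_loo(X, y), atol=1e-10
            )

    def test_exact_linear_data(self):
        x = np.arange(12.0)[:, None]
        assert q2_loo(x, 3 * x.ravel() - 1) == pytest.approx(1.0)

    def test_noise_q2_below_r2(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        assert q2_loo(X, y) < ols_fit(X, y).r2_

    def test_degenerate_leverage_raises(self):
        # one point isolated in x makes its leverage 1 on refit designs
        X = np.array([[0.0], [0.0], [0.0], [1.0]])
        X = np.column_stack([X, X**2])
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            q2_loo(X, np.array([0.0, 0.1, -0.1, 5.0]))


class TestExternalMetrics:
    def fit_toy(self, rng):
        X = rng.standard_normal((20, 2))
        y = X @ [1.0, -0.5] + 0.1 * rng.standard_normal(20)
        return DescriptorMLR().fit(X, y), X, y

    def test_perfect_predictions(self):
        x = np.arange(10.0)[:, None]
        y = 2 * x.ravel()
        model = DescriptorMLR().fit(x, y)
        x_ext = np.array([[1.5], [3.5], [7.2]])
        out = external_metrics(model, x_ext, 2 * x_ext.ravel(), y)
        for key in ("Q2_F1", "Q2_F2", "Q2_F3", "CCC_ext", "R2_ext"):
            assert out[key] == pytest.approx(1.0, abs=1e-10)
        assert out["RMSE_ext"] == pytest.approx(0.0, abs=1e-10)

    def test_training_mean_predictions_zero_f1(self, rng):
        model, X, y = self.fit_toy(rng)
        # force predictions == training mean by zeroing the model
        model.coef_ = np.zeros(2)
        model.intercept_ = float(y.mean())
        out = external_metrics(model, rng.standard_normal((6, 2)),
                               y[:6] + y.mean() - y[:6].mean() + rng.standard_normal(6),
                               y)
        # Q2_F1 = 1 - press/sum((y_ext - mean_tr)^2); with yhat == mean_tr
        assert out["Q2_F1"] == pytest.approx(0.0, abs=1e-10)

    def test_f1_geq_f2_on_random_inputs(self, rng):
        for _ in range(25):
            model, X, y = self.fit_toy(rng)
            X_ext = rng.standard_normal((8, 2))
            y_ext = rng.standard_normal(8)
            out = external_metrics(model, X_ext, y_ext, y)
            assert out["Q2_F1"] >= out["Q2_F2"] - 1e-12

    def test_empty_external_set(self, rng):
        model, X, y = self.fit_toy(rng)
        with pytest.raises(ValueError):
            external_metrics(model, np.empty((0, 2)), np.empty(0), y)


@settings(max_examples=50, derandomize=True)
@given(
    y_ext=arrays(float, 6, elements=st.floats(-5, 5)),
    shift=st.floats(-2, 2),
)
def test_q2f1_never_below_q2f2(y_ext, shift):
    """Theorem-level: the training-mean denominator can only be larger."""
    y_ext = np.asarray(y_ext)
    if np.ptp(y_ext) < 1e-3:
        return
    x = np.arange(12.0)[:, None]
    y_tr = x.ravel() * 0.3 + shift
    model = DescriptorMLR().fit(x, y_tr)
    out = external_metrics(model, np.linspace(0, 11, 6)[:, None], y_ext, y_tr)
    assert out["Q2_F1"] >= out["Q2_F2"] - 1e-12


class TestCCCAndR2m:
    def test_ccc_perfect_agreement(self):
        y = np.arange(8.0)
        assert ccc(y, y) == pytest.approx(1.0)

    def test_ccc_penalises_shift(self):
        y = np.arange(8.0)
        assert ccc(y, y + 2.0) < 1.0
        assert -1.0 <= ccc(y, -y) <= 1.0

    def test_r2m_identity(self):
        y = np.array([0.9, 1.2, 1.5, 1.7, 1.9, 2.0])
        avg, diff = r2m_metrics(y, y.copy())
        assert avg == pytest.approx(1.0)
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_r2m_shift_asymmetry(self):
        y = np.arange(1.0, 7.0)
        avg, diff = r2m_metrics(y, y + 0.8)
        assert diff > 0.0
        assert avg < 1.0

    def test_r2m_frozen_hand_oracle(self):
        # six-point vectors worked through the definition by hand
        y_obs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y_pred = [1.2, 1.8, 3.3, 3.9, 5.4, 5.7]
        avg, diff = r2m_metrics(y_obs, y_pred)
        assert avg == pytest.approx(0.9463161311003934, abs=1e-12)
        assert diff == pytest.approx(0.021779670711471688, abs=1e-12)

    def test_r2m_zero_variance(self):
        with pytest.raises(ValueError):
            r2m_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKCorrelation:
    def test_orthogonal_columns_zero(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        assert k_correlation(X) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_pair_one(self):
        x = np.arange(6.0)
        assert k_correlation(np.column_stack([x, 3 * x])) == pytest.approx(1.0)

    def test_three_columns_eigenvalue_oracle(self, rng):
        X = rng.standard_normal((50, 3))
        lam = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
        expected = np.sum(np.abs(lam / lam.sum() - 1 / 3)) / (2 * 2 / 3)
        assert k_correlation(X) == pytest.approx(expected, abs=1e-12)

    def test_bounded(self, rng):
        for _ in range(10):
            assert 0.0 <= k_correlation(rng.standard_normal((20, 4))) <= 1.0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            k_correlation(np.column_stack([np.ones(5), np.arange(5.0)]))


class TestYScramble:
    def test_null_mean_r2_near_p_over_n_minus_1(self, rng):
        X = rng.standard_normal((28, 3))
        y = rng.standard_normal(28)
        out = y_scramble(X, y, n_iter=500, seed=9)
        assert out["R2_scr_mean"] == pytest.approx(3 / 27, abs=0.03)

    def test_q2_below_r2(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        out = y_scramble(X, y, n_iter=200, seed=4)
        assert out["Q2_scr_mean"] < out["R2_scr_mean"]

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        assert y_scramble(X, y, 100, seed=7) == y_scramble(X, y, 100, seed=7)


class TestApplicabilityDomain:
    def test_warning_leverage_three_descriptor_28_compounds(self, rng):
        X = rng.standard_normal((28, 3))
        y = rng.standard_normal(28)
        model = DescriptorMLR().fit(X, y)
        wd = applicability_domain(model, X, y)
        assert round(wd.h_star, 3) == 0.429

    def test_training_leverages_sum_to_p_prime(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        model = DescriptorMLR().fit(X, y)
        wd = applicability_domain(model, X, y)
        assert wd.leverage.sum() == pytest.approx(4.0, abs=1e-8)

    def test_centroid_leverage_is_one_over_n(self, rng):
        X = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        model = DescriptorMLR().fit(X, y)
        wd = applicability_domain(model, X.mean(0, keepdims=True), y[:1])
        assert wd.leverage[0] == pytest.approx(1 / 25, abs=1e-10)

    def test_far_point_outside_domain(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        model = DescriptorMLR().fit(X, y)
        far = X.mean(0, keepdims=True) + 50.0
        wd = applicability_domain(model, far, np.array([0.0]), ids=["far"])
        assert wd.leverage[0] > wd.h_star
        assert wd.out_of_domain == ["far"]

    def test_outlier_flagging_uses_std_residual(self, rng):
        X = rng.standard_normal((20, 2))
        y = X @ [1.0, 1.0] + 0.05 * rng.standard_normal(20)
        model = DescriptorMLR().fit(X, y)
        y_bad = y.copy()
        y_bad[3] += 10 * model.s_
        wd = applicability_domain(model, X, y_bad, ids=list(range(20)))
        assert 3 in wd.outliers


class TestReportAssembly:
    def test_full_report_internally_consistent(self, rng):
        X = rng.standard_normal((24, 3))
        y = X @ [1.0, -1.0, 0.5] + 0.3 * rng.standard_normal(24)
        model = DescriptorMLR().fit(X[:18], y[:18])
        report = build_validation_report(
            model, X[:18], y[:18], X[18:], y[18:], n_scramble=100, seed=3
        )
        s = report.stats
        assert s["Q2_F1"] >= s["Q2_F2"]
        assert s["RMSE_tr"] >= s["MAE_tr"] >= 0
        assert s["RMSE_cv"] >= s["RMSE_tr"]
        assert -1 <= s["CCC_tr"] <= 1
        assert s["Q2_LOO"] <= s["R2"]
        assert s["delta_K"] == pytest.approx(s["Kxy"] - s["Kxx"], abs=1e-12)
        assert report.williams.h_star == pytest.approx(3 * 4 / 18)
        d = report.to_dict()
        assert set(d) == {"stats", "williams"}
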