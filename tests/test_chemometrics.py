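"""PLS calibration chain: standardization, NIPALS vs OLS/reference oracles,
cross-validation, range scan, detection limits, summaries."""

import numpy as np
import pandas as pd
import pytest

from mipsense import chemometrics as chem
from mipsense.colorimetry import FEATURE_COLUMNS

# Ten replicate determinations at a nominal 5 mg/L, used as the canonical
# repeatability example throughout the package.
REPEATABILITY_VALUES = [4.14, 4.51, 6.56, 4.44, 5.62, 5.01, 4.15, 5.36, 5.02, 4.89]


def make_table(X, y, columns=None):
    cols = columns or [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df["conc_mg_per_L"] = y
    return df, cols


def linear_table(rng, n=24, p=6, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return make_table(X, y)


class TestStandardize:
    def test_closed_form_column(self):
        df, cols = make_table(np.array([[1.0], [2.0], [3.0]]), [0, 1, 2])
        Xs, params = chem.standardize(df, cols)
        np.testing.assert_allclose(Xs[:, 0], [-1.0, 0.0, 1.0])

    def test_reapplying_params_is_idempotent(self, rng):
        df, cols = linear_table(rng)
        Xs, params = chem.standardize(df, cols)
        np.testing.assert_allclose(params.transform_x(df), Xs)

    def test_constant_column_dropped_and_recorded(self, rng):
        df, cols = linear_table(rng, p=3)
        df["x1"] = 7.0
        Xs, params = chem.standardize(df, cols)
        assert params.dropped == ["x1"]
        assert Xs.shape[1] == 2

    def test_all_constant_rejected(self):
        df, cols = make_table(np.ones((5, 2)), np.arange(5))
        with pytest.raises(ValueError, match="constant"):
            chem.standardize(df, cols)


class TestNipals:
    def test_exact_recovery_one_component(self, rng):
        # y carried entirely by one column of an orthogonal design
        X, _ = np.linalg.qr(rng.normal(size=(20, 5)))
        y = 2.5 * X[:, 0]
        model = chem.pls_fit(X, y, 1)
        np.testing.assert_allclose(X @ model.coef, y, atol=1e-12)

    def test_first_weight_proportional_to_xty(self, rng):
        df, cols = linear_table(rng)
        Xs, params = chem.standardize(df, cols)
        ys = params.transform_y(df["conc_mg_per_L"].to_numpy())
        model = chem.pls_fit(Xs, ys, 3, params)
        w0 = Xs.T @ ys
        w0 = w0 / np.linalg.norm(w0)
        np.testing.assert_allclose(model.weights[:, 0], w0, atol=1e-12)

    def test_full_rank_equals_ols(self, rng):
        df, cols = linear_table(rng, n=30, p=5, noise=0.5)
        Xs, params = chem.standardize(df, cols)
        ys = params.transform_y(df["conc_mg_per_L"].to_numpy())
        model = chem.pls_fit(Xs, ys, 5, params)
        beta_ols, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        np.testing.assert_allclose(Xs @ model.coef, Xs @ beta_ols, atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        df, cols = linear_table(rng, n=40, p=8, noise=1.0)
        Xs, params = chem.standardize(df, cols)
        ys = params.transform_y(df["conc_mg_per_L"].to_numpy())
        model = chem.pls_fit(Xs, ys, 5, params)
        T = model.scores
        for i in range(5):
            for j in range(i + 1, 5):
                bound = 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                assert abs(T[:, i] @ T[:, j]) <= bound

    def test_matches_reference_pls_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        df, cols = linear_table(rng, n=30, p=7, noise=0.8)
        Xs, params = chem.standardize(df, cols)
        ys = params.transform_y(df["conc_mg_per_L"].to_numpy())
        model = chem.pls_fit(Xs, ys, 3, params)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(Xs, ys)
        np.testing.assert_allclose(
            Xs @ model.coef, ref.predict(Xs).ravel(), atol=1e-8
        )

    def test_components_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X = np.hstack([X, X])  # rank 3
        with pytest.raises(ValueError, match="rank"):
            chem.pls_fit(X - X.mean(0), rng.normal(size=10), 4)

    def test_constant_y_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="variance"):
            chem.pls_fit(X, np.ones(10), 1)


class TestPredict:
    @pytest.fixture()
    def fitted(self, rng):
        df, cols = linear_table(rng, noise=0.3)
        Xs, params = chem.standardize(df, cols)
        ys = params.transform_y(df["conc_mg_per_L"].to_numpy())
        return df, cols, chem.pls_fit(Xs, ys, 3, params)

    def test_training_consistency(self, fitted):
        df, cols, model = fitted
        Xs = model.standardization.transform_x(df)
        direct = model.standardization.inverse_y(Xs @ model.coef)
        np.testing.assert_allclose(chem.pls_predict(model, df), direct)

    def test_centering_identity(self, fitted):
        df, cols, model = fitted
        mean_row = pd.DataFrame([df[cols].mean()], columns=cols)
        pred = chem.pls_predict(model, mean_row)[0]
        assert pred == pytest.approx(df["conc_mg_per_L"].mean(), abs=1e-10)

    def test_column_permutation_invariance(self, fitted):
        df, cols, model = fitted
        shuffled = df[list(reversed(cols))]
        np.testing.assert_allclose(
            chem.pls_predict(model, shuffled), chem.pls_predict(model, df)
        )

    def test_serialization_round_trip(self, fitted, tmp_path):
        df, cols, model = fitted
        model.to_json(tmp_path / "m.json")
        loaded = chem.PLSModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(
            chem.pls_predict(loaded, df), chem.pls_predict(model, df)
        )

    def test_newer_schema_rejected(self, fitted, tmp_path):
        import json

        df, cols, model = fitted
        model.to_json(tmp_path / "m.json")
        payload = json.loads((tmp_path / "m.json").read_text())
        payload["schema_version"] = "99.0"
        (tmp_path / "m.json").write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="newer"):
            chem.PLSModel.from_json(tmp_path / "m.json")


class TestCrossValidation:
    def test_noise_free_linear_rmsecv_zero(self, rng):
        df, cols = linear_table(rng, n=20, p=4, noise=0.0)
        cv = chem.cross_validate(df, n_components=4, feature_columns=cols)
        assert cv.rmsecv <= 1e-8

    def test_fold_accounting(self, rng):
        df, cols = linear_table(rng, n=15, noise=0.2)
        cv = chem.cross_validate(df, 3, cols)
        assert cv.predicted.shape == (15,)
        assert np.isfinite(cv.predicted).all()

    def test_rmsecv_at_least_rmsec_typically(self, rng):
        wins = 0
        for seed in range(8):
            r = np.random.default_rng(seed)
            df, cols = linear_table(r, n=18, p=6, noise=1.0)
            Xs, params = chem.standardize(df, cols)
            ys = params.transform_y(df["conc_mg_per_L"].to_numpy())
            model = chem.pls_fit(Xs, ys, 4, params)
            fitted = chem.pls_predict(model, df)
            rmsec = np.sqrt(np.mean((fitted - df["conc_mg_per_L"]) ** 2))
            cv = chem.cross_validate(df, 4, cols)
            wins += cv.rmsecv >= rmsec
        assert wins >= 7

    def test_too_few_samples_rejected(self, rng):
        df, cols = linear_table(rng, n=5, p=4)
        with pytest.raises(ValueError, match="samples"):
            chem.cross_validate(df, 4, cols)


class TestCalibrationMetrics:
    def test_identity_line(self):
        m = chem.calibration_metrics([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert (m.r2, m.slope, m.rmse) == pytest.approx((1.0, 1.0, 0.0))

    def test_constant_offset(self):
        m = chem.calibration_metrics([1, 2, 3.0], [2, 3, 4.0])
        assert (m.slope, m.intercept, m.rmse) == pytest.approx((1.0, 1.0, 1.0))

    def test_hand_computed_regression(self):
        measured = np.array([0.0, 1.0, 2.0, 3.0])
        predicted = np.array([0.1, 0.9, 2.2, 2.8])
        # by hand: Sxy = 4.7, Sxx = 5.0, means both 1.5
        m = chem.calibration_metrics(measured, predicted)
        assert m.slope == pytest.approx(4.7 / 5.0)
        assert m.intercept == pytest.approx(1.5 - 0.94 * 1.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            chem.calibration_metrics([1.0, 1.0, 1.0], [1, 2, 3.0])


class TestWorkingRangeAndLimits:
    def test_single_candidate_returned(self, calibration_table):
        scan = chem.select_working_range(calibration_table, 4, [20.0])
        assert scan.chosen_upper == 20.0

    def test_all_candidates_reported(self, calibration_table):
        scan = chem.select_working_range(calibration_table, 4, [7.0, 20.0])
        assert list(scan.metrics["upper"]) == [7.0, 20.0]
        assert scan.metrics["feasible"].all()

    def test_saturating_data_prefers_truncated_range(self, calibration_table):
        scan = chem.select_working_range(calibration_table, 4)
        assert scan.chosen_upper < 20.0

    def test_infeasible_candidates_flagged_not_dropped(self, calibration_table):
        scan = chem.select_working_range(calibration_table, 4, [0.5, 20.0])
        assert not scan.metrics.iloc[0]["feasible"]
        assert scan.chosen_upper == 20.0

    def test_no_feasible_candidate_rejected(self, calibration_table):
        with pytest.raises(ValueError, match="no candidate"):
            chem.select_working_range(calibration_table, 4, [0.1])

    def test_lod_loq_arithmetic(self):
        residuals = np.array([0.09, -0.09, 0.09, -0.09])  # sd ~ 0.1039
        s = np.std(residuals, ddof=1)
        lim = chem.lod_loq(residuals, slope=1.0, lowest_nonzero_standard=None)
        assert lim.lod == pytest.approx(3.3 * s)
        assert lim.loq / lim.lod == pytest.approx(10 / 3.3)

    def test_loq_floored_at_lowest_standard(self):
        lim = chem.lod_loq(np.array([0.05, -0.05, 0.03, -0.03]), 1.0, 1.0)
        assert lim.floored and lim.loq == 1.0
        assert lim.loq_unfloored < 1.0
        assert lim.lod < lim.loq

    def test_degenerate_zero_residuals(self):
        lim = chem.lod_loq(np.zeros(5), 1.0)
        assert lim.degenerate and lim.lod == 0.0 and lim.loq == 0.0

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            chem.lod_loq(np.array([0.1, -0.1, 0.2]), 0.0)


class TestBiplot:
    def test_correlation_signs_on_fixture(self, calibration_table):
        corr = chem.pca_biplot(calibration_table).correlations
        assert corr["H"] > 0 and corr["S"] > 0 and corr["Y"] > 0
        assert corr["V"] < 0 and corr["R"] < 0 and corr["G"] < 0

    def test_duplicated_rows_leave_loadings_unchanged(self, calibration_table):
        once = chem.pca_biplot(calibration_table)
        doubled = chem.pca_biplot(
            pd.concat([calibration_table, calibration_table], ignore_index=True)
        )
        np.testing.assert_allclose(doubled.loadings, once.loadings, atol=1e-8)

    def test_rank_two_reconstruction(self, rng):
        # standardized X of true rank 2: two components reproduce it
        t = rng.normal(size=(30, 2))
        load = rng.normal(size=(2, 4))
        X = t @ load
        df = pd.DataFrame(X, columns=list("abcd"))
        df["conc_mg_per_L"] = X[:, 0] + 0.5 * X[:, 1]
        res = chem.pca_biplot(df)
        Xs, _ = chem.standardize(df, list("abcd"))
        np.testing.assert_allclose(res.scores @ res.loadings.T, Xs, atol=1e-8)


class TestSummaries:
    def test_repeatability_reproduces_printed_statistics(self):
        s = chem.repeatability_summary(REPEATABILITY_VALUES, nominal=5.0)
        assert round(s.mean, 2) == 4.97
        assert round(s.sd, 2) == 0.74
        assert round(s.rsd_percent, 1) == 14.9
        assert round(s.accuracy_percent, 1) == 99.4

    def test_constant_values(self):
        s = chem.repeatability_summary([5.0, 5.0, 5.0], nominal=5.0)
        assert s.sd == 0.0 and s.rsd_percent == 0.0 and s.accuracy_percent == 100.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="2 replicate"):
            chem.repeatability_summary([5.0], 5.0)

    def test_standard_addition_constructed_inverse(self):
        added = np.array([0.0, 5.0, 10.0, 15.0])
        responses = 0.02 * (13.6 + added)  # a/b = 13.6
        assert chem.standard_addition_estimate(added, responses) == pytest.approx(13.6)

    def test_standard_addition_scale_invariant(self):
        added = np.array([0.0, 2.0, 4.0])
        resp = 1.0 + 0.5 * added
        est1 = chem.standard_addition_estimate(added, resp)
        est2 = chem.standard_addition_estimate(added, 2 * resp)
        assert est1 == pytest.approx(est2) == pytest.approx(2.0)

    def test_standard_addition_zero_intercept(self):
        added = np.array([0.0, 1.0, 2.0])
        assert chem.standard_addition_estimate(added, 3.0 * added) == pytest.approx(0.0)

    def test_standard_addition_needs_zero_level_and_positive_slope(self):
        with pytest.raises(ValueError, match="zero"):
            chem.standard_addition_estimate([1.0, 2.0, 3.0], [1, 2, 3.0])
        with pytest.raises(ValueError, match="slope"):
            chem.standard_addition_estimate([0.0, 1.0, 2.0], [3, 2, 1.0])
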