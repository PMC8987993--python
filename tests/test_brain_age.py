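"""Cascade network and brain-age model: capacity, determinism, CV contracts."""

import numpy as np
import pandas as pd
import pytest

from padkit.brain_age import BrainAgeModel, cross_validate, evaluate_predictions
from padkit.cascade import CascadeForwardRegressor

from conftest import FAST_NET


def _linear_panel(n, d, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = X @ w + 50 + noise * rng.standard_normal(n)
    return X, y


class TestCascadeForwardRegressor:
    def test_represents_linear_map_exactly(self):
        """The input-to-output skip connection must capture a pure linear rule."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 124))
        w = rng.normal(size=124)
        y = X @ w + 50
        model = CascadeForwardRegressor(alpha=1e-6, random_state=0).fit(X, y)
        Xt = rng.normal(size=(200, 124))
        yt = Xt @ w + 50
        assert np.mean(np.abs(model.predict(Xt) - yt)) < 0.5

    def test_training_is_deterministic(self):
        X, y = _linear_panel(60, 10, seed=4, noise=1.0)
        a = CascadeForwardRegressor(n_layers=3, width=4, max_iter=60, random_state=5).fit(X, y)
        b = CascadeForwardRegressor(n_layers=3, width=4, max_iter=60, random_state=5).fit(X, y)
        for Wa, Wb in zip(a.coefs_, b.coefs_):
            np.testing.assert_array_equal(Wa, Wb)
        np.testing.assert_array_equal(a.output_coef_, b.output_coef_)

    def test_constant_network_predicts_bias(self):
        X, y = _linear_panel(30, 5, seed=6, noise=1.0)
        model = CascadeForwardRegressor(n_layers=2, width=3, max_iter=5).fit(X, y)
        model.coefs_ = [np.zeros_like(W) for W in model.coefs_]
        model.intercepts_ = [np.zeros_like(b) for b in model.intercepts_]
        model.output_coef_ = np.zeros_like(model.output_coef_)
        model.output_intercept_ = 1.5
        expected = 1.5 * model.y_scale_ + model.y_mean_
        np.testing.assert_allclose(model.predict(X), expected)

    def test_affine_input_rescaling_is_absorbed(self):
        """Standardization makes predictions invariant to per-feature affine maps."""
        X, y = _linear_panel(80, 6, seed=7, noise=0.5)
        scale = np.array([2.0, 0.1, 5.0, 1.0, 10.0, 0.5])
        shift = np.array([1.0, -3.0, 0.0, 2.0, -1.0, 4.0])
        a = CascadeForwardRegressor(n_layers=3, width=4, max_iter=100, random_state=8).fit(X, y)
        b = CascadeForwardRegressor(n_layers=3, width=4, max_iter=100, random_state=8).fit(
            X * scale + shift, y
        )
        np.testing.assert_allclose(a.predict(X), b.predict(X * scale + shift), atol=1e-8)

    def test_duplicated_rows_give_identical_predictions(self):
        X, y = _linear_panel(40, 5, seed=9, noise=0.5)
        model = CascadeForwardRegressor(n_layers=2, width=3, max_iter=40).fit(X, y)
        doubled = np.vstack([X[:3], X[:3]])
        pred = model.predict(doubled)
        np.testing.assert_array_equal(pred[:3], pred[3:])

    def test_rejects_non_finite(self):
        X, y = _linear_panel(20, 4, seed=10)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            CascadeForwardRegressor().fit(X, y)


class TestEvaluatePredictions:
    def test_perfect_and_shifted(self):
        ages = np.array([50.0, 60.0, 70.0])
        r0, mae0 = evaluate_predictions(ages, ages)
        assert r0 == pytest.approx(1.0)
        assert mae0 == 0.0
        r, mae = evaluate_predictions(ages + 2, ages)
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # predicted (3,1,2) vs chronological (1,2,3):
        # cov = -0.5, sds = 1 -> r = -0.5; MAE = (2+1+1)/3
        r, mae = evaluate_predictions([3.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(-0.5)
        assert mae == pytest.approx(4.0 / 3.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            evaluate_predictions([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_predictions([1.0, 2.0], [5.0, 5.0])


class TestBrainAgeModel:
    def test_panel_contract(self, traj, train_cohort):
        with pytest.raises(ValueError, match="expects 90 features"):
            BrainAgeModel(modality="WM").fit(
                train_cohort.tables["GM"], train_cohort.ages, train_cohort.sex_codes
            )

    def test_feature_mismatch_named(self, gm_model, train_cohort):
        frame = train_cohort.tables["GM"].values.drop(columns=["Vol L Cuneus"])
        with pytest.raises(ValueError, match="Vol L Cuneus"):
            gm_model.predict(frame, train_cohort.sex_codes)

    def test_column_order_is_restored(self, gm_model, train_cohort):
        frame = train_cohort.tables["GM"].values
        shuffled = frame[list(frame.columns[::-1])]
        np.testing.assert_allclose(
            gm_model.predict(frame, train_cohort.sex_codes),
            gm_model.predict(shuffled, train_cohort.sex_codes),
        )

    def test_holdout_accuracy_on_session_model(self, traj, gm_model):
        from padkit.simulate import generate_normative_population

        hold = generate_normative_population(300, traj, seed=33, id_prefix="t")
        pred = gm_model.predict(hold.tables["GM"], hold.sex_codes)
        r, mae = evaluate_predictions(pred, hold.ages)
        assert mae < 2.0
        assert r > 0.98

    def test_json_roundtrip_preserves_predictions(self, tmp_path, gm_model, hc_cohort):
        path = tmp_path / "model.json"
        gm_model.save(path)
        loaded = BrainAgeModel.load(path)
        np.testing.assert_allclose(
            loaded.predict(hc_cohort.tables["GM"], hc_cohort.sex_codes),
            gm_model.predict(hc_cohort.tables["GM"], hc_cohort.sex_codes),
        )
        assert loaded.feature_names_ == gm_model.feature_names_
        assert loaded.modality == "GM"


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def small_gm(self, traj):
        from padkit.simulate import generate_normative_population

        return generate_normative_population(100, traj, seed=55)

    def test_folds_partition_sample(self, small_gm):
        report = cross_validate(
            small_gm.tables["GM"], small_gm.ages, small_gm.sex_codes,
            k=10, seed=1, **FAST_NET,
        )
        sizes = np.bincount(report.fold_assignments)
        assert sizes.tolist() == [10] * 10
        assert report.pooled_mae >= 0
        assert -1 <= report.pooled_r <= 1

    def test_perfect_predictor_when_age_is_a_feature(self, traj):
        """Noiseless features are exact functions of age, so out-of-fold
        prediction is near-perfect."""
        from padkit.simulate import generate_normative_population

        cohort = generate_normative_population(60, traj.with_sigma(0.0), seed=56)
        report = cross_validate(
            cohort.tables["GM"], cohort.ages, cohort.sex_codes,
            k=5, seed=2, **FAST_NET,
        )
        assert report.pooled_r > 0.999
        assert report.pooled_mae < 0.5

    def test_leave_one_out_boundary(self, traj):
        from padkit.simulate import generate_normative_population

        cohort = generate_normative_population(12, traj, seed=57)
        report = cross_validate(
            cohort.tables["GM"], cohort.ages, cohort.sex_codes,
            k=12, seed=3, n_layers=2, width=3, max_iter=30,
        )
        assert report.k == 12
        assert len(np.unique(report.fold_assignments)) == 12

    def test_k_larger_than_n_fails(self, traj):
        from padkit.simulate import generate_normative_population

        cohort = generate_normative_population(5, traj, seed=58)
        with pytest.raises(ValueError, match="k <= n"):
            cross_validate(cohort.tables["GM"], cohort.ages, cohort.sex_codes, k=10)
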