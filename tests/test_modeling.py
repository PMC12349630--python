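"""Stacked ensemble machinery: scaling, MI selection, tuning, stacking, CV."""

import numpy as np
import pandas as pd
import pytest

from pulsebp.embedder import EmbedderConfig
from pulsebp.features import BASE_COLUMNS, CONTINUOUS_BASE
from pulsebp.modeling import (
    BaseSearchSpace,
    ContractError,
    CVConfig,
    MetaConfig,
    PipelineConfig,
    StackedEnsemble,
    _binned_mi,
    cross_validate,
    mi_select,
    robust_scale,
    tune_fit_base,
)

FAST = PipelineConfig(
    k_keep=12,
    embedder=EmbedderConfig(embed_dim=16, depth=1, heads=2, dropout=0.1,
                            epochs=15),
    base_space=BaseSearchSpace(n_trials=1),
    seed=0,
)


def _toy_dataset(n=60, seed=0, noise=1.0):
    """Feature table in the training column order with a linear BP map."""
    rng = np.random.default_rng(seed)
    rows = {}
    s = rng.uniform(0, 1, n)
    for i in range(n):
        rows[f"S{i:03d}"] = {
            "ascending_time": 0.2 - 0.07 * s[i] + rng.normal(0, 0.004),
            "descending_time": 0.6 + 0.02 * s[i] + rng.normal(0, 0.004),
            "pulse_width": 0.3 - 0.05 * s[i] + rng.normal(0, 0.004),
            "pulse_rate": 75 + rng.normal(0, 2),
            "pulse_intensity_rate": 1.2 + 0.2 * s[i] + rng.normal(0, 0.02),
            "ascending_slope": 5 + 2 * s[i] + rng.normal(0, 0.1),
            "descending_slope": -2.5 - s[i] + rng.normal(0, 0.1),
            "ascending_area": 0.1 + rng.normal(0, 0.002),
            "descending_area": 0.2 - 0.05 * s[i] + rng.normal(0, 0.002),
            "ascending_intensity_diff": 1.0 + rng.normal(0, 0.02),
            "descending_intensity_diff": 0.9 + rng.normal(0, 0.02),
            "age": rng.uniform(20, 80),
            "gender": float(rng.integers(0, 2)),
            "height_cm": rng.normal(170, 8),
            "weight_kg": rng.normal(72, 10),
            "bmi": rng.normal(25, 3),
        }
    X = pd.DataFrame.from_dict(rows, orient="index")[BASE_COLUMNS]
    X.index.name = "subject_id"
    y = pd.DataFrame(
        {
            "sbp": 80 + 70 * s + rng.normal(0, noise, n),
            "dbp": 45 + 40 * s + rng.normal(0, noise, n),
        },
        index=X.index,
    )
    return X, y, s


class TestRobustScale:
    def test_five_point_column(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "gender": [0.0] * 5})
        scaled, params = robust_scale(df)
        np.testing.assert_allclose(scaled["x"], [-1, -0.5, 0, 0.5, 1])
        assert params.median[0] == 3 and params.iqr[0] == 2

    def test_constant_column_centered_only(self):
        df = pd.DataFrame({"x": [4.0] * 6, "gender": [0.0] * 6})
        scaled, _ = robust_scale(df)
        np.testing.assert_allclose(scaled["x"], 0.0)

    def test_transform_with_saved_params_matches_manual(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"x": rng.normal(10, 3, 50),
                              "gender": np.zeros(50)})
        _, params = robust_scale(train)
        new = pd.DataFrame({"x": rng.normal(10, 3, 20),
                            "gender": np.ones(20)})
        scaled, _ = robust_scale(new, params)
        manual = (new["x"] - params.median[0]) / params.iqr[0]
        np.testing.assert_allclose(scaled["x"], manual)
        np.testing.assert_allclose(scaled["gender"], 1.0)  # untouched

    def test_column_mismatch_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2], "gender": [0.0, 1]})
        _, params = robust_scale(df)
        with pytest.raises(ContractError):
            robust_scale(df.rename(columns={"x": "y"}), params)


class TestMiSelect:
    def test_identical_feature_ranked_first(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 1000)
        df = pd.DataFrame(
            {"noise1": rng.normal(size=1000), "signal": y,
             "noise2": rng.normal(size=1000)}
        )
        assert mi_select(df, np.column_stack([y, y]), 1) == ["signal"]

    def test_keep_all_is_identity_in_original_order(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 4)),
                          columns=list("abcd"))
        y = rng.normal(size=(100, 2))
        assert mi_select(df, y, 4) == list("abcd")

    def test_independent_feature_scores_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = rng.normal(size=n)
        indep = rng.normal(size=n)
        corr = y + rng.normal(0, 0.5, n)
        # brute-force MI on the binned contingency table is the estimator
        # itself; check bias bound and ordering
        assert _binned_mi(indep, y) < 0.06  # estimator bias at 8x8, n=2000
        assert _binned_mi(corr, y) > 5 * _binned_mi(indep, y)

    def test_k_out_of_range_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            mi_select(df, np.zeros((3, 2)), 5)


class TestTuneFitBase:
    @pytest.mark.parametrize("variant", ["xgboost", "lightgbm", "gbdt"])
    def test_fits_identity_signal(self, variant):
        rng = np.random.default_rng(4)
        # n large enough that default leaf-size floors don't limit precision
        X = rng.uniform(0, 1, (400, 3))
        y = X[:, 0]
        model, params, _ = tune_fit_base(
            X, y, BaseSearchSpace(n_trials=2), variant, seed=0
        )
        mae = np.mean(np.abs(model.predict(X) - y))
        assert mae < 0.01 * (y.max() - y.min())
        assert 300 <= params["n_estimators"] <= 1000
        assert 0.01 <= params["learn_rate"] <= 0.1
        assert 3 <= params["max_depth"] <= 10

    def test_single_trial_returns_that_configuration(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        _, p1, _ = tune_fit_base(X, y, BaseSearchSpace(n_trials=1), "gbdt",
                                 seed=7)
        _, p2, _ = tune_fit_base(X, y, BaseSearchSpace(n_trials=1), "gbdt",
                                 seed=7)
        assert p1 == p2

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            tune_fit_base(np.zeros((5, 2)), np.zeros(5),
                          BaseSearchSpace(n_trials=1), "gbdt")


@pytest.fixture(scope="module")
def fitted_ensemble():
    X, y, _ = _toy_dataset()
    return X, y, StackedEnsemble(FAST).fit(X, y)


class TestStackedEnsemble:
    def test_manifest_echoes_stated_configuration(self, fitted_ensemble):
        _, _, ens = fitted_ensemble
        m = ens.manifest()
        assert m["base_search_space"]["n_estimators"] == [300, 1000]
        assert m["base_search_space"]["learn_rate"] == [0.01, 0.1]
        assert m["base_search_space"]["max_depth"] == [3, 10]
        assert m["meta"] == {"n_estimators": 200, "learn_rate": 0.05,
                             "max_depth": 4}
        assert m["cv"] == {"k": 5, "shuffle": True, "seed": 42}
        assert m["column_order"] == BASE_COLUMNS

    def test_predicts_training_rows_within_envelope(self, fitted_ensemble):
        X, y, ens = fitted_ensemble
        pred = ens.predict(X)
        assert np.all(np.isfinite(pred))
        for t in ("sbp", "dbp"):
            lo, hi = y[t].min() - 20, y[t].max() + 20
            assert pred[t].between(lo, hi).all()

    def test_duplicated_row_identical_output(self, fitted_ensemble):
        X, _, ens = fitted_ensemble
        two = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        pred = ens.predict(two)
        assert pred.iloc[0].equals(pred.iloc[1])

    def test_row_permutation_permutes_predictions(self, fitted_ensemble):
        X, _, ens = fitted_ensemble
        perm = X.iloc[::-1]
        a = ens.predict(X)
        b = ens.predict(perm)
        np.testing.assert_allclose(a.loc[X.index[::-1]], b, rtol=1e-12)

    def test_column_order_contract_enforced(self, fitted_ensemble):
        X, _, ens = fitted_ensemble
        with pytest.raises(ContractError):
            ens.predict(X[list(reversed(BASE_COLUMNS))])

    def test_nonfinite_row_rejected_with_nan(self, fitted_ensemble):
        X, _, ens = fitted_ensemble
        bad = X.copy()
        bad.iloc[0, 0] = np.inf
        with pytest.warns(UserWarning, match="non-finite"):
            pred = ens.predict(bad)
        assert pred.iloc[0].isna().all()
        assert np.isfinite(pred.iloc[1:]).all().all()


class TestCrossValidate:
    def test_folds_partition_subjects(self):
        X, y, _ = _toy_dataset(n=10)
        res = cross_validate(X, y, FAST)
        folds = res.predictions["fold"]
        assert sorted(folds.value_counts()) == [2, 2, 2, 2, 2]
        assert set(res.predictions.index) == set(X.index)

    def test_reproducible_given_seed(self):
        X, y, _ = _toy_dataset(n=25)
        a = cross_validate(X, y, FAST)
        b = cross_validate(X, y, FAST)
        assert abs(a.pooled["sbp"].mae - b.pooled["sbp"].mae) < 1e-6
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_recovers_linear_map(self):
        X, y, _ = _toy_dataset(n=60, noise=1.0)
        res = cross_validate(X, y, FAST)
        assert res.pooled["sbp"].r2 > 0.7
        # regression of predicted on true: slope near 1
        slope = np.polyfit(res.predictions["sbp_true"],
                           res.predictions["sbp_pred"], 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_scaler_fitted_on_training_folds_only(self):
        X, y, _ = _toy_dataset(n=30)
        from sklearn.model_selection import KFold

        kf = KFold(5, shuffle=True, random_state=42)
        tr, va = next(kf.split(X))
        ens = StackedEnsemble(FAST).fit(X.iloc[tr], y.iloc[tr])
        from pulsebp.features import engineer_features

        cont = [c for c in engineer_features(X.iloc[tr]).columns
                if c != "gender"]
        train_medians = engineer_features(X.iloc[tr])[cont].median()
        np.testing.assert_allclose(ens.scaler_.median,
                                   train_medians.to_numpy())

    def test_duplicate_subject_rejected(self):
        X, y, _ = _toy_dataset(n=10)
        X2 = pd.concat([X, X.iloc[[0]]])
        y2 = pd.concat([y, y.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate subject"):
            cross_validate(X2, y2, FAST)
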