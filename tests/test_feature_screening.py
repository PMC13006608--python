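"""Rebalancing, importance screening, candidate-set algebra and TreeSHAP
summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from hypothesis import given, settings
from hypothesis import strategies as st

from traumaprog import feature_screening as fs
from traumaprog import synthetic_cohort as sc
from traumaprog.pipeline import encode_features

RF_SET = fs.REFERENCE_RF_FEATURES
XGB_SET = fs.REFERENCE_XGB_FEATURES


@pytest.fixture(scope="module")
def binary_data(demo_frame):
    df = demo_frame
    cols = ["albumin", "hemoglobin", "heart_rate", "creatinine", "ast",
            "prealbumin", "ada", "cholinesterase"]
    X = encode_features(df[cols]).fillna(df[cols].median(numeric_only=True))
    y = sc.dichotomize_outcome(df["outcome"])
    return X, y


class TestSmote:
    def test_balances_classes(self, binary_data):
        X, y = binary_data
        Xr, yr = fs.smote_oversample(X.to_numpy(float), y, seed=0)
        counts = np.bincount(yr)
        assert counts[0] == counts[1]

    def test_synthetic_points_on_minority_segments(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(4, 1, (12, 2))])
        y = np.array([0] * 40 + [1] * 12)
        Xr, yr = fs.smote_oversample(X, y, k=5, seed=1)
        X_min = X[y == 1]
        for p in Xr[len(X):]:
            # point must be a convex combination of two minority originals
            on_segment = False
            for i in range(len(X_min)):
                for j in range(len(X_min)):
                    if i == j:
                        continue
                    d = X_min[j] - X_min[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    t = (p - X_min[i]) @ d / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(
                        X_min[i] + t * d, p, atol=1e-8
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_minority_smaller_than_k_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError):
            fs.smote_oversample(X, y, k=5)


class TestEnn:
    def test_deletes_rows_never_edits_values(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1, 1, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        Xc, yc, kept = fs.enn_clean(X, y)
        np.testing.assert_array_equal(Xc, X[kept])
        np.testing.assert_array_equal(yc, y[kept])

    def test_removes_label_noise(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        y_noisy = y.copy()
        y_noisy[0] = 1  # a class-1 label deep inside class-0 territory
        _, _, kept = fs.enn_clean(X, y_noisy)
        assert 0 not in kept


class TestRebalance:
    def test_none_is_identity(self, binary_data):
        X, y = binary_data
        Xr, yr, res = fs.rebalance(X.to_numpy(float), y, method="none")
        assert res.ratio_after == res.ratio_before
        np.testing.assert_array_equal(yr, y)

    def test_smote_enn_improves_study_shaped_imbalance(self, binary_data):
        X, y = binary_data
        assert round(res_ratio := (y == 0).sum() / y.sum(), 1) == 4.4
        for seed in range(10):
            _, yr, res = fs.rebalance(X.to_numpy(float), y,
                                      method="smote_enn", seed=seed)
            assert res.ratio_after < 4.0  # minority no longer ~1:4.4
            assert all(c > 0 for c in res.counts_after.values())

    def test_majority_rows_unedited_by_smote_enn(self, binary_data):
        X, y = binary_data
        Xv = X.to_numpy(float)
        Xr, yr, _ = fs.rebalance(Xv, y, method="smote_enn", seed=3)
        # every surviving majority-class row is an original row
        original = {tuple(row) for row in Xv[y == 0]}
        for row in Xr[yr == 0]:
            assert tuple(row) in original

    def test_unknown_method_rejected(self, binary_data):
        X, y = binary_data
        with pytest.raises(ValueError):
            fs.rebalance(X.to_numpy(float), y, method="bogus")


class TestImportanceScreen:
    def test_perfect_feature_always_retained(self):
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n = 300
            y = rng.integers(0, 2, n)
            X = pd.DataFrame(rng.normal(size=(n, 6)),
                             columns=[f"noise{i}" for i in range(6)])
            X["signal"] = y + rng.normal(0, 0.05, n)
            screen = fs.importance_screen(X, y, seed=seed, n_estimators=100)
            assert "signal" in screen.retained["rf"]
            assert "signal" in screen.retained["xgb"]

    def test_importances_normalized(self, binary_data):
        X, y = binary_data
        screen = fs.importance_screen(X, y, seed=0, n_estimators=100)
        for algo in ("rf", "xgb"):
            assert screen.importances[algo].sum() == pytest.approx(1.0,
                                                                   abs=1e-9)

    def test_zero_threshold_retains_everything(self, binary_data):
        X, y = binary_data
        screen = fs.importance_screen(X, y, threshold=0.0, seed=0,
                                      n_estimators=50)
        assert set(screen.retained["rf"]) == set(X.columns)

    def test_single_class_rejected(self, binary_data):
        X, _ = binary_data
        with pytest.raises(ValueError):
            fs.importance_screen(X, np.zeros(len(X), dtype=int))

    def test_screening_stable_across_seeds(self, binary_data):
        # retained sets should overlap substantially across resampling and
        # model seeds (Jaccard >= 0.5 pairwise against the first run)
        X, y = binary_data
        sets = []
        for seed in range(10):
            Xr, yr, _ = fs.rebalance(X.to_numpy(float), y,
                                     method="smote_enn", seed=seed)
            screen = fs.importance_screen(
                pd.DataFrame(Xr, columns=X.columns), yr, seed=seed,
                n_estimators=100,
            )
            sets.append(set(screen.retained["rf"]) | set(screen.retained["xgb"]))
        ref = sets[0]
        for other in sets[1:]:
            jaccard = len(ref & other) / len(ref | other)
            assert jaccard >= 0.5


class TestCandidateSets:
    def test_reference_lists_union_eleven_intersection_seven(self):
        sets = fs.build_candidate_sets(RF_SET, XGB_SET)
        assert len(sets.union) == 11
        assert len(sets.intersection) == 7

    def test_identical_sets_collapse(self):
        sets = fs.build_candidate_sets(["a", "b"], ["a", "b"])
        assert sets.union == sets.intersection == ["a", "b"]

    @given(
        st.sets(st.sampled_from(list("abcdefghij"))),
        st.sets(st.sampled_from(list("abcdefghij"))),
    )
    @settings(max_examples=100, deadline=None)
    def test_inclusion_exclusion_identity(self, d1, d2):
        sets = fs.build_candidate_sets(sorted(d1), sorted(d2))
        assert len(sets.union) + len(sets.intersection) == len(d1) + len(d2)
        assert set(sets.intersection) <= set(sets.d1) <= set(sets.union)


class TestEvaluateCandidateSets:
    def test_perfect_feature_gives_unit_test_auc(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({
            "perfect": y.astype(float),
            "noise": rng.normal(size=n),
        })
        sets = fs.build_candidate_sets(["perfect"], ["perfect", "noise"])
        table = fs.evaluate_candidate_sets(sets, X, y, seed=0)
        assert (table.loc[table.set == "D1", "test_auc"] == 1.0).all()

    def test_deterministic_under_fixed_seed(self, binary_data):
        X, y = binary_data
        sets = fs.build_candidate_sets(list(X.columns[:4]), list(X.columns[2:6]))
        a = fs.evaluate_candidate_sets(sets, X, y, seed=5)
        b = fs.evaluate_candidate_sets(sets, X, y, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_set_skipped_with_warning(self, binary_data):
        X, y = binary_data
        sets = fs.build_candidate_sets([], list(X.columns[:3]))
        with pytest.warns(UserWarning, match="empty"):
            table = fs.evaluate_candidate_sets(sets, X, y, seed=0)
        assert "D1" not in set(table["set"])


class TestEpvGuard:
    def test_warns_when_violated(self):
        with pytest.warns(UserWarning, match="EPV"):
            assert not fs.check_epv(n_features=10, n_events=54)

    def test_silent_when_satisfied(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert fs.check_epv(n_features=5, n_events=54)


class TestShapSummary:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(9)
        n = 400
        risk = rng.normal(size=n)
        protective = rng.normal(size=n)
        inert = rng.normal(size=n)
        logit = 1.5 * risk - 1.5 * protective
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        X = pd.DataFrame({"risk": risk, "protective": protective,
                          "inert": inert})
        model = xgb.XGBClassifier(n_estimators=100, max_depth=3,
                                  random_state=0, verbosity=0,
                                  eval_metric="logloss").fit(X, y)
        return model, X

    def test_additivity_reconstructs_margin(self, fitted):
        model, X = fitted
        summary = fs.shap_summary(model, X)
        margin = model.get_booster().predict(xgb.DMatrix(X),
                                             output_margin=True)
        contrib = model.get_booster().predict(xgb.DMatrix(X),
                                              pred_contribs=True)
        np.testing.assert_allclose(contrib.sum(axis=1), margin, atol=1e-5)
        assert summary.values.shape == X.shape

    def test_directions_recovered(self, fitted):
        model, X = fitted
        table = fs.shap_summary(model, X).table
        assert table.loc["risk", "direction"] == "risk"
        assert table.loc["protective", "direction"] == "protective"
        assert table.loc["inert", "mean_abs_shap"] < table.loc[
            "risk", "mean_abs_shap"]

    def test_protective_generator_effect_negative_mean_shap(self):
        # albumin is generated lower in the poor-prognosis class, so its
        # attribution for the poor class should be negative at high values
        signs = []
        for seed in range(10):
            spec = sc.CohortSpec(n_cure=60, n_improved=70, n_poor=40,
                                 missing_rate=0.0, seed=300 + seed)
            df = sc.cohort_to_frame(sc.generate_cohort(spec))
            X = df[["albumin", "heart_rate"]]
            y = sc.dichotomize_outcome(df["outcome"])
            model = xgb.XGBClassifier(n_estimators=60, max_depth=3,
                                      random_state=0, verbosity=0,
                                      eval_metric="logloss").fit(X, y)
            values = fs.shap_summary(model, X).values
            high_albumin = X["albumin"] > X["albumin"].median()
            signs.append(values[high_albumin.to_numpy(), 0].mean() < 0)
        assert sum(signs) >= 8

    def test_unsupported_backend_rejected(self, binary_data):
        from sklearn.linear_model import LogisticRegression

        X, y = binary_data
        model = LogisticRegression().fit(X, y)
        with pytest.raises(TypeError, match="attribution backend"):
            fs.shap_summary(model, X)
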