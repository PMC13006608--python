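"""Metric panels, stepwise logistic regression, nomogram and benchmark
harness."""

import logging

import numpy as np
import pandas as pd
import pytest

from traumaprog import prognostic_models as pm


def _logistic_data(n, coefs, noise_vars, seed):
    """Binary outcome from a known logistic model plus inert covariates."""
    rng = np.random.default_rng(seed)
    p = len(coefs)
    X = rng.normal(size=(n, p + noise_vars))
    logit = X[:, :p] @ np.asarray(coefs)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    cols = [f"signal{i}" for i in range(p)] + [f"noise{i}" for i in range(noise_vars)]
    return pd.DataFrame(X, columns=cols), y


class TestMetricPanel:
    def test_perfect_confusion_matrix(self):
        y = np.repeat([0, 1], 50)
        panel = pm.metric_panel(y, y, y.astype(float))
        assert (panel.acc, panel.pre, panel.tpr, panel.tnr, panel.f1,
                panel.auc) == (1, 1, 1, 1, 1, 1)

    def test_hand_computed_matrix(self):
        # rows true, cols predicted, positive class second:
        # [[8, 2], [3, 7]]
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        panel = pm.metric_panel(y_true, y_pred)
        assert panel.acc == pytest.approx(0.75)
        assert panel.tpr == pytest.approx(0.7)
        assert panel.tnr == pytest.approx(0.8)
        assert panel.pre == pytest.approx(7 / 9)
        expected_f1 = 2 * (7 / 9) * 0.7 / (7 / 9 + 0.7)
        assert panel.f1 == pytest.approx(expected_f1)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        score = rng.random(10_000)
        panel = pm.metric_panel(y, (score > 0.5).astype(int), score)
        assert panel.auc == pytest.approx(0.5, abs=0.02)

    def test_undefined_precision_flagged_as_zero(self):
        y = np.array([0, 1, 1, 0])
        pred = np.zeros(4, dtype=int)
        panel = pm.metric_panel(y, pred)
        assert panel.pre == 0.0
        assert panel.undefined_precision

    def test_macro_f1_equals_binary_on_balanced_symmetric(self):
        y_true = np.repeat([0, 1], 50)
        flip = np.zeros(100, dtype=bool)
        flip[:10] = True
        flip[50:60] = True  # symmetric confusion matrix
        y_pred = np.where(flip, 1 - y_true, y_true)
        binary = pm.metric_panel(y_true, y_pred)
        macro = pm.metric_panel(y_true, y_pred, averaging="macro")
        assert macro.f1 == pytest.approx(binary.f1)

    def test_macro_multiclass_ranges(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 300)
        score = rng.dirichlet(np.ones(3), 300)
        pred = score.argmax(axis=1)
        panel = pm.metric_panel(y, pred, score, averaging="macro")
        for v in panel.as_dict().values():
            assert 0.0 <= v <= 1.0


class TestOverfitGap:
    def test_identical_panels_zero_gap(self):
        gap = pm.overfit_gap({"m": 0.9}, {"m": 0.9})
        assert gap.loc["m", "gap"] == 0.0
        assert not gap.loc["m", "flagged"]

    def test_printed_example_difference(self):
        gap = pm.overfit_gap({"m": 0.985}, {"m": 0.768})
        assert round(gap.loc["m", "gap"], 3) == 0.217
        assert gap.loc["m", "flagged"]

    def test_flag_boundary(self):
        gap = pm.overfit_gap({"a": 0.90, "b": 0.90}, {"a": 0.75, "b": 0.74})
        assert not gap.loc["a", "flagged"]  # exactly at threshold
        assert gap.loc["b", "flagged"]


class TestStepwiseLogistic:
    def test_exp_b_and_ci_shape(self):
        X, y = _logistic_data(500, [1.0, -1.0], 2, seed=0)
        fit = pm.stepwise_logistic(X, y)
        t = fit.table
        np.testing.assert_allclose(t["ExpB"], np.exp(t["B"]))
        assert (t["ci_low"] < t["ExpB"]).all()
        assert (t["ExpB"] < t["ci_high"]).all()

    def test_zero_coefficient_gives_unit_odds_ratio(self):
        assert np.exp(0.0) == 1.0
        # CI symmetric around 1 on the log scale
        se = 0.3
        lo, hi = np.exp(0 - 1.96 * se), np.exp(0 + 1.96 * se)
        assert lo * hi == pytest.approx(1.0)

    def test_signal_retained_and_noise_mostly_dropped(self):
        # at alpha_exit = 0.10 each null predictor independently survives
        # with probability ~0.10, so a single run may keep a stray one
        coefs = [1.0, -1.0, 0.8, -0.8, 0.6]
        X, y = _logistic_data(2000, coefs, 10, seed=1)
        fit = pm.stepwise_logistic(X, y)
        assert set(f"signal{i}" for i in range(5)) <= set(fit.retained)
        n_noise = sum(f.startswith("noise") for f in fit.retained)
        assert n_noise <= 2
        # true coefficients inside the 95% CI (each interval individually
        # misses ~5% of the time, so allow one miss in this single seed)
        covered = 0
        for i, b in enumerate(coefs):
            lo = fit.table.loc[f"signal{i}", "B"] - 1.96 * fit.table.loc[
                f"signal{i}", "SE"]
            hi = fit.table.loc[f"signal{i}", "B"] + 1.96 * fit.table.loc[
                f"signal{i}", "SE"]
            covered += lo <= b <= hi
        assert covered >= 4

    def test_aic_recorded_per_accepted_step(self):
        X, y = _logistic_data(800, [1.2], 6, seed=2)
        fit = pm.stepwise_logistic(X, y)
        assert len(fit.aic_trace) == len(fit.dropped) + 1

    def test_perfect_separation_flagged(self):
        n = 60
        x = np.concatenate([np.linspace(-3, -1, 30), np.linspace(1, 3, 30)])
        y = (x > 0).astype(int)
        X = pd.DataFrame({"x": x})
        fit = pm.stepwise_logistic(X, y)
        assert fit.separation_flag


class TestNomogram:
    def test_single_variable_spans_full_scale(self):
        X, y = _logistic_data(400, [1.5], 0, seed=3)
        fit = pm.stepwise_logistic(X, y)
        nomo = pm.build_nomogram(fit, X, y, n_bootstrap=50, seed=0)
        pts = nomo.point_tables["signal0"]["points"]
        assert pts.min() == pytest.approx(0.0, abs=1e-9)
        assert pts.max() == pytest.approx(100.0, abs=1e-9)

    def test_probability_map_monotone(self):
        X, y = _logistic_data(400, [1.0, 0.5], 0, seed=4)
        fit = pm.stepwise_logistic(X, y)
        nomo = pm.build_nomogram(fit, X, y, n_bootstrap=50, seed=0)
        totals = np.linspace(0, 150, 20)
        probs = nomo.total_to_probability(totals)
        assert np.all(np.diff(probs) >= 0)

    def test_c_index_one_on_separable_fixture(self):
        x = np.concatenate([np.linspace(-3, -1, 40), np.linspace(1, 3, 40)])
        y = (x > 0).astype(int)
        X = pd.DataFrame({"x": x})
        fit = pm.stepwise_logistic(X, y)
        nomo = pm.build_nomogram(fit, X, y, n_bootstrap=20, seed=0)
        assert nomo.c_index == 1.0

    def test_calibration_mae_small_when_well_specified(self):
        X, y = _logistic_data(2000, [1.0, -0.8], 0, seed=5)
        fit = pm.stepwise_logistic(X, y)
        nomo = pm.build_nomogram(fit, X, y, n_bootstrap=200, seed=0)
        assert nomo.calibration_mae < 0.05

    def test_zero_range_variable_rejected(self):
        X, y = _logistic_data(200, [1.0], 0, seed=6)
        X["flat"] = 1.0
        fit = pm.stepwise_logistic(X[["signal0"]], y)
        fit.retained = ["flat"]
        fit.table.loc["flat"] = fit.table.loc["signal0"]
        with pytest.raises(ValueError, match="zero observed range"):
            pm.build_nomogram(fit, X, y, n_bootstrap=10)


class TestBenchmark:
    @pytest.fixture(scope="class")
    def small_config(self):
        return pm.BenchConfig(models=("l2_logistic", "rf", "lgbm"),
                              inner_tuner="fixed", n_boot_ci=50, seed=0)

    @pytest.fixture(scope="class")
    def data(self):
        return _logistic_data(250, [1.2, -1.0], 4, seed=7)

    def test_label_leak_probe(self, small_config):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 250)
        X = pd.DataFrame({"leak": y.astype(float),
                          "noise": rng.normal(size=250)})
        out = pm.run_benchmark(X, y, small_config)
        for model, res in out["models"].items():
            assert res["test"]["auc"] > 0.99, model

    def test_random_labels_auc_near_chance(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(900 + seed)
            y = rng.integers(0, 2, 200)
            X = pd.DataFrame(rng.normal(size=(200, 5)))
            X.columns = [f"f{i}" for i in range(5)]
            out = pm.run_benchmark(
                X, y,
                pm.BenchConfig(models=("lgbm",), inner_tuner="fixed",
                               n_boot_ci=20, seed=seed),
            )
            aucs.append(out["models"]["lgbm"]["test"]["auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_deterministic_under_seed(self, data, small_config):
        X, y = data
        a = pm.run_benchmark(X, y, small_config)
        b = pm.run_benchmark(X, y, small_config)
        for m in a["models"]:
            assert a["models"][m]["test"] == b["models"][m]["test"]
        assert a["fold_fingerprints"] == b["fold_fingerprints"]

    def test_missing_backend_skipped_with_log(self, data, caplog):
        X, y = data
        cfg = pm.BenchConfig(models=("l2_logistic", "ga_tabtransformer_rf"),
                             inner_tuner="fixed", n_boot_ci=20, seed=0)
        with caplog.at_level(logging.WARNING):
            out = pm.run_benchmark(X, y, cfg)
        assert out["skipped"] == ["ga_tabtransformer_rf"]
        assert any("backend" in rec.message for rec in caplog.records)

    def test_multiclass_macro_panel(self):
        rng = np.random.default_rng(10)
        n = 240
        y = rng.integers(0, 3, n)
        X = pd.DataFrame(rng.normal(size=(n, 4)) + y[:, None] * 0.8)
        X.columns = [f"f{i}" for i in range(4)]
        out = pm.run_benchmark(
            X, y,
            pm.BenchConfig(models=("rf",), task="multiclass",
                           inner_tuner="fixed", n_boot_ci=20, seed=0),
        )
        res = out["models"]["rf"]["test"]
        assert 0.5 < res["auc"] <= 1.0
        assert 0.0 <= res["f1"] <= 1.0

    def test_ga_tuner_runs_on_booster(self):
        X, y = _logistic_data(150, [1.5], 2, seed=11)
        cfg = pm.BenchConfig(models=("xgb",), inner_tuner="ga",
                             ga_population=4, ga_generations=1,
                             inner_folds=2, n_boot_ci=20, seed=0)
        out = pm.run_benchmark(X, y, cfg)
        assert out["models"]["xgb"]["test"]["auc"] > 0.7
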