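"""Nested CV, evaluation metrics, permutation importance, improvement loop."""

import numpy as np
import pandas as pd
import pytest

from cardioloop.classify import (
    LIGHT_GRID,
    CVResult,
    ModelConfig,
    evaluate,
    fit_final,
    improvement_loop,
    make_pipeline,
    nested_cv,
    permutation_importance_report,
)
from cardioloop.features.table import FeatureTable


def _synthetic_table(n=64, n_noise=5, classes=("A", "B"), seed=0,
                     informative_gap=4.0) -> FeatureTable:
    """Two-class table where only the 'signal' column separates classes."""
    rng = np.random.default_rng(seed)
    y = np.array([classes[i % len(classes)] for i in range(n)])
    signal = np.where(y == classes[0], 0.0, informative_gap) + rng.normal(0, 1, n)
    data = {"row_id": [f"c{i}::s{i}" for i in range(n)],
            "case_id": [f"c{i}" for i in range(n)],
            "session_id": [f"s{i}" for i in range(n)],
            "class_label": y,
            "signal": signal,
            "constant": np.full(n, 3.14)}
    for k in range(n_noise):
        data[f"noise{k}"] = rng.normal(0, 1, n)
    schema = [{"column": "signal", "group": "shape"},
              {"column": "constant", "group": "shape"}] + [
        {"column": f"noise{k}", "group": "first_order"} for k in range(n_noise)]
    return FeatureTable(data=pd.DataFrame(data), schema=schema)


class TestNestedCV:
    def test_separable_table_reaches_high_outer_accuracy(self):
        res = nested_cv(_synthetic_table(), seed=0)
        assert res.accuracy >= 0.95
        assert res.confusion_matrix.sum() == 64

    def test_permuted_labels_score_at_chance(self):
        table = _synthetic_table()
        rng = np.random.default_rng(0)
        table.data["class_label"] = rng.permutation(table.data["class_label"].to_numpy())
        res = nested_cv(table, grid=LIGHT_GRID, seed=0)
        assert 0.3 <= res.accuracy <= 0.7

    def test_same_seed_reproduces_result(self):
        a = nested_cv(_synthetic_table(), seed=3)
        b = nested_cv(_synthetic_table(), seed=3)
        assert a.accuracy == b.accuracy
        assert a.outer_scores == b.outer_scores
        assert np.array_equal(a.confusion_matrix, b.confusion_matrix)
        assert a.selected == b.selected

    def test_single_class_rejected(self):
        table = _synthetic_table()
        table.data["class_label"] = "A"
        with pytest.raises(ValueError, match="2 classes"):
            nested_cv(table, seed=0)

    def test_small_class_reduces_folds_with_warning(self):
        table = _synthetic_table(n=10)
        with pytest.warns(UserWarning, match="reducing outer folds"):
            res = nested_cv(table, outer_folds=8, seed=0)
        assert isinstance(res, CVResult)

    def test_accuracy_equals_confusion_trace(self):
        res = nested_cv(_synthetic_table(seed=5), seed=5)
        cm = res.confusion_matrix
        assert res.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        assert res.macro_auc == pytest.approx(
            np.mean([v for v in res.per_class_auc.values()]))


class TestNoLeakage:
    def test_test_fold_labels_never_touch_preprocessing(self):
        table = _synthetic_table()
        X = table.data[[e["column"] for e in table.schema]]
        y = table.data["class_label"].to_numpy()
        tr, te = np.arange(0, 48), np.arange(48, 64)
        pipe = make_pipeline(ModelConfig(family="random_forest",
                                         hyperparameters={"n_estimators": 10}))
        pipe.fit(X.iloc[tr], y[tr])
        stats1 = (pipe["impute"].statistics_.copy(), pipe["scale"].mean_.copy())
        y2 = y.copy()
        y2[te] = np.random.default_rng(0).permutation(y2[te])
        pipe2 = make_pipeline(ModelConfig(family="random_forest",
                                          hyperparameters={"n_estimators": 10}))
        pipe2.fit(X.iloc[tr], y2[tr])
        assert np.array_equal(stats1[0], pipe2["impute"].statistics_)
        assert np.array_equal(stats1[1], pipe2["scale"].mean_)


class TestFitFinalAndEvaluate:
    def test_published_style_forest_config_fits(self):
        config = ModelConfig(family="random_forest", hyperparameters={
            "n_estimators": 230, "criterion": "gini", "max_depth": 6,
            "min_samples_leaf": 6, "min_samples_split": 9})
        model = fit_final(_synthetic_table(), config)
        assert evaluate(model, _synthetic_table())["accuracy"] >= 0.9

    def test_published_style_extra_trees_config_fits(self):
        config = ModelConfig(family="extra_trees", hyperparameters={
            "n_estimators": 190, "criterion": "gini", "max_depth": 6,
            "min_samples_leaf": 6, "min_samples_split": 9})
        model = fit_final(_synthetic_table(), config)
        assert model.pipeline is not None

    def test_out_of_domain_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="max_depth"):
            ModelConfig(family="random_forest",
                        hyperparameters={"max_depth": -1}).validate()
        with pytest.raises(ValueError, match="unknown hyperparameter"):
            ModelConfig(family="svm_rbf", hyperparameters={"depth": 2}).validate()

    def test_perfect_predictions_metrics(self):
        table = _synthetic_table(n=20, classes=("A", "B", "C", "D", "E"),
                                 informative_gap=50.0)
        model = fit_final(table, ModelConfig(family="random_forest",
                                             hyperparameters={"n_estimators": 50}))
        out = evaluate(model, table)
        assert out["accuracy"] == 1.0
        assert all(v == 1.0 for v in out["per_class_precision"].values())
        assert all(v == 1.0 for v in out["per_class_recall"].values())
        assert out["macro_auc"] == 1.0

    def test_confusion_matrix_arithmetic(self):
        # predictions equivalent to the confusion matrix [[3,1],[1,3]]
        table = _synthetic_table(n=8, n_noise=0, informative_gap=0.0)
        model = fit_final(table, ModelConfig(family="logistic"))
        y = table.data["class_label"].to_numpy()
        pred = y.copy()
        pred[0], pred[1] = "B", "A"  # one error per class
        from cardioloop.classify import _metrics_from_predictions
        m = _metrics_from_predictions(y, pred, None, ["A", "B"])
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["recall"] == {"A": pytest.approx(0.75), "B": pytest.approx(0.75)}

    def test_auc_equals_mann_whitney_statistic(self):
        from cardioloop.classify import _metrics_from_predictions
        y = np.array(["A", "A", "A", "B", "B", "B"])
        scores_b = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        scores = np.stack([1 - scores_b, scores_b], axis=1)
        m = _metrics_from_predictions(y, y, scores, ["A", "B"])
        # Mann-Whitney U / (n1*n2) by exhaustive pair counting
        pos = scores_b[3:]
        neg = scores_b[:3]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert m["auc"]["B"] == pytest.approx(u / 9.0)


class TestPermutationImportance:
    def test_constant_feature_importance_exactly_zero(self):
        table = _synthetic_table()
        model = fit_final(table, ModelConfig(family="random_forest",
                                             hyperparameters={"n_estimators": 40}))
        report = permutation_importance_report(model, table, repeats=5, seed=0)
        row = report.table[report.table["feature"] == "constant"].iloc[0]
        assert row["importance"] == 0.0
        assert row["sd"] == 0.0

    def test_informative_feature_ranked_first_and_dominant(self):
        table = _synthetic_table(seed=2)
        model = fit_final(table, ModelConfig(family="random_forest",
                                             hyperparameters={"n_estimators": 60}))
        report = permutation_importance_report(model, table, repeats=10, seed=2)
        assert report.ranking[0] == "signal"
        top = report.table.iloc[0]["importance"]
        others = report.table.iloc[1:]["importance"]
        assert (others.abs() < top / 2).all()

    def test_more_repeats_stabilize_the_estimate_keep_sign(self):
        table = _synthetic_table(seed=4)
        model = fit_final(table, ModelConfig(family="random_forest",
                                             hyperparameters={"n_estimators": 60}))

        def estimates(repeats):
            return [permutation_importance_report(model, table, repeats=repeats,
                                                  seed=s)
                    .table.set_index("feature").loc["signal", "importance"]
                    for s in range(5)]

        few, many = estimates(1), estimates(30)
        assert all(np.sign(v) == 1 for v in few + many)
        # Monte-Carlo convergence: the mean-importance estimate spreads less
        # across seeds when each estimate averages more shuffles
        assert np.std(many) <= np.std(few) + 1e-12

    def test_duplicated_informative_feature_splits_importance(self):
        table = _synthetic_table(seed=6)
        solo_model = fit_final(table, ModelConfig(
            family="random_forest", hyperparameters={"n_estimators": 60}))
        solo = permutation_importance_report(solo_model, table, repeats=10, seed=6)
        solo_imp = solo.table.set_index("feature").loc["signal", "importance"]
        dup = _synthetic_table(seed=6)
        dup.data["signal_copy"] = dup.data["signal"]
        dup.schema.append({"column": "signal_copy", "group": "shape"})
        dup_model = fit_final(dup, ModelConfig(
            family="random_forest", hyperparameters={"n_estimators": 60}))
        rep = permutation_importance_report(dup_model, dup, repeats=10, seed=6)
        by_feature = rep.table.set_index("feature")["importance"]
        assert by_feature["signal"] <= solo_imp + 1e-12
        assert by_feature["signal_copy"] <= solo_imp + 1e-12


class TestWallThicknessDominance:
    def test_wall_determined_cohort_ranks_wall_features_top3(self):
        """On a NOR-vs-HCM cohort, where wall thickness is the only class
        separator by construction, permutation importance (probability
        scoring) puts a septum or myocardial-volume feature in the top 3."""
        from cardioloop.features.table import extract_feature_table
        from cardioloop.phantom import PhantomConfig, generate_cohort
        config = PhantomConfig(n_cases=40, phases=10, slices=6, grid=(96, 96),
                               seed=31, class_mix={"NOR": 0.5, "HCM": 0.5})
        cohort, _ = generate_cohort(config)
        table = extract_feature_table(cohort, feature_set="fast")
        model = fit_final(table, ModelConfig(
            family="random_forest",
            hyperparameters={"n_estimators": 230, "criterion": "gini",
                             "max_depth": 6, "min_samples_leaf": 6,
                             "min_samples_split": 9}, seed=31))
        report = permutation_importance_report(model, table, repeats=10, seed=31,
                                               scoring="neg_log_loss")
        wall = ("septum_thickness", "relative_septum_thickness",
                "lv_myocardium.volume")
        assert any(f.startswith(wall) for f in report.top(3)), report.top(3)


class TestImprovementLoop:
    def test_zero_corruption_is_a_fixed_point(self, small_cohort):
        cohort, truths = small_cohort
        out = improvement_loop(cohort, truths, seed=0, outer_folds=2)
        assert out["corrected_cases"] == []
        assert out["accuracy_after"] == out["accuracy_before"]

    def test_corrected_cases_subset_of_flagged(self):
        from cardioloop.phantom import CorruptionModel, PhantomConfig, generate_cohort
        config = PhantomConfig(n_cases=12, phases=14, slices=5, grid=(64, 64),
                               seed=17, class_mix={"NOR": 0.5, "HCM": 0.5},
                               corruption=CorruptionModel(rate=0.3))
        cohort, truths = generate_cohort(config)
        out = improvement_loop(cohort, truths, seed=17, outer_folds=2)
        assert set(out["corrected_cases"]) <= set(out["flagged_cases"])
        corrupted = {t.case_id for t in truths if t.corruption}
        assert set(out["corrected_cases"]) <= corrupted | set(out["flagged_cases"])
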