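"""Forest training, validation schemes, metrics, and feature diagnostics."""

import numpy as np
import pandas as pd
import pytest

import _oracles
from metoncokit.classifier_eval import (
    compute_metrics,
    feature_target_correlation,
    gene_level_aggregate,
    holdout_validation,
    importance_report,
    k_fold_cv,
    leave_one_cell_line_out,
    leave_one_feature_set_out,
    permutation_significance,
    train_random_forest,
)
from metoncokit.feature_table import FeatureMatrix
from metoncokit.synthetic_fixtures import FixtureSpec, generate_feature_dataset
from metoncokit.target_labels import DOWN, NEUTRAL, UP

SMALL_FOREST = {"n_estimators": 100}


@pytest.fixture(scope="module")
def signal_matrix():
    return generate_feature_dataset(
        FixtureSpec(n_genes=45, n_cell_lines=4, label_noise=0.0, seed=5)
    )


@pytest.fixture(scope="module")
def noise_matrix():
    return generate_feature_dataset(
        FixtureSpec(n_genes=45, n_cell_lines=4, signal_features=(),
                    effect_size=0.0, label_noise=0.0, seed=6)
    )


class TestTraining:
    def test_planted_signal_beats_chance_in_training(self, signal_matrix):
        x, y = signal_matrix.data, signal_matrix.labels["target"]
        model = train_random_forest(x, y, SMALL_FOREST, seed=0)
        assert (model.predict(x) == y).mean() > 1 / 3

    def test_same_seed_identical_predictions(self, signal_matrix):
        x, y = signal_matrix.data, signal_matrix.labels["target"]
        p1 = train_random_forest(x, y, SMALL_FOREST, seed=9).predict(x)
        p2 = train_random_forest(x, y, SMALL_FOREST, seed=9).predict(x)
        assert (p1 == p2).all()

    def test_single_class_labels_rejected(self, signal_matrix):
        x = signal_matrix.data
        y = pd.Series([UP] * len(x), index=x.index)
        with pytest.raises(ValueError):
            train_random_forest(x, y)

    def test_grid_search_records_best_params(self, signal_matrix):
        x, y = signal_matrix.data, signal_matrix.labels["target"]
        model = train_random_forest(
            x, y, {"n_estimators": 20}, seed=0,
            param_grid={"max_depth": [2, None]},
        )
        assert "max_depth" in model.hyperparameters


class TestCrossValidation:
    def test_separable_data_near_perfect(self, signal_matrix):
        report = k_fold_cv(signal_matrix, "target", k=5, seed=0,
                           forest_params=SMALL_FOREST)
        assert report.accuracy > 0.9
        assert sum(sum(row) for row in report.confusion_matrix) == report.n_eval

    def test_noise_data_near_chance(self, noise_matrix):
        report = k_fold_cv(noise_matrix, "target", k=5, seed=0,
                           forest_params=SMALL_FOREST)
        n = report.n_eval
        sigma = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(report.accuracy - 1 / 3) < 3 * sigma

    def test_class_smaller_than_k_is_fold_error(self, signal_matrix):
        with pytest.raises(ValueError, match="use k"):
            k_fold_cv(signal_matrix, "target", k=10_000)

    def test_leave_one_out_boundary_runs(self):
        matrix = generate_feature_dataset(
            FixtureSpec(n_genes=6, n_cell_lines=2, n_topological=2, n_dynamic=2,
                        n_biochemical=2, label_noise=0.0, seed=3,
                        signal_features=("bio_feat_00",))
        )
        report = k_fold_cv(matrix, "target", k=len(matrix.data), seed=0,
                           forest_params={"n_estimators": 20})
        assert report.n_eval == len(matrix.data)

    def test_fold_assignment_depends_only_on_seed(self, signal_matrix):
        r1 = k_fold_cv(signal_matrix, "target", k=5, seed=2, forest_params=SMALL_FOREST)
        r2 = k_fold_cv(signal_matrix, "target", k=5, seed=2, forest_params=SMALL_FOREST)
        assert r1.confusion_matrix == r2.confusion_matrix


class TestHoldout:
    def test_split_sizes_and_disjointness(self, signal_matrix):
        report = holdout_validation(signal_matrix, "target", seed=0,
                                    forest_params=SMALL_FOREST)
        n = len(signal_matrix.data)
        assert abs(report.n_eval - round(0.3 * n)) <= 1

    def test_consistent_with_cv_on_separable_data(self, signal_matrix):
        cv = k_fold_cv(signal_matrix, "target", k=5, seed=0, forest_params=SMALL_FOREST)
        ho = holdout_validation(signal_matrix, "target", seed=0,
                                forest_params=SMALL_FOREST)
        assert abs(cv.accuracy - ho.accuracy) < 0.1


class TestLeaveOneOutSchemes:
    def test_one_report_per_cell_line(self, signal_matrix):
        reports = leave_one_cell_line_out(signal_matrix, "target",
                                          forest_params=SMALL_FOREST)
        assert len(reports) == 4
        assert all(r.accuracy > 0.8 for r in reports.values())

    def test_single_cell_line_is_error(self):
        matrix = generate_feature_dataset(
            FixtureSpec(n_genes=30, n_cell_lines=1, label_noise=0.0, seed=2)
        )
        with pytest.raises(ValueError):
            leave_one_cell_line_out(matrix, "target")

    def test_line_specific_label_noise_lowers_only_that_line(self, signal_matrix):
        labels = signal_matrix.labels.copy()
        held = labels.index.get_level_values("cell_line") == "CL0"
        rng = np.random.default_rng(0)
        noisy = rng.permutation(labels.loc[held, "target"].to_numpy())
        labels.loc[held, "target"] = noisy
        matrix = FeatureMatrix(signal_matrix.data, signal_matrix.schema, labels)
        reports = leave_one_cell_line_out(matrix, "target", forest_params=SMALL_FOREST)
        others = [r.accuracy for line, r in reports.items() if line != "CL0"]
        assert reports["CL0"].accuracy < min(others)

    def test_one_report_per_feature_category(self, signal_matrix):
        reports = leave_one_feature_set_out(signal_matrix, "target", k=5,
                                            forest_params=SMALL_FOREST)
        assert set(reports) == {"topological", "dynamic", "biochemical"}

    def test_dropping_signal_category_hurts_most(self, signal_matrix):
        reports = leave_one_feature_set_out(signal_matrix, "target", k=5,
                                            forest_params=SMALL_FOREST)
        accs = {cat: r.accuracy for cat, r in reports.items()}
        # the planted features are biochemical: dropping them erases the signal
        assert min(accs, key=accs.get) == "biochemical"
        assert accs["biochemical"] < 0.6
        assert accs["topological"] > 0.9  # inert category, no loss


class TestMetrics:
    def test_perfect_diagonal(self):
        report = compute_metrics(np.diag([10, 10, 10]), (DOWN, NEUTRAL, UP))
        assert report.accuracy == 1.0
        assert report.mcc == pytest.approx(1.0)
        assert report.f1 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        classes = (DOWN, NEUTRAL, UP)
        y_true = rng.choice(classes, size=200)
        y_pred = rng.choice(classes, size=200)
        mat = np.zeros((3, 3), dtype=int)
        idx = {c: i for i, c in enumerate(classes)}
        for t, p in zip(y_true, y_pred):
            mat[idx[t], idx[p]] += 1
        mine = compute_metrics(mat, classes)
        oracle = _oracles.sklearn_metric_bundle(y_true, y_pred, classes)
        for key in ("accuracy", "precision", "recall", "f1", "mcc"):
            assert getattr(mine, key) == pytest.approx(oracle[key], abs=1e-12)

    def test_uniform_random_matrix_has_near_zero_mcc(self):
        report = compute_metrics(np.full((3, 3), 50), (DOWN, NEUTRAL, UP))
        assert report.mcc == pytest.approx(0.0, abs=1e-12)

    def test_single_class_predictions_degenerate_convention(self):
        mat = np.array([[10, 0, 0], [10, 0, 0], [10, 0, 0]])
        report = compute_metrics(mat, (DOWN, NEUTRAL, UP))
        recalls = [report.per_class[c]["recall"] for c in (DOWN, NEUTRAL, UP)]
        assert recalls == [1.0, 0.0, 0.0]
        assert report.mcc == 0.0

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((3, 3)), (DOWN, NEUTRAL, UP))

    def test_confusion_row_sums_match_class_counts(self, signal_matrix):
        report = k_fold_cv(signal_matrix, "target", k=5, seed=0,
                           forest_params=SMALL_FOREST)
        row_sums = [sum(row) for row in report.confusion_matrix]
        counts = signal_matrix.labels["target"].value_counts()
        assert row_sums == [int(counts[c]) for c in report.classes]

    def test_auroc_reported_for_probability_scores(self, signal_matrix):
        report = holdout_validation(signal_matrix, "target", seed=0,
                                    forest_params=SMALL_FOREST)
        assert 0.9 <= report.auroc <= 1.0


class TestPermutation:
    def test_planted_signal_is_significant(self, signal_matrix):
        result = permutation_significance(
            signal_matrix, "target", n_iter=30, seed=0,
            forest_params={"n_estimators": 30},
        )
        assert result["p_empirical"] == pytest.approx(1 / 31)
        assert result["z_score"] > 3

    def test_noise_is_not_significant(self, noise_matrix):
        result = permutation_significance(
            noise_matrix, "target", n_iter=30, seed=0,
            forest_params={"n_estimators": 30},
        )
        assert result["p_empirical"] > 0.05
        assert abs(result["null_mean"] - 1 / 3) < 0.1

    def test_too_few_iterations_rejected(self, noise_matrix):
        with pytest.raises(ValueError):
            permutation_significance(noise_matrix, "target", n_iter=1)


class TestFeatureDiagnostics:
    def test_correlation_sign_calls(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.choice([DOWN, NEUTRAL, UP], size=300))
        encoded = y.map({DOWN: -1, NEUTRAL: 0, UP: 1}).astype(float)
        x = pd.DataFrame(
            {"same": encoded, "negated": -encoded,
             "noise": rng.normal(size=300)}
        )
        signs = feature_target_correlation(x, y)
        assert signs.loc["same", "sign"] == "+"
        assert signs.loc["negated", "sign"] == "-"
        assert signs.loc["noise", "sign"] == "~"
        assert signs.loc["same", "r"] == pytest.approx(1.0)

    def test_zero_variance_feature_warns_and_is_tilde(self):
        y = pd.Series([DOWN, NEUTRAL, UP] * 10)
        x = pd.DataFrame({"flat": np.ones(30)})
        with pytest.warns(UserWarning, match="flat"):
            signs = feature_target_correlation(x, y)
        assert signs.loc["flat", "sign"] == "~"

    def test_importances_sum_to_one_with_rank_permutation(self, signal_matrix):
        x, y = signal_matrix.data, signal_matrix.labels["target"]
        model = train_random_forest(x, y, SMALL_FOREST, seed=0)
        report = importance_report(model, x, y)
        assert report["gini_importance"].sum() == pytest.approx(1.0)
        assert sorted(report["rank"]) == list(range(1, len(x.columns) + 1))
        assert (report["gini_importance"] >= 0).all()

    def test_planted_features_rank_top(self, signal_matrix):
        x, y = signal_matrix.data, signal_matrix.labels["target"]
        model = train_random_forest(x, y, SMALL_FOREST, seed=0)
        report = importance_report(model, x, y)
        planted = [f"bio_feat_{i:02d}" for i in range(5)]
        assert set(report.index[:5]) == set(planted)


class TestGeneAggregation:
    def test_plurality_vote(self):
        rows = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        label, summary = gene_level_aggregate(rows, [UP, UP, NEUTRAL])
        assert label == UP
        assert summary["f"] == 2.0

    def test_tie_falls_back_to_median_encoding(self):
        rows = pd.DataFrame({"f": [1.0, 2.0]})
        label, _ = gene_level_aggregate(rows, [UP, DOWN])
        assert label == NEUTRAL

    def test_single_row_is_itself(self):
        rows = pd.DataFrame({"f": [4.0]})
        label, summary = gene_level_aggregate(rows, [DOWN])
        assert label == DOWN
        assert summary["f"] == 4.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_level_aggregate(pd.DataFrame({"f": []}), [])
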