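"""Feature table, splits, target handling, metrics and the model benchmark."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
)

from resprout import (
    accuracy,
    balanced_accuracy,
    binarize_target,
    build_feature_table,
    count_events,
    evaluate_holdout,
    generate_scenarios,
    make_splits,
    per_class_metrics,
    run_model_suite,
    n_test_rows,
    weighted_f1,
)
from resprout.fusion import MergedQSM
from resprout.prediction import DEFAULT_FEATURES, FeatureTableError


def truth_tables(n_trees=6, seed=0):
    scenarios = generate_scenarios(n_trees, seed=seed)
    models = [count_events(MergedQSM(qsm=sc.truth_merged.copy()))
              for sc in scenarios]
    return build_feature_table(models)


@pytest.fixture(scope="module")
def table():
    return truth_tables()


class TestFeatureTable:
    def test_one_row_per_cylinder(self):
        scenarios = generate_scenarios(2, seed=1)
        models = [count_events(MergedQSM(qsm=sc.truth_merged.copy()))
                  for sc in scenarios]
        table = build_feature_table(models)
        assert len(table) == sum(len(m.qsm) for m in models)

    def test_fields_round_trip(self):
        sc = generate_scenarios(1, seed=2)[0]
        m = count_events(MergedQSM(qsm=sc.truth_merged.copy()))
        table = build_feature_table([m]).set_index("cylinder_id")
        for c in m.qsm.cylinders:
            row = table.loc[c.cylinder_id]
            assert row["radius"] == c.radius
            assert row["branch_order"] == c.branch_order
            assert row["n_pruned_children"] == c.n_pruned_children
            assert row["target_label"] == m.target_labels[c.cylinder_id]

    def test_pruned_rows_present_and_flagged(self, table):
        pruned = table[table["target_label"] == -1]
        assert len(pruned) > 0
        assert pruned["is_pruned"].all()

    def test_duplicate_rows_rejected(self):
        sc = generate_scenarios(1, seed=3)[0]
        m = count_events(MergedQSM(qsm=sc.truth_merged.copy()))
        with pytest.raises(FeatureTableError, match="duplicate"):
            build_feature_table([m, m])


class TestSplits:
    def test_printed_dataset_convention(self):
        # 16,558 usable rows at fraction 0.2 give a 3,312-row test set
        assert n_test_rows(16_558, 0.2) == 3_312

    def test_ceil_convention_small(self):
        assert n_test_rows(10, 0.2) == 2
        assert n_test_rows(11, 0.2) == 3

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_partition_integrity(self, table, seed):
        split = make_splits(table, seed=seed)
        assert len(split.eval_tree_ids) == 2
        eval_set = set(split.eval_tree_ids)
        assert not (set(split.train["tree_id"]) & eval_set)
        assert not (set(split.test["tree_id"]) & eval_set)
        train_keys = set(map(tuple, split.train[["tree_id", "cylinder_id"]].values))
        test_keys = set(map(tuple, split.test[["tree_id", "cylinder_id"]].values))
        assert not (train_keys & test_keys)
        for part in (split.train, split.test, split.eval):
            assert (part["target_label"] >= 0).all()

    def test_test_size_follows_ceil(self, table):
        split = make_splits(table, seed=4)
        n_rest = len(split.train) + len(split.test)
        assert len(split.test) == n_test_rows(n_rest, 0.2)

    def test_same_seed_identical_partitions(self, table):
        a = make_splits(table, seed=9)
        b = make_splits(table, seed=9)
        pd.testing.assert_frame_equal(a.train, b.train)
        pd.testing.assert_frame_equal(a.test, b.test)
        assert a.eval_tree_ids == b.eval_tree_ids

    def test_too_few_trees_rejected(self, table):
        two = table[table["tree_id"].isin(sorted(table["tree_id"].unique())[:2])]
        with pytest.raises(ValueError):
            make_splits(two, n_eval_trees=2)


class TestBinarize:
    def test_counts_collapse_to_presence(self):
        np.testing.assert_array_equal(
            binarize_target([0, 1, 2, 4]), [0, 1, 1, 1]
        )

    def test_all_zero_unchanged(self):
        np.testing.assert_array_equal(binarize_target([0, 0]), [0, 0])

    def test_pruned_rows_rejected(self):
        with pytest.raises(ValueError):
            binarize_target([0, -1, 1])


class TestMetrics:
    def test_hand_example(self):
        # recall(0) = 2/3, recall(1) = 1 -> balanced accuracy 5/6
        assert balanced_accuracy([0, 0, 0, 1], [0, 0, 1, 1]) == pytest.approx(5 / 6)

    def test_perfect_prediction(self):
        y = [0, 1, 2, 1]
        assert accuracy(y, y) == 1.0
        assert balanced_accuracy(y, y) == 1.0
        assert weighted_f1(y, y) == 1.0

    def test_majority_predictor_balanced_half(self):
        y_true = [0] * 9 + [1]
        y_pred = [0] * 10
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.5)

    def test_strict_mode_rejects_unknown_predicted_class(self):
        with pytest.raises(ValueError):
            balanced_accuracy([0, 0, 1], [0, 2, 1])
        # lenient mode: extra predictions only hurt recall of true classes
        assert balanced_accuracy([0, 0, 1], [0, 2, 1], strict=False) == pytest.approx(
            0.75
        )

    def test_f1_closed_form(self):
        # TP=8, FN=2, FP=1, TN=9 -> precision 8/9, recall 0.8
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        m = per_class_metrics(y_true, y_pred).set_index("label")
        assert m.loc[1, "precision"] == pytest.approx(8 / 9)
        assert m.loc[1, "recall"] == pytest.approx(0.8)
        assert m.loc[1, "f1"] == pytest.approx(
            2 * (8 / 9 * 0.8) / (8 / 9 + 0.8)
        )

    def test_never_predicted_class_zero_precision_with_warning(self):
        with pytest.warns(UserWarning, match="never predicted"):
            m = per_class_metrics([0, 1, 1], [0, 0, 0]).set_index("label")
        assert m.loc[1, "precision"] == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=60).flatmap(
            lambda y: st.tuples(
                st.just(y),
                st.lists(
                    st.sampled_from(sorted(set(y))),
                    min_size=len(y), max_size=len(y),
                ),
            )
        )
    )
    def test_metrics_match_sklearn_oracles(self, pair):
        y_true, y_pred = pair
        assert accuracy(y_true, y_pred) == pytest.approx(
            accuracy_score(y_true, y_pred), abs=1e-12
        )
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred), abs=1e-12
        )
        assert weighted_f1(y_true, y_pred) == pytest.approx(
            f1_score(y_true, y_pred, average="weighted", zero_division=0),
            abs=1e-12,
        )


@pytest.fixture(scope="module")
def split():
    return make_splits(truth_tables(8, seed=5), seed=5)


class TestModelSuite:

    def test_one_row_per_model(self, split):
        report = run_model_suite(split, task="binary", seed=0)
        assert len(report.scores) == 8
        assert set(report.scores["name"]) == {
            "LGBMClassifier", "GaussianNB", "NearestCentroid", "MLP_64_128",
            "LogisticRegression", "RandomForestClassifier",
            "DecisionTreeClassifier", "KNeighborsClassifier",
        }

    def test_scores_within_unit_interval(self, split):
        report = run_model_suite(split, task="multiclass", seed=0)
        for col in ("accuracy", "balanced_accuracy", "f1"):
            assert report.scores[col].between(0, 1).all()

    def test_gbdt_learns_deterministic_rule(self, split):
        report = run_model_suite(split, task="binary", seed=0)
        ba = report.scores.set_index("name").loc[
            "LGBMClassifier", "balanced_accuracy"
        ]
        assert ba >= 0.95

    def test_multiclass_never_easier_than_binary(self, split):
        rb = run_model_suite(split, task="binary", seed=0)
        rm = run_model_suite(split, task="multiclass", seed=0)
        b = rb.scores.set_index("name")["balanced_accuracy"]
        m = rm.scores.set_index("name")["balanced_accuracy"]
        for name in b.index:
            assert m[name] <= b[name] + 0.05

    def test_degenerate_single_class_training_skipped(self, split):
        degenerate = split.train.copy()
        degenerate["target_label"] = 0
        from resprout.prediction import DatasetSplit

        ds = DatasetSplit(
            split.eval_tree_ids, degenerate, split.test, split.eval, 0.2, 0
        )
        report = run_model_suite(ds, task="binary", seed=0)
        assert len(report.scores) == 0
        assert len(report.skipped) == 8

    def test_evaluate_holdout_perfect_diagonal(self, split):
        report = run_model_suite(split, task="binary", seed=0)
        model = report.models["LGBMClassifier"]
        cm, per_class, summary = evaluate_holdout(
            model, split.eval, task="binary"
        )
        assert cm.values.sum() == len(split.eval)
        assert 0 <= summary["balanced_accuracy"] <= 1
        # deterministic rule is a function of the features: near-perfect holdout
        assert summary["accuracy"] >= 0.95
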