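"""Per-cylinder resprouting prediction: features, splits, model benchmark.

Every cylinder of the time-integrated QSM becomes one row with its
geometric and topological attributes; the target is the number of new
shoots that emerged on it (0..4, counts above 4 capped) or -1 for
cylinders that were pruned away. Pruned rows never feed the models —
a removed cylinder cannot resprout. Whole trees are held out for
evaluation, the rest is split 80/20 into train and test, and a suite of
classifiers at library defaults is benchmarked with imbalance-aware
metrics (balanced accuracy, weighted F1) for a binary
(will-it-resprout) and a multiclass (how many shoots) task.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .fusion import MergedQSM

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureTableError",
    "DatasetSplit",
    "ModelScore",
    "BenchmarkReport",
    "build_feature_table",
    "make_splits",
    "n_test_rows",
    "binarize_target",
    "accuracy",
    "balanced_accuracy",
    "weighted_f1",
    "per_class_metrics",
    "evaluate_holdout",
    "default_model_suite",
    "run_model_suite",
]

FEATURE_COLUMNS = [
    "tree_id",
    "cylinder_id",
    "parent_id",
    "extension_id",
    "start_x",
    "start_y",
    "start_z",
    "axis_x",
    "axis_y",
    "axis_z",
    "branch_id",
    "position_in_branch",
    "branch_order",
    "length",
    "radius",
    "n_pruned_children",
    "n_new_children",
    "is_virtual",
    "is_pruned",
    "target_label",
]

# Identifiers and booleans are excluded from the default predictors;
# n_new_children is the target source and never a predictor.
DEFAULT_FEATURES = [
    "start_x",
    "start_y",
    "start_z",
    "axis_x",
    "axis_y",
    "axis_z",
    "branch_order",
    "position_in_branch",
    "length",
    "radius",
    "n_pruned_children",
]


class FeatureTableError(ValueError):
    pass


def build_feature_table(merged_models: list[MergedQSM]) -> pd.DataFrame:
    """One row per cylinder across all merged models.

    Raises :class:`FeatureTableError` on duplicate (tree_id, cylinder_id).
    """
    rows = []
    for m in merged_models:
        targets = m.target_labels
        for c in m.qsm.cylinders:
            rows.append(
                {
                    "tree_id": m.qsm.tree_id,
                    "cylinder_id": c.cylinder_id,
                    "parent_id": -1 if c.parent_id is None else c.parent_id,
                    "extension_id": -1 if c.extension_id is None else c.extension_id,
                    "start_x": float(c.start[0]),
                    "start_y": float(c.start[1]),
                    "start_z": float(c.start[2]),
                    "axis_x": float(c.axis[0]),
                    "axis_y": float(c.axis[1]),
                    "axis_z": float(c.axis[2]),
                    "branch_id": c.branch_id,
                    "position_in_branch": c.position_in_branch,
                    "branch_order": c.branch_order,
                    "length": float(c.length),
                    "radius": float(c.radius),
                    "n_pruned_children": c.n_pruned_children,
                    "n_new_children": c.n_new_children,
                    "is_virtual": bool(c.is_virtual),
                    "is_pruned": targets[c.cylinder_id] == -1,
                    "target_label": targets[c.cylinder_id],
                }
            )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    dup = df.duplicated(subset=["tree_id", "cylinder_id"])
    if dup.any():
        bad = df.loc[dup, ["tree_id", "cylinder_id"]].iloc[0]
        raise FeatureTableError(
            f"duplicate cylinder row: tree {bad.tree_id!r} id {bad.cylinder_id}"
        )
    return df


def n_test_rows(n_remaining: int, test_fraction: float) -> int:
    """Test-partition size: ceil(fraction x n). ceil(0.2 x 16558) = 3312."""
    return math.ceil(test_fraction * n_remaining)


@dataclass
class DatasetSplit:
    """Evaluation trees held out whole; the rest split into train/test."""

    eval_tree_ids: list[str]
    train: pd.DataFrame
    test: pd.DataFrame
    eval: pd.DataFrame
    test_fraction: float
    seed: int


def make_splits(
    table: pd.DataFrame,
    n_eval_trees: int = 2,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Drop pruned rows, hold out whole trees, split the rest 80/20.

    Pruned cylinders (target -1) never enter any partition. The
    evaluation trees are a seeded random choice, wholly disjoint from
    train/test; the remaining rows are partitioned uniformly at random
    with test size ceil(test_fraction x n).
    """
    rng = np.random.default_rng(seed)
    usable = table[table["target_label"] != -1].reset_index(drop=True)
    tree_ids = sorted(usable["tree_id"].unique())
    if len(tree_ids) < n_eval_trees + 1:
        raise ValueError(
            f"need at least {n_eval_trees + 1} trees, got {len(tree_ids)}"
        )
    eval_ids = sorted(
        rng.choice(np.array(tree_ids, dtype=object), size=n_eval_trees, replace=False)
    )
    eval_rows = usable[usable["tree_id"].isin(eval_ids)].reset_index(drop=True)
    rest = usable[~usable["tree_id"].isin(eval_ids)].reset_index(drop=True)
    n_test = n_test_rows(len(rest), test_fraction)
    perm = rng.permutation(len(rest))
    test_rows = rest.iloc[perm[:n_test]].reset_index(drop=True)
    train_rows = rest.iloc[perm[n_test:]].reset_index(drop=True)
    return DatasetSplit(
        eval_tree_ids=[str(t) for t in eval_ids],
        train=train_rows,
        test=test_rows,
        eval=eval_rows,
        test_fraction=test_fraction,
        seed=seed,
    )


def binarize_target(targets: np.ndarray | pd.Series) -> np.ndarray:
    """Map shoot counts to will-it-resprout labels: 0 -> 0, 1..4 -> 1."""
    t = np.asarray(targets, dtype=int)
    if np.any(t < 0):
        raise ValueError("pruned rows (target -1) must be removed before binarizing")
    return (t > 0).astype(int)


# ---------------------------------------------------------------------------
# metrics (confusion-matrix arithmetic; sklearn scorers cross-check in tests)


def _labels_union(y_true, y_pred) -> np.ndarray:
    return np.unique(np.concatenate([np.asarray(y_true), np.asarray(y_pred)]))


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(y_true == y_pred))


def balanced_accuracy(y_true, y_pred, strict: bool = True) -> float:
    """Unweighted mean of per-class recall.

    With ``strict`` (default), a predicted class absent from ``y_true``
    raises, since its recall is undefined; the model benchmark relaxes
    this because extra predicted classes do not affect the true-class
    recalls.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    true_classes = np.unique(y_true)
    if strict:
        extra = np.setdiff1d(np.unique(y_pred), true_classes)
        if extra.size:
            raise ValueError(f"predicted classes absent from y_true: {extra.tolist()}")
    labels = _labels_union(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    support = cm.sum(axis=1)
    present = support > 0
    recall = cm.diagonal()[present] / support[present]
    return float(recall.mean())


def per_class_metrics(y_true, y_pred) -> pd.DataFrame:
    """Per-class precision, recall, F1 and support from the confusion matrix.

    A class that is never predicted gets precision 0 with a warning
    (zero-division convention), so rare classes never crash a report.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = _labels_union(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    tp = cm.diagonal().astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    if np.any(pred_tot == 0):
        never = labels[pred_tot == 0]
        warnings.warn(
            f"classes never predicted, precision reported as 0: {never.tolist()}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.where(true_tot > 0, true_tot, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame(
        {
            "label": labels,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": true_tot.astype(int),
        }
    )


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 (the multiclass F1 the report uses)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = per_class_metrics(y_true, y_pred)
    total = m["support"].sum()
    if total == 0:
        raise ValueError("empty label vectors")
    return float((m["f1"] * m["support"]).sum() / total)


def evaluate_holdout(
    model,
    eval_rows: pd.DataFrame,
    features: list[str] | None = None,
    task: str = "multiclass",
):
    """Score a trained model on the held-out evaluation trees.

    Returns (confusion matrix DataFrame with true labels as rows,
    per-class metrics DataFrame, summary dict with accuracy / balanced
    accuracy / weighted F1). ``task`` must match the labelling the model
    was trained on.
    """
    features = features or DEFAULT_FEATURES
    y_true = eval_rows["target_label"].to_numpy()
    if task == "binary":
        y_true = binarize_target(y_true)
    y_pred = np.asarray(model.predict(eval_rows[features].to_numpy()))
    labels = _labels_union(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    cm_df = pd.DataFrame(
        cm,
        index=[f"true_{l}" for l in labels],
        columns=[f"pred_{l}" for l in labels],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = per_class_metrics(y_true, y_pred)
    summary = {
        "accuracy": accuracy(y_true, y_pred),
        "balanced_accuracy": balanced_accuracy(y_true, y_pred, strict=False),
        "weighted_f1": weighted_f1(y_true, y_pred),
    }
    return cm_df, per_class, summary


# ---------------------------------------------------------------------------
# model suite


def default_model_suite(seed: int = 0) -> dict[str, object]:
    """Classifier suite at library-default hyperparameters.

    Includes the four mandatory members — a gradient-boosted decision
    tree, Gaussian naive Bayes, nearest centroid, and an MLP with hidden
    layers of 64 and 128 units — plus four other common defaults.
    """
    from lightgbm import LGBMClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeClassifier

    return {
        "LGBMClassifier": LGBMClassifier(random_state=seed, verbose=-1),
        "GaussianNB": GaussianNB(),
        "NearestCentroid": NearestCentroid(),
        "MLP_64_128": make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64, 128), random_state=seed,
                          max_iter=300),
        ),
        "LogisticRegression": make_pipeline(
            StandardScaler(), LogisticRegression(random_state=seed)
        ),
        "RandomForestClassifier": RandomForestClassifier(random_state=seed),
        "DecisionTreeClassifier": DecisionTreeClassifier(random_state=seed),
        "KNeighborsClassifier": KNeighborsClassifier(),
    }


@dataclass
class ModelScore:
    name: str
    task: str
    accuracy: float
    balanced_accuracy: float
    f1: float
    fit_seconds: float


@dataclass
class BenchmarkReport:
    """Scores per model, sorted by descending total score, plus the fitted models."""

    task: str
    scores: pd.DataFrame
    models: dict[str, object] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def run_model_suite(
    split: DatasetSplit,
    task: str = "binary",
    features: list[str] | None = None,
    seed: int = 0,
    models: dict[str, object] | None = None,
) -> BenchmarkReport:
    """Train every suite member on the train rows and score on the test rows.

    ``task`` is "binary" (will the cylinder resprout) or "multiclass"
    (exact shoot count 0..4). Models whose training target collapses to a
    single class are skipped with a logged reason. The report is sorted
    by descending accuracy + balanced accuracy + F1, mirroring the usual
    benchmark ordering.
    """
    if task not in ("binary", "multiclass"):
        raise ValueError("task must be 'binary' or 'multiclass'")
    if len(split.train) == 0 or len(split.test) == 0:
        raise ValueError("split has empty train or test partition")
    features = features or DEFAULT_FEATURES
    models = models if models is not None else default_model_suite(seed)

    def target(rows: pd.DataFrame) -> np.ndarray:
        t = rows["target_label"].to_numpy()
        return binarize_target(t) if task == "binary" else t.astype(int)

    X_train = split.train[features].to_numpy()
    y_train = target(split.train)
    X_test = split.test[features].to_numpy()
    y_test = target(split.test)

    rows, fitted, skipped = [], {}, {}
    for name, model in models.items():
        if np.unique(y_train).size < 2:
            skipped[name] = "degenerate single-class training target"
            continue
        t0 = time.perf_counter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_train, y_train)
        dt = time.perf_counter() - t0
        y_pred = np.asarray(model.predict(X_test))
        rows.append(
            ModelScore(
                name=name,
                task=task,
                accuracy=accuracy(y_test, y_pred),
                balanced_accuracy=balanced_accuracy(y_test, y_pred, strict=False),
                f1=weighted_f1(y_test, y_pred),
                fit_seconds=dt,
            )
        )
        fitted[name] = model
    df = pd.DataFrame([vars(r) for r in rows])
    if len(df):
        df["total"] = df["accuracy"] + df["balanced_accuracy"] + df["f1"]
        df = df.sort_values("total", ascending=False).reset_index(drop=True)
    return BenchmarkReport(task=task, scores=df, models=fitted, skipped=skipped)
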