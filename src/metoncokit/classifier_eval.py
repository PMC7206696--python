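"""Random-forest training, validation schemes, and feature diagnostics.

A random forest is trained per prediction target (differential expression,
copy-number class, survival class) on the gene × cell-line feature matrix.
Four validation schemes are provided: stratified k-fold cross-validation,
a stratified 70/30 holdout, leave-one-cell-line-out, and
leave-one-feature-set-out (dropping each of the topological / dynamic /
biochemical feature categories in turn).  Preprocessing that can leak
evaluation information — robust scaling and minority-class oversampling —
is fit inside training folds only by default; an explicit ``paper_mode``
applies both to the full matrix before splitting for comparison, at the
cost of duplicated rows straddling the split.

Significance of an observed accuracy is assessed against a null built by
re-running the evaluation on label permutations; both a normal-fit
upper-tail p-value and the empirical ``(1 + #null ≥ obs)/(n + 1)`` are
reported.  Feature diagnostics are Gini importances (with ranks) and the
direction of the Pearson correlation between each feature and the
ordinally encoded class (+ above R = 0.6, − below −0.6, ~ otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .feature_table import FeatureMatrix, random_oversample, robust_scale
from .target_labels import DOWN, NEUTRAL, UP, encode_label, reconcile_labels

__all__ = [
    "DEFAULT_FOREST_PARAMS",
    "TrainedModel",
    "EvaluationReport",
    "train_random_forest",
    "k_fold_cv",
    "holdout_validation",
    "leave_one_cell_line_out",
    "leave_one_feature_set_out",
    "compute_metrics",
    "permutation_significance",
    "feature_target_correlation",
    "importance_report",
    "gene_level_aggregate",
]

# 500 unbounded-depth trees with sqrt(n_features) per split.
DEFAULT_FOREST_PARAMS: dict = {
    "n_estimators": 500,
    "max_depth": None,
    "max_features": "sqrt",
}


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    target: str
    hyperparameters: dict
    seed: int

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(frame[list(self.feature_names)])


@dataclass
class EvaluationReport:
    scheme: str
    target: str
    classes: tuple[str, ...]
    confusion_matrix: list[list[int]]
    accuracy: float
    per_class: dict[str, dict[str, float]]
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    auroc: float
    n_eval: int
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "target": self.target,
            "classes": list(self.classes),
            "confusion_matrix": self.confusion_matrix,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "n_eval": self.n_eval,
            "seed": self.seed,
            "extras": self.extras,
        }


def _xy(matrix: FeatureMatrix, target: str) -> tuple[pd.DataFrame, pd.Series]:
    if matrix.labels is None or target not in matrix.labels.columns:
        raise ValueError(f"matrix carries no labels for target {target!r}")
    return matrix.data, matrix.labels[target]


def train_random_forest(
    x: pd.DataFrame,
    y: pd.Series,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
    target: str = "",
    param_grid: Mapping | None = None,
) -> TrainedModel:
    """Fit a seeded random forest; optional grid search keeps the best fit.

    With *param_grid*, a 3-fold stratified grid search is run and the best
    parameters are recorded in ``hyperparameters`` alongside the defaults.
    """
    if y.nunique() < 2:
        raise ValueError("training labels contain fewer than two classes")
    params = {**DEFAULT_FOREST_PARAMS, **(hyperparameters or {})}
    forest = RandomForestClassifier(random_state=seed, **params)
    if param_grid:
        search = GridSearchCV(forest, dict(param_grid), cv=3, scoring="accuracy")
        search.fit(x, y)
        forest = search.best_estimator_
        params = {**params, **search.best_params_}
    else:
        forest.fit(x, y)
    return TrainedModel(forest, tuple(x.columns), target, params, seed)


def _fit_and_score(
    x_train: pd.DataFrame,
    y_train: pd.Series,
    x_eval: pd.DataFrame,
    forest_params: Mapping | None,
    seed: int,
    preprocess: bool,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Scale + oversample on the training split only, fit, score the eval split."""
    if preprocess:
        x_train, scaling = robust_scale(x_train)
        x_eval = (x_eval - scaling["center"]) / scaling["iqr"]
        x_train, y_train = random_oversample(x_train, y_train, seed)
    model = train_random_forest(x_train, y_train, forest_params, seed=seed)
    preds = model.forest.predict(x_eval)
    probas = model.forest.predict_proba(x_eval)
    return preds, probas, tuple(model.forest.classes_)


def _pooled_report(
    scheme: str,
    target: str,
    classes: Sequence[str],
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None,
    seed: int,
) -> EvaluationReport:
    confusion = _confusion(y_true, y_pred, classes)
    return compute_metrics(
        confusion, classes, y_true=y_true, scores=scores,
        scheme=scheme, target=target, seed=seed,
    )


def k_fold_cv(
    matrix: FeatureMatrix,
    target: str,
    k: int = 10,
    seed: int = 0,
    forest_params: Mapping | None = None,
    paper_mode: bool = False,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with a pooled out-of-fold confusion
    matrix.  ``k == n_rows`` degenerates to (unstratified) leave-one-out."""
    x, y = _xy(matrix, target)
    classes = tuple(sorted(y.unique()))
    if paper_mode:
        x, scaling = robust_scale(x)
        x, y = random_oversample(x, y, seed)
        x, y = x.reset_index(drop=True), y.reset_index(drop=True)
    if k == len(x):
        folds = [(np.delete(np.arange(len(x)), i), np.array([i])) for i in range(len(x))]
    else:
        min_class = y.value_counts().min()
        if min_class < k:
            raise ValueError(
                f"a class has only {min_class} members; use k <= {min_class}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(x, y))
    y_true, y_pred, scores = [], [], []
    for i, (train_idx, eval_idx) in enumerate(folds):
        preds, probas, fold_classes = _fit_and_score(
            x.iloc[train_idx], y.iloc[train_idx], x.iloc[eval_idx],
            forest_params, seed + i, preprocess=not paper_mode,
        )
        y_true.append(np.asarray(y.iloc[eval_idx]))
        y_pred.append(preds)
        scores.append(_align_scores(probas, fold_classes, classes))
    return _pooled_report(
        "kfold", target, classes,
        np.concatenate(y_true), np.concatenate(y_pred), np.vstack(scores), seed,
    )


def _align_scores(
    probas: np.ndarray, fold_classes: tuple, classes: Sequence[str]
) -> np.ndarray:
    """Expand fold probabilities to the full class list (absent classes → 0)."""
    out = np.zeros((probas.shape[0], len(classes)))
    for j, cls in enumerate(fold_classes):
        out[:, list(classes).index(cls)] = probas[:, j]
    return out


def holdout_validation(
    matrix: FeatureMatrix,
    target: str,
    fraction: float = 0.3,
    seed: int = 0,
    forest_params: Mapping | None = None,
    paper_mode: bool = False,
) -> EvaluationReport:
    """Single stratified split: train on 1 − fraction, evaluate on fraction."""
    x, y = _xy(matrix, target)
    classes = tuple(sorted(y.unique()))
    if paper_mode:
        x, _ = robust_scale(x)
        x, y = random_oversample(x, y, seed)
        x, y = x.reset_index(drop=True), y.reset_index(drop=True)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=fraction, random_state=seed, stratify=y
    )
    preds, probas, fold_classes = _fit_and_score(
        x_tr, y_tr, x_te, forest_params, seed, preprocess=not paper_mode
    )
    return _pooled_report(
        "holdout", target, classes, np.asarray(y_te), preds,
        _align_scores(probas, fold_classes, classes), seed,
    )


def leave_one_cell_line_out(
    matrix: FeatureMatrix,
    target: str,
    seed: int = 0,
    forest_params: Mapping | None = None,
) -> dict[str, EvaluationReport]:
    """Hold out each cell line in turn, training on the remaining lines."""
    x, y = _xy(matrix, target)
    lines = sorted(x.index.get_level_values("cell_line").unique())
    if len(lines) < 2:
        raise ValueError("leave-one-cell-line-out requires at least two cell lines")
    classes = tuple(sorted(y.unique()))
    reports = {}
    for line in lines:
        held = x.index.get_level_values("cell_line") == line
        preds, probas, fold_classes = _fit_and_score(
            x[~held], y[~held], x[held], forest_params, seed, preprocess=True
        )
        reports[line] = _pooled_report(
            f"loco:{line}", target, classes, np.asarray(y[held]), preds,
            _align_scores(probas, fold_classes, classes), seed,
        )
    return reports


def leave_one_feature_set_out(
    matrix: FeatureMatrix,
    target: str,
    seed: int = 0,
    forest_params: Mapping | None = None,
    k: int = 10,
    evaluator: Callable[..., EvaluationReport] | None = None,
) -> dict[str, EvaluationReport]:
    """Drop each feature category (topological / dynamic / biochemical) in
    turn and re-evaluate; the accuracy drop measures the category's impact."""
    evaluate = evaluator or (lambda m: k_fold_cv(m, target, k=k, seed=seed,
                                                 forest_params=forest_params))
    reports = {}
    for category in ("topological", "dynamic", "biochemical"):
        drop = matrix.schema.of_category(category)
        if not drop:
            warnings.warn(f"feature category {category!r} has no features; skipped")
            continue
        keep = [n for n in matrix.schema.names if n not in drop]
        sub = FeatureMatrix(
            data=matrix.data[keep],
            schema=_subset_schema(matrix.schema, keep),
            labels=matrix.labels,
            code_maps={c: m for c, m in matrix.code_maps.items() if c in keep},
            scaling=None,
        )
        reports[category] = evaluate(sub)
    return reports


def _subset_schema(schema, keep: list[str]):
    from .feature_table import FeatureSchema

    return FeatureSchema(
        tuple(keep),
        {n: schema.category[n] for n in keep},
        {n: schema.kind[n] for n in keep},
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _confusion(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[str]
) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return mat


def compute_metrics(
    confusion: np.ndarray | Sequence[Sequence[int]],
    classes: Sequence[str],
    y_true: np.ndarray | None = None,
    scores: np.ndarray | None = None,
    scheme: str = "",
    target: str = "",
    seed: int = 0,
) -> EvaluationReport:
    """Metric bundle from a confusion matrix (rows = true, cols = predicted).

    Per-class one-vs-rest TP/TN/FP/FN give precision, recall, specificity,
    and F1 (macro-averaged; classes with no positive predictions contribute
    precision 0).  MCC is the multiclass covariance form.  AUROC is
    one-vs-rest macro over class-probability *scores* when provided.
    """
    mat = np.asarray(confusion, dtype=float)
    total = mat.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(mat) / total)

    per_class: dict[str, dict[str, float]] = {}
    precisions, recalls, specificities, f1s = [], [], [], []
    for i, cls in enumerate(classes):
        tp = mat[i, i]
        fn = mat[i, :].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_class[cls] = {
            "tp": float(tp), "tn": float(tn), "fp": float(fp), "fn": float(fn),
            "precision": float(precision), "recall": float(recall),
            "specificity": float(specificity), "f1": float(f1),
        }
        precisions.append(precision)
        recalls.append(recall)
        specificities.append(specificity)
        f1s.append(f1)

    # Multiclass MCC, covariance form over the confusion matrix.
    t_k = mat.sum(axis=1)
    p_k = mat.sum(axis=0)
    cov = np.trace(mat) * total - float(t_k @ p_k)
    denom = np.sqrt(total**2 - float(p_k @ p_k)) * np.sqrt(
        total**2 - float(t_k @ t_k)
    )
    mcc = float(cov / denom) if denom > 0 else 0.0

    auroc = float("nan")
    if scores is not None and y_true is not None:
        try:
            auroc = float(
                roc_auc_score(
                    y_true, scores, multi_class="ovr", average="macro",
                    labels=list(classes),
                )
            )
        except ValueError:
            pass  # e.g. a class absent from y_true

    return EvaluationReport(
        scheme=scheme,
        target=target,
        classes=tuple(classes),
        confusion_matrix=[[int(v) for v in row] for row in np.asarray(confusion)],
        accuracy=accuracy,
        per_class=per_class,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        specificity=float(np.mean(specificities)),
        f1=float(np.mean(f1s)),
        mcc=mcc,
        auroc=auroc,
        n_eval=int(total),
        seed=seed,
    )


def permutation_significance(
    matrix: FeatureMatrix,
    target: str,
    n_iter: int = 1000,
    seed: int = 0,
    forest_params: Mapping | None = None,
    evaluator: Callable[[FeatureMatrix], EvaluationReport] | None = None,
) -> dict[str, float]:
    """Label-permutation null for the evaluation accuracy.

    The evaluator (default: stratified 70/30 holdout) is re-run on *n_iter*
    label shuffles.  Returns the observed accuracy, the null mean/sd, the
    z-score, the upper-tail normal-fit p, and the empirical
    ``(1 + #null ≥ obs)/(n_iter + 1)``.
    """
    if n_iter < 2:
        raise ValueError("permutation null needs n_iter >= 2")
    evaluate = evaluator or (
        lambda m: holdout_validation(m, target, seed=seed, forest_params=forest_params)
    )
    observed = evaluate(matrix).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        shuffled = matrix.labels.copy()
        shuffled[target] = rng.permutation(shuffled[target].to_numpy())
        null[i] = evaluate(
            FeatureMatrix(matrix.data, matrix.schema, shuffled,
                          matrix.code_maps, matrix.scaling)
        ).accuracy
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("inf")
    p_normal = float(stats.norm.sf(z)) if np.isfinite(z) else 0.0
    p_empirical = float((1 + np.sum(null >= observed)) / (n_iter + 1))
    return {
        "observed_accuracy": float(observed),
        "null_mean": mean,
        "null_sd": sd,
        "z_score": float(z),
        "p_normal": p_normal,
        "p_empirical": p_empirical,
        "n_iter": n_iter,
    }


# ---------------------------------------------------------------------------
# Feature diagnostics
# ---------------------------------------------------------------------------


def feature_target_correlation(
    x: pd.DataFrame, y: pd.Series, threshold: float = 0.6
) -> pd.DataFrame:
    """Pearson R of each feature against the ordinally encoded class.

    Classes are encoded DOWN/LOSS → −1, NEUTRAL → 0, UP/GAIN → +1; the
    sign column is '+' for R > threshold, '−' for R < −threshold, else '~'.
    Zero-variance features get '~' with a warning.
    """
    encoded = np.array([encode_label(v) for v in y], dtype=float)
    rows = []
    for col in x.columns:
        values = x[col].to_numpy(dtype=float)
        if np.std(values) == 0 or np.std(encoded) == 0:
            warnings.warn(f"zero-variance feature {col!r}; correlation undefined")
            r = 0.0
        else:
            r = float(np.corrcoef(values, encoded)[0, 1])
        sign = "+" if r > threshold else "-" if r < -threshold else "~"
        rows.append({"feature": col, "r": r, "sign": sign})
    return pd.DataFrame(rows).set_index("feature")


def importance_report(
    model: TrainedModel, x: pd.DataFrame, y: pd.Series, threshold: float = 0.6
) -> pd.DataFrame:
    """Gini importances with ranks (1 = most important) and correlation signs."""
    importances = model.forest.feature_importances_
    order = np.argsort(-importances, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    corr = feature_target_correlation(x, y, threshold)
    frame = pd.DataFrame(
        {
            "gini_importance": importances,
            "rank": ranks,
            "sign": [corr.loc[c, "sign"] for c in model.feature_names],
        },
        index=pd.Index(model.feature_names, name="feature"),
    )
    return frame.sort_values("rank")


def gene_level_aggregate(
    rows: pd.DataFrame, labels: Sequence[str]
) -> tuple[str, pd.Series]:
    """Collapse one gene's per-cell-line rows to a single summary.

    The label is the plurality vote over cell lines; on a tie the label is
    taken from the median of the ordinal encodings (so {UP, DOWN} resolves
    to NEUTRAL).  Numeric features are summarized by their median.
    """
    if len(rows) == 0:
        raise ValueError("no rows to aggregate")
    labels = list(labels)
    label = reconcile_labels(labels)
    if label == NEUTRAL and NEUTRAL not in labels:
        med = float(np.median([encode_label(v) for v in labels]))
        label = {-1: DOWN, 0: NEUTRAL, 1: UP}.get(int(round(med)), NEUTRAL)
    return label, rows.median(axis=0)
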