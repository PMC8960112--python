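"""Nested cross-validated disease classification with permutation importance.

Model selection follows the multi-modal setup of expert-in-the-loop cardiac
cohorts: an outer stratified k-fold (default 8) estimates generalization;
an inner stratified k-fold per outer-training set selects, by mean
accuracy, among five classifier families (random forest, extra trees,
gradient boosting, RBF-SVM, logistic regression), their hyperparameter
grids, and candidate *feature-class* subsets (shape, first-order, GLCM,
NGTDM, cardiac, clinical groups rather than single columns).  Median
imputation and standardization are fitted on training folds only.

Permutation feature importance is the model-agnostic shuffle procedure:
importance = baseline score minus the mean score after permuting one
feature column, repeated R times.

``improvement_loop`` composes the whole pipeline: extract features, score
the cohort, build the outlier worklist, replace flagged sessions with
reference masks (a simulated expert correction), re-extract and re-score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features.table import FeatureTable

log = logging.getLogger(__name__)

FAMILIES = ("random_forest", "extra_trees", "gradient_boosting", "svm_rbf", "logistic")

#: Declared hyperparameter domains (validation, not the search grid).
HYPERPARAMETER_DOMAINS: dict[str, dict] = {
    "random_forest": {
        "n_estimators": (1, 2000), "max_depth": (1, 64), "criterion": {"gini", "entropy"},
        "min_samples_leaf": (1, 100), "min_samples_split": (2, 100),
    },
    "extra_trees": {
        "n_estimators": (1, 2000), "max_depth": (1, 64), "criterion": {"gini", "entropy"},
        "min_samples_leaf": (1, 100), "min_samples_split": (2, 100),
    },
    "gradient_boosting": {
        "n_estimators": (1, 2000), "max_depth": (1, 16), "learning_rate": (1e-4, 1.0),
    },
    "svm_rbf": {"C": (1e-4, 1e4), "gamma": (1e-6, 1e3)},
    "logistic": {"C": (1e-4, 1e4)},
}

#: Small, documented default search grid (config-overridable).  Candidates
#: are ordered simpler-first; inner-loop ties keep the earlier candidate.
DEFAULT_GRID: dict[str, list[dict]] = {
    "logistic": [{"C": 1.0}],
    "svm_rbf": [{"C": 1.0}, {"C": 10.0}],
    "random_forest": [{"n_estimators": 60, "max_depth": 6}],
    "extra_trees": [{"n_estimators": 60, "max_depth": 6}],
    "gradient_boosting": [{"n_estimators": 40, "max_depth": 2}],
}

LIGHT_GRID: dict[str, list[dict]] = {
    "random_forest": [{"n_estimators": 80, "max_depth": 6}],
}

#: Candidate feature-class subsets searched in the inner loop (group names
#: resolved against the table schema; missing groups are dropped).
DEFAULT_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("shape", "cardiac"),
    ("shape", "cardiac", "clinical"),
    ("glcm", "ngtdm", "first_order"),
    ("shape", "cardiac", "glcm", "ngtdm", "first_order", "clinical"),
)


@dataclass(frozen=True)
class ModelConfig:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    impute: bool = True
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; allowed: {FAMILIES}")
        domain = HYPERPARAMETER_DOMAINS[self.family]
        for name, value in self.hyperparameters.items():
            if name not in domain:
                raise ValueError(f"{self.family}: unknown hyperparameter {name!r}")
            allowed = domain[name]
            if isinstance(allowed, set):
                if value not in allowed:
                    raise ValueError(f"{self.family}.{name}={value!r} not in {sorted(allowed)}")
            elif value is None:
                if name != "max_depth":
                    raise ValueError(f"{self.family}.{name} may not be None")
            elif not (allowed[0] <= value <= allowed[1]):
                raise ValueError(
                    f"{self.family}.{name}={value!r} outside domain {allowed}")


def _make_estimator(config: ModelConfig):
    hp = dict(config.hyperparameters)
    seed = config.seed
    if config.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if config.family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **hp)
    if config.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if config.family == "svm_rbf":
        hp.setdefault("gamma", "scale")
        return SVC(kernel="rbf", random_state=seed, **hp)
    return LogisticRegression(max_iter=5000, random_state=seed, **hp)


def make_pipeline(config: ModelConfig) -> Pipeline:
    config.validate()
    steps = []
    if config.impute:
        steps.append(("impute", SimpleImputer(strategy="median")))
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _make_estimator(config)))
    return Pipeline(steps)


@dataclass
class FittedModel:
    """A fitted preprocessing+classifier pipeline bound to its columns."""

    pipeline: Pipeline
    feature_columns: list[str]
    classes_: np.ndarray
    config: ModelConfig

    def predict(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(_X(table, self.feature_columns))

    def class_scores(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        """Per-class scores: probabilities where native, else min-max
        rescaled decision-function values."""
        X = _X(table, self.feature_columns)
        return _scores_of(self.pipeline, X)

    def score(self, table: FeatureTable | pd.DataFrame) -> float:
        df = _frame(table)
        return float(np.mean(self.predict(df) == df["class_label"].to_numpy()))


def _frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, FeatureTable) else table


def _X(table, columns: list[str]) -> pd.DataFrame:
    return _frame(table)[columns].apply(pd.to_numeric, errors="coerce")


def _scores_of(pipeline: Pipeline, X) -> np.ndarray:
    if hasattr(pipeline, "predict_proba") and hasattr(pipeline[-1], "predict_proba"):
        return pipeline.predict_proba(X)
    scores = pipeline.decision_function(X)
    if scores.ndim == 1:
        scores = np.stack([-scores, scores], axis=1)
    lo = scores.min(axis=0, keepdims=True)
    hi = scores.max(axis=0, keepdims=True)
    return (scores - lo) / np.where(hi > lo, hi - lo, 1.0)


def _resolve_subsets(table: FeatureTable, subsets) -> list[tuple[tuple[str, ...], list[str]]]:
    groups = table.columns_by_group()
    resolved = []
    seen = set()
    for subset in subsets:
        cols: list[str] = []
        names = tuple(g for g in subset if g in groups)
        for g in names:
            cols.extend(groups[g])
        key = tuple(cols)
        if cols and key not in seen:
            seen.add(key)
            resolved.append((names, cols))
    if not resolved:
        resolved = [(("all",), table.feature_columns)]
    return resolved


@dataclass
class CVResult:
    outer_scores: list[float]
    selected: list[dict]
    confusion_matrix: np.ndarray
    class_names: list[str]
    accuracy: float
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    per_class_auc: dict[str, float]
    macro_auc: float
    y_true: np.ndarray
    y_pred: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "outer_scores": self.outer_scores,
            "macro_auc": self.macro_auc,
            "per_class_auc": self.per_class_auc,
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_names": self.class_names,
            "selected": self.selected,
        }


def _metrics_from_predictions(y_true, y_pred, scores, class_names) -> dict:
    cm = sk_confusion_matrix(y_true, y_pred, labels=class_names)
    accuracy = float(np.trace(cm)) / float(cm.sum()) if cm.sum() else float("nan")
    precision, recall, auc = {}, {}, {}
    for k, cls in enumerate(class_names):
        col = cm[:, k].sum()
        row = cm[k, :].sum()
        precision[cls] = float(cm[k, k] / col) if col else float("nan")
        recall[cls] = float(cm[k, k] / row) if row else float("nan")
        binary = (np.asarray(y_true) == cls).astype(int)
        if scores is not None and 0 < binary.sum() < len(binary):
            auc[cls] = float(roc_auc_score(binary, scores[:, k]))
        else:
            auc[cls] = float("nan")
    finite = [v for v in auc.values() if np.isfinite(v)]
    macro_auc = float(np.mean(finite)) if finite else float("nan")
    return {"confusion_matrix": cm, "accuracy": accuracy, "precision": precision,
            "recall": recall, "auc": auc, "macro_auc": macro_auc}


def _inner_accuracy(config: ModelConfig, X, y, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        pipe = make_pipeline(config)
        pipe.fit(X.iloc[tr], y[tr])
        scores.append(float(np.mean(pipe.predict(X.iloc[te]) == y[te])))
    return float(np.mean(scores))


def nested_cv(
    table: FeatureTable,
    grid: dict[str, list[dict]] | None = None,
    outer_folds: int = 8,
    inner_folds: int = 8,
    seed: int = 0,
    subsets=DEFAULT_SUBSETS,
) -> CVResult:
    """Nested stratified CV with inner model/feature-class selection.

    The inner loop grid-searches classifier families x hyperparameters x
    feature-class subsets by mean inner accuracy (ties keep the simpler,
    earlier candidate); the winning candidate is refitted on the outer
    training set and evaluated on the held-out outer fold.  Outer test
    predictions are pooled into one confusion matrix.  Deterministic given
    ``seed``.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    df = _frame(table)
    if df["class_label"].isna().any():
        raise ValueError("all rows need a class label")
    y = df["class_label"].to_numpy()
    class_names = sorted(np.unique(y))
    if len(class_names) < 2:
        raise ValueError("classification needs >= 2 classes")
    min_count = int(pd.Series(y).value_counts().min())
    if min_count < 2:
        raise ValueError("every class needs >= 2 cases for stratified CV")
    if min_count < outer_folds:
        new_outer = max(2, min_count)
        warnings.warn(f"reducing outer folds {outer_folds} -> {new_outer} "
                      f"(smallest class has {min_count} cases)")
        outer_folds = new_outer
    resolved_subsets = _resolve_subsets(table, subsets)
    candidates = [
        (ModelConfig(family=family, hyperparameters=hp, seed=seed), names, cols)
        for family, hps in grid.items() if family in FAMILIES
        for hp in hps
        for names, cols in resolved_subsets
    ]
    if not candidates:
        raise ValueError("empty search grid")

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    y_true_parts, y_pred_parts, score_parts = [], [], []
    outer_scores, selected = [], []
    X_full = _X(df, sorted({c for _, _, cols in candidates for c in cols}))
    for fold_idx, (tr, te) in enumerate(outer.split(X_full, y)):
        y_tr = y[tr]
        inner = min(inner_folds, int(pd.Series(y_tr).value_counts().min()))
        if len(candidates) == 1 or inner < 2:
            if inner < 2 and len(candidates) > 1:
                warnings.warn("outer-training fold too small for inner selection; "
                              "using the first grid candidate")
            best = candidates[0]
        else:
            best, best_score = None, -np.inf
            for cand in candidates:
                config, names, cols = cand
                acc = _inner_accuracy(config, X_full[cols].iloc[tr], y_tr, inner, seed)
                if acc > best_score:
                    best, best_score = cand, acc
        config, names, cols = best
        pipe = make_pipeline(config)
        pipe.fit(X_full[cols].iloc[tr], y_tr)
        pred = pipe.predict(X_full[cols].iloc[te])
        outer_scores.append(float(np.mean(pred == y[te])))
        selected.append({"fold": fold_idx, "family": config.family,
                         "hyperparameters": config.hyperparameters,
                         "feature_classes": list(names)})
        y_true_parts.append(y[te])
        y_pred_parts.append(pred)
        raw = _scores_of(pipe, X_full[cols].iloc[te])
        full = np.zeros((len(te), len(class_names)))
        for k, cls in enumerate(pipe.classes_):
            full[:, class_names.index(cls)] = raw[:, k]
        score_parts.append(full)

    y_true = np.concatenate(y_true_parts)
    y_pred = np.concatenate(y_pred_parts)
    scores = np.vstack(score_parts)
    m = _metrics_from_predictions(y_true, y_pred, scores, class_names)
    return CVResult(
        outer_scores=outer_scores,
        selected=selected,
        confusion_matrix=m["confusion_matrix"],
        class_names=list(class_names),
        accuracy=m["accuracy"],
        per_class_precision=m["precision"],
        per_class_recall=m["recall"],
        per_class_auc=m["auc"],
        macro_auc=m["macro_auc"],
        y_true=y_true,
        y_pred=y_pred,
    )


def fit_final(table: FeatureTable, config: ModelConfig,
              feature_columns: list[str] | None = None) -> FittedModel:
    """Fit preprocessing + classifier on the full table (training split)."""
    config.validate()
    df = _frame(table)
    columns = feature_columns or (
        table.feature_columns if isinstance(table, FeatureTable)
        else [c for c in df.columns if c not in ("row_id", "case_id", "session_id",
                                                 "class_label")])
    pipe = make_pipeline(config)
    X = _X(df, columns)
    y = df["class_label"].to_numpy()
    pipe.fit(X, y)
    return FittedModel(pipeline=pipe, feature_columns=list(columns),
                       classes_=pipe.classes_, config=config)


def evaluate(model: FittedModel, test_table: FeatureTable | pd.DataFrame) -> dict:
    """Accuracy, per-class precision/recall, confusion matrix and OvR AUC."""
    df = _frame(test_table)
    y_true = df["class_label"].to_numpy()
    y_pred = model.predict(df)
    class_names = [str(c) for c in model.classes_]
    scores = model.class_scores(df)
    m = _metrics_from_predictions(y_true, y_pred, scores, class_names)
    return {
        "accuracy": m["accuracy"],
        "confusion_matrix": m["confusion_matrix"],
        "class_names": class_names,
        "per_class_precision": m["precision"],
        "per_class_recall": m["recall"],
        "per_class_auc": m["auc"],
        "macro_auc": m["macro_auc"],
    }


@dataclass
class ImportanceReport:
    table: pd.DataFrame          # feature, baseline, mean_permuted, importance, sd
    baseline: float

    @property
    def ranking(self) -> list[str]:
        return list(self.table["feature"])

    def top(self, n: int) -> list[str]:
        return self.ranking[:n]


def permutation_importance_report(
    model: FittedModel,
    table: FeatureTable | pd.DataFrame,
    repeats: int = 10,
    seed: int = 0,
    scoring: str = "accuracy",
) -> ImportanceReport:
    """Permutation feature importance: baseline minus mean permuted score.

    One feature column is shuffled at a time (others fixed), the model is
    re-scored, and the drop from the baseline score is averaged over
    ``repeats`` shuffles.  Deterministic given ``seed``; an all-constant
    feature has importance exactly 0.

    With heavily correlated feature panels (e.g. four aggregates of the
    same curve) accuracy barely moves when a single column is shuffled;
    ``scoring="neg_log_loss"`` is the probability-sensitive choice that
    still ranks such features meaningfully.
    """
    from sklearn.inspection import permutation_importance as sk_permutation_importance
    from sklearn.metrics import get_scorer

    df = _frame(table)
    X = _X(df, model.feature_columns)
    y = df["class_label"].to_numpy()
    baseline = float(get_scorer(scoring)(model.pipeline, X, y))
    result = sk_permutation_importance(
        model.pipeline, X, y, scoring=scoring,
        n_repeats=repeats, random_state=seed)
    out = pd.DataFrame({
        "feature": model.feature_columns,
        "baseline": baseline,
        "mean_permuted": baseline - result.importances_mean,
        "importance": result.importances_mean,
        "sd": result.importances_std,
    })
    out = out.sort_values(["importance", "feature"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return ImportanceReport(table=out, baseline=baseline)


def improvement_loop(
    cohort,
    truths,
    seed: int = 0,
    feature_set: str = "fast",
    grid: dict | None = None,
    outer_folds: int = 5,
    subsets=(("shape", "cardiac", "glcm", "ngtdm", "first_order"),),
) -> dict:
    """One expert-in-the-loop round: score, flag, correct, re-score.

    Extracts features, estimates classification accuracy by (nested) CV,
    builds the outlier worklist from the mask-based rules, replaces every
    flagged session with the reference mask from the truth records (the
    simulated expert correction, recorded as a ``corrected`` session), then
    re-extracts and re-scores.  Corrected cases are always a subset of the
    flagged cases.
    """
    from .curation import correct_with_reference
    from .datamodel import iter_cases
    from .features.table import extract_feature_table
    from .qc import build_worklist, feature_outliers, mask_outlier_report

    grid = grid if grid is not None else LIGHT_GRID
    truth_by_case = {t.case_id: t for t in truths}

    table_before = extract_feature_table(cohort, feature_set=feature_set)
    res_before = nested_cv(table_before, grid=grid, outer_folds=outer_folds,
                           inner_folds=3, seed=seed, subsets=subsets)

    reports = [mask_outlier_report(cohort), feature_outliers(table_before)]
    worklist = build_worklist(*reports)
    flagged = [item.case_id for item in worklist]

    corrected = []
    for case in iter_cases(cohort):
        if case.case_id not in flagged:
            continue
        truth = truth_by_case.get(case.case_id)
        if truth is None:
            continue
        session = case.latest_session()
        new = correct_with_reference(case, session, truth.true_mask)
        if new is not session:
            corrected.append(case.case_id)

    table_after = extract_feature_table(cohort, feature_set=feature_set)
    res_after = nested_cv(table_after, grid=grid, outer_folds=outer_folds,
                          inner_folds=3, seed=seed, subsets=subsets)
    return {
        "accuracy_before": res_before.accuracy,
        "accuracy_after": res_after.accuracy,
        "macro_auc_before": res_before.macro_auc,
        "macro_auc_after": res_after.macro_auc,
        "flagged_cases": flagged,
        "corrected_cases": corrected,
        "n_corrected": len(corrected),
    }
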