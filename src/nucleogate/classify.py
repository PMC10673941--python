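"""Random-forest classification of damage/death subpopulations.

The classifier must predict the four marker-gated subpopulations from
nuclear morphology and chromatin texture alone, so any feature column
derived from the gating markers themselves is rejected up front.  Evaluation
is stratified five-fold cross-validation with balanced accuracy
(macro-averaged recall); chance level for four balanced classes is 25%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .synthetic import SUBPOP_ORDER, Subpopulation

#: substrings that mark a feature as derived from the gating markers
MARKER_BLACKLIST = ("gamma", "h2ax", "draq7")

#: metadata columns that are silently ignored if present
NON_FEATURE_COLUMNS = ("nucleus_id", "undefined", "subpop", "spheroid_id",
                       "cell_type", "row", "col")


class BlacklistedFeatureError(ValueError):
    """A marker-derived column was offered to the marker-free classifier."""


@dataclass
class ClassifierReport:
    """Cross-validation report for the subpopulation classifier."""

    class_names: list
    confusion: np.ndarray            # row-normalized, rows = true classes
    per_class_recall: dict
    balanced_accuracy: float
    feature_importances: pd.Series   # mean decrease in impurity, descending
    fold_assignments: np.ndarray
    n_samples: int
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Subpopulation classifier - stratified "
            f"{self.hyperparameters.get('n_folds', '?')}-fold CV "
            f"(n = {self.n_samples}, seed = {self.seed})",
            f"  balanced accuracy: {self.balanced_accuracy:.3f} "
            "(chance 0.250 for 4 balanced classes)",
            "  per-class recall:",
        ]
        for name, rec in self.per_class_recall.items():
            lines.append(f"    {name}: {rec:.3f}")
        lines.append("  top features (mean decrease in impurity):")
        for name, imp in self.feature_importances.head(5).items():
            lines.append(f"    {name}: {imp:.3f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "per_class_recall": self.per_class_recall,
            "balanced_accuracy": self.balanced_accuracy,
            "feature_importances": self.feature_importances.to_dict(),
            "fold_assignments": self.fold_assignments.tolist(),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "hyperparameters": self.hyperparameters,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _clean_features(features: pd.DataFrame,
                    enforce_blacklist: bool = True) -> pd.DataFrame:
    cols = [c for c in features.columns if c not in NON_FEATURE_COLUMNS]
    if enforce_blacklist:
        bad = [c for c in cols
               if any(tok in c.lower() for tok in MARKER_BLACKLIST)]
        if bad:
            raise BlacklistedFeatureError(
                f"marker-derived feature columns not allowed: {bad}")
    return features[cols]


def _validate_inputs(features: pd.DataFrame, labels, class_floor: int):
    labels = pd.Series([lab.value if isinstance(lab, Subpopulation)
                        else str(lab) for lab in labels])
    if len(labels) != len(features):
        raise ValueError("features and labels differ in length")
    counts = labels.value_counts()
    below = counts[counts < class_floor]
    if len(below):
        raise ValueError(
            f"classes below the {class_floor}-sample floor: "
            f"{below.to_dict()}")
    return labels


@dataclass
class SubpopulationClassifier:
    """Ensemble-of-trees subpopulation model with a fit/report surface."""

    n_trees: int = 500
    max_depth: int | None = None
    n_folds: int = 5
    class_floor: int = 100
    seed: int = 0
    enforce_blacklist: bool = True
    model_: RandomForestClassifier | None = None
    feature_columns_: list | None = None

    def fit(self, features: pd.DataFrame, labels,
            evaluate: bool = True) -> "ClassifierReport | None":
        """Cross-validate (optional) and fit the final model on all data."""
        X = _clean_features(features, self.enforce_blacklist)
        y = _validate_inputs(X, labels, self.class_floor if evaluate else 1)
        keep = ~X.isna().any(axis=1)          # undefined rows are excluded
        X, y = X.loc[keep], y.loc[keep.to_numpy()]
        report = None
        if evaluate:
            report = crossval_classify(
                X, y, n_folds=self.n_folds, n_trees=self.n_trees,
                max_depth=self.max_depth, seed=self.seed,
                class_floor=self.class_floor,
                enforce_blacklist=False)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            max_features="sqrt", random_state=self.seed, n_jobs=1)
        self.model_.fit(X.to_numpy(), y.to_numpy())
        self.feature_columns_ = list(X.columns)
        return report

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_subpop(self, features)


def crossval_classify(features: pd.DataFrame, labels, n_folds: int = 5,
                      n_trees: int = 500, max_depth: int | None = None,
                      seed: int = 0, class_floor: int = 100,
                      enforce_blacklist: bool = True) -> ClassifierReport:
    """Stratified k-fold CV; pooled out-of-fold predictions scored by
    balanced accuracy.  Deterministic given the seed."""
    X = _clean_features(features, enforce_blacklist)
    y = _validate_inputs(X, labels, class_floor)
    keep = ~X.isna().any(axis=1)
    X = X.loc[keep].reset_index(drop=True)
    y = y.loc[keep.to_numpy()].reset_index(drop=True)

    class_names = [sp.value for sp in SUBPOP_ORDER
                   if sp.value in set(y)] or sorted(set(y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=object)
    folds = np.full(len(y), -1, dtype=int)
    importances = np.zeros(X.shape[1])
    for k, (train, test) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_depth=max_depth, max_features="sqrt",
            random_state=seed + k, n_jobs=1)
        rf.fit(X.iloc[train].to_numpy(), y.iloc[train].to_numpy())
        oof[test] = rf.predict(X.iloc[test].to_numpy())
        folds[test] = k
        importances += rf.feature_importances_
    importances /= n_folds
    if importances.sum() > 0:
        importances = importances / importances.sum()

    cm = confusion_matrix(y, oof.astype(str), labels=class_names)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = cm / np.maximum(row_sums, 1)
    recall = {name: float(cm_norm[i, i]) for i, name in enumerate(class_names)}
    bal = float(balanced_accuracy_score(y, oof.astype(str)))

    return ClassifierReport(
        class_names=class_names, confusion=cm_norm,
        per_class_recall=recall, balanced_accuracy=bal,
        feature_importances=pd.Series(importances, index=X.columns)
        .sort_values(ascending=False),
        fold_assignments=folds, n_samples=len(y), seed=seed,
        hyperparameters={"n_trees": n_trees, "max_depth": max_depth,
                         "n_folds": n_folds, "max_features": "sqrt",
                         "class_floor": class_floor})


def predict_subpop(model: SubpopulationClassifier,
                   features: pd.DataFrame) -> np.ndarray:
    """Predicted subpopulation labels, one per feature row."""
    if model.model_ is None:
        raise ValueError("classifier has not been fitted")
    X = _clean_features(features, model.enforce_blacklist)
    if list(X.columns) != model.feature_columns_:
        missing = set(model.feature_columns_) - set(X.columns)
        extra = set(X.columns) - set(model.feature_columns_)
        if missing or extra:
            raise ValueError(
                f"feature columns mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}")
        X = X[model.feature_columns_]
    if len(X) == 0:
        return np.array([], dtype=object)
    return model.model_.predict(X.to_numpy())


def confusion_similarity_check(report: ClassifierReport):
    """Off-diagonal confusion within vs across death-marker status.

    Returns ``(same_death_mass, different_death_mass)``: the mean
    row-normalized confusion per ordered class pair sharing the death label
    versus pairs that differ in it (per-pair means, so a uniform confusion
    matrix yields equal masses).
    """
    cm = np.asarray(report.confusion, dtype=float)
    if cm.shape != (4, 4):
        raise ValueError("expected a 4x4 confusion matrix")
    death = {Subpopulation.LOW_LOW.value: 0, Subpopulation.HIGH_LOW.value: 0,
             Subpopulation.LOW_HIGH.value: 1, Subpopulation.HIGH_HIGH.value: 1}
    names = list(report.class_names)
    same, diff = [], []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            (same if death[a] == death[b] else diff).append(cm[i, j])
    return float(np.mean(same)), float(np.mean(diff))
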