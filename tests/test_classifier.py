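"""Subpopulation classifier: calibration, determinism, guardrails."""

import numpy as np
import pandas as pd
import pytest

from nucleogate.classify import (BlacklistedFeatureError, ClassifierReport,
                                 SubpopulationClassifier,
                                 confusion_similarity_check,
                                 crossval_classify, predict_subpop)
from nucleogate.synthetic import SUBPOP_ORDER

CLASS_NAMES = [sp.value for sp in SUBPOP_ORDER]


def separable_toy(n_per_class=100, spread=0.1, seed=0):
    """Four well-separated Gaussian blobs in 3 features."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]], float)
    X, y = [], []
    for name, c in zip(CLASS_NAMES, centers):
        X.append(rng.normal(c, spread, size=(n_per_class, 3)))
        y += [name] * n_per_class
    return pd.DataFrame(np.vstack(X), columns=["f1", "f2", "f3"]), \
        pd.Series(y)


class TestCrossval:
    def test_report_is_valid_and_deterministic(self, cohort400):
        X, y, _ = cohort400
        rep1 = crossval_classify(X, y, seed=3, n_trees=100)
        rep2 = crossval_classify(X, y, seed=3, n_trees=100)
        assert rep1.to_json() == rep2.to_json()
        assert rep1.confusion.shape == (4, 4)
        assert np.allclose(rep1.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert 0.0 <= rep1.balanced_accuracy <= 1.0
        assert (rep1.feature_importances >= 0).all()
        assert rep1.feature_importances.sum() == pytest.approx(1.0)
        assert "balanced accuracy" in rep1.summary()

    def test_informative_cohort_beats_chance(self, cohort400):
        X, y, _ = cohort400
        rep = crossval_classify(X, y, seed=0, n_trees=100)
        assert rep.balanced_accuracy > 0.6

    def test_blacklisted_columns_rejected(self, cohort400):
        X, y, _ = cohort400
        bad = X.copy()
        bad["norm_gamma"] = 1.0
        with pytest.raises(BlacklistedFeatureError):
            crossval_classify(bad, y)

    def test_class_floor_enforced(self, cohort400):
        X, y, _ = cohort400
        with pytest.raises(ValueError):
            crossval_classify(X.head(350), y.head(350), class_floor=100)

    def test_constant_feature_is_chance_level(self):
        rng = np.random.default_rng(1)
        y = pd.Series(rng.permutation(np.repeat(CLASS_NAMES, 100)))
        X = pd.DataFrame({"f": np.ones(400)})
        rep = crossval_classify(X, y, seed=0, n_trees=50)
        assert rep.balanced_accuracy == pytest.approx(0.25, abs=0.02)

    def test_balanced_accuracy_invariant_to_class_duplication(self):
        """Macro-averaged recall does not change when one class's samples
        are duplicated (separable toy: exactly 1.0 both ways)."""
        X, y = separable_toy()
        rep = crossval_classify(X, y, seed=0, n_trees=50)
        dup = y == CLASS_NAMES[0]
        X2 = pd.concat([X, X[dup]], ignore_index=True)
        y2 = pd.concat([y, y[dup]], ignore_index=True)
        rep2 = crossval_classify(X2, y2, seed=0, n_trees=50)
        assert rep.balanced_accuracy == rep2.balanced_accuracy == 1.0

    def test_signal_monotone_in_class_separation(self):
        """Mean CV accuracy never decreases as blob separation grows."""
        accs = []
        for spread in (3.0, 1.2, 0.4):
            per_seed = [crossval_classify(
                *separable_toy(spread=spread, seed=s), seed=s,
                n_trees=50).balanced_accuracy for s in range(3)]
            accs.append(np.mean(per_seed))
        assert accs[0] <= accs[1] <= accs[2]


class TestPredict:
    def test_training_recall_bounds_cv_recall(self, cohort400):
        X, y, _ = cohort400
        clf = SubpopulationClassifier(n_trees=100, seed=0)
        report = clf.fit(X, y)
        train_pred = clf.predict(X)
        train_bal = np.mean([
            (train_pred[(y == c).to_numpy()] == c).mean()
            for c in CLASS_NAMES])
        assert train_bal >= report.balanced_accuracy

    def test_empty_feature_table(self):
        X, y = separable_toy(n_per_class=30)
        clf = SubpopulationClassifier(n_trees=20, class_floor=10, seed=0)
        clf.fit(X, y)
        assert len(clf.predict(X.head(0))) == 0

    def test_column_mismatch_rejected(self):
        X, y = separable_toy(n_per_class=30)
        clf = SubpopulationClassifier(n_trees=20, class_floor=10, seed=0)
        clf.fit(X, y)
        with pytest.raises(ValueError):
            predict_subpop(clf, X.rename(columns={"f1": "other"}))

    def test_predicted_classes_preserve_planted_ki67_ordering(self):
        """Train on features, predict a fresh cohort, and check that the
        planted Ki67 ordering across classes survives label transfer."""
        from nucleogate.workflows import balanced_feature_cohort
        Xtr, ytr, _ = balanced_feature_cohort(61, n_per_class=60,
                                              separable=True,
                                              ki67_ordering=True)
        Xte, yte, matched = balanced_feature_cohort(62, n_per_class=60,
                                                    separable=True,
                                                    ki67_ordering=True)
        clf = SubpopulationClassifier(n_trees=100, class_floor=50, seed=0)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        ki67 = matched["ki67_mean"].to_numpy()
        medians = {c: np.median(ki67[pred == c]) for c in CLASS_NAMES
                   if (pred == c).sum() >= 10}
        # planted ordering: low/low lowest, high-damage/low-death highest
        assert medians[CLASS_NAMES[0]] == min(medians.values())
        assert medians[CLASS_NAMES[1]] == max(medians.values())


class TestConfusionSimilarity:
    def _report(self, confusion):
        return ClassifierReport(
            class_names=CLASS_NAMES, confusion=np.asarray(confusion, float),
            per_class_recall={}, balanced_accuracy=0.0,
            feature_importances=pd.Series(dtype=float),
            fold_assignments=np.array([]), n_samples=0, seed=0)

    def test_identity_matrix_no_confusion(self):
        same, diff = confusion_similarity_check(self._report(np.eye(4)))
        assert same == diff == 0.0

    def test_uniform_confusion_equal_masses(self):
        same, diff = confusion_similarity_check(
            self._report(np.full((4, 4), 0.25)))
        assert same == pytest.approx(diff)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            confusion_similarity_check(self._report(np.eye(3)))

    def test_planted_death_ambiguity_confuses_same_death_pairs(self):
        """Classes sharing death status are built to share texture; their
        mutual confusion should exceed cross-death confusion."""
        from dataclasses import replace
        from nucleogate.presets import four_class
        from nucleogate.synthetic import Subpopulation
        from nucleogate.workflows import analyze_config
        from nucleogate.features import FEATURE_COLUMNS
        arms = four_class(71, n_per_class=80)
        cfg = replace(
            arms["cohort"],
            area_scale=(1.0, 1.05, 1.6, 1.65),
            condensation_params={
                Subpopulation.LOW_LOW: (0.30, 2.55),
                Subpopulation.HIGH_LOW: (0.30, 2.45),
                Subpopulation.LOW_HIGH: (0.26, 1.45),
                Subpopulation.HIGH_HIGH: (0.26, 1.40),
            })
        analysis = analyze_config(cfg, with_features=True)
        matched = analysis.matched()
        matched = matched[~matched["undefined"].astype(bool)]
        rep = crossval_classify(matched[FEATURE_COLUMNS],
                                matched["true_subpop"], seed=0, n_trees=100,
                                class_floor=50)
        same, diff = confusion_similarity_check(rep)
        assert same > diff
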