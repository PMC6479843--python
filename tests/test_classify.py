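"""AUC computation and cross-validated classifier evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from conftest import auc_brute
from gaitefs import FoldConstructionError, ParameterError, auc_from_scores, crossval_auc
from gaitefs.classify import CLASSIFIERS, evaluate_all


def _feature_table(n_subjects=10, trials_per_subject=2, gap=3.0, sd=0.5, seed=0):
    """Separable two-group table: HP shifted by `gap` on every feature."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, shift in (("HP", gap), ("HC", 0.0)):
        for s in range(n_subjects):
            centre = rng.normal(shift, sd)
            for t in range(trials_per_subject):
                rows.append(
                    {
                        "trial_id": f"{group}{s}_{t}",
                        "subject_id": f"{group}{s}",
                        "group": group,
                        "symmetry_dtw": centre + rng.normal(0, 0.1),
                        "sampen": rng.normal(0, 1),
                        "stability_index": rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def test_auc_separated_and_tied_cases():
    assert auc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert auc_from_scores([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5


def test_auc_matches_pair_counting_and_sklearn(rng):
    for _ in range(25):
        n = int(rng.integers(4, 30))
        labels = np.r_[np.ones(n // 2, bool), np.zeros(n - n // 2, bool)]
        scores = rng.integers(0, 5, size=n).astype(float)  # forces ties
        ours = auc_from_scores(scores, labels)
        assert ours == pytest.approx(auc_brute(scores, labels), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_label_reversal_and_monotone_invariance(rng):
    scores = rng.standard_normal(40)
    labels = rng.integers(0, 2, 40).astype(bool)
    labels[:2] = [True, False]  # both classes present
    a = auc_from_scores(scores, labels)
    assert auc_from_scores(scores, ~labels) == pytest.approx(1.0 - a, abs=1e-12)
    assert auc_from_scores(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ParameterError):
        auc_from_scores([0.1, 0.2], [1, 1])


def test_knn_perfect_on_separable_feature():
    table = _feature_table(gap=20.0, sd=0.1)
    res = crossval_auc(table, "KNN", cfg={"n_neighbors": 1}, seed=1)
    assert res.auc == 1.0


def test_grouped_folds_keep_subjects_together():
    table = _feature_table()
    res = crossval_auc(table, "KNN", seed=3)
    folds = pd.Series(res.fold_assignments)
    subj = folds.index.str.rsplit("_", n=1).str[0]
    assert folds.groupby(subj).nunique().max() == 1
    assert folds.nunique() == 10
    assert set(folds.index) == set(table["trial_id"])


def test_deterministic_given_seed():
    table = _feature_table()
    a = crossval_auc(table, "SVM", seed=11)
    b = crossval_auc(table, "SVM", seed=11)
    assert a.auc == b.auc and a.fold_assignments == b.fold_assignments


def test_unknown_classifier_rejected():
    with pytest.raises(ParameterError):
        crossval_auc(_feature_table(), "RandomForest")


def test_too_few_subjects_rejected():
    table = _feature_table(n_subjects=1, trials_per_subject=12)
    with pytest.raises(FoldConstructionError):
        crossval_auc(table, "KNN")


def test_evaluate_all_covers_four_classifiers():
    frame = evaluate_all(_feature_table(gap=8.0), seed=2)
    assert list(frame["classifier"]) == list(CLASSIFIERS)
    assert ((frame["auc"] >= 0.0) & (frame["auc"] <= 1.0)).all()
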