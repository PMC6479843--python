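"""HP-vs-HC classification of the 3-feature gait vector.

Four standard classifiers — RBF-kernel SVM, decision tree, k-nearest
neighbours and a one-hidden-layer MLP — are evaluated under stratified
tenfold cross-validation on the (symmetry, SampEn, stability-index)
vector.  By default the folds are *subject-grouped*: all trials of one
subject land in the same fold, so the five repeated trials per subject can
never leak between training and test sets.  Decision scores from the test
folds are pooled into a single ROC and summarised by the AUC, computed as
a rank statistic (Mann-Whitney U / n+ n-) with midrank tie handling.

Features are standardised inside each fold: the scaler is fit on the
training split only and applied to the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import FoldConstructionError, ParameterError
from .stats import FEATURE_COLUMNS

CLASSIFIERS = ("SVM", "DT", "KNN", "MLP")
N_FOLDS = 10
POSITIVE = "HP"


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validated AUC of one classifier."""

    classifier_name: str
    auc: float
    fold_assignments: dict[str, int]
    config_used: dict = field(default_factory=dict)


def auc_from_scores(scores, labels) -> float:
    """Area under the ROC curve from decision scores and binary labels.

    Computed as U / (n+ * n-) with midranks, i.e. the probability that a
    random positive outscores a random negative, ties counted half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.size != labels.size:
        raise ParameterError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def _make_estimator(name: str, seed: int, overrides: dict | None):
    """Classifier with the package defaults, seed-pinned where stochastic."""
    overrides = dict(overrides or {})
    if name == "SVM":
        # gamma='scale' = 1 / (n_features * var(X)), i.e. 1/(3*var) here
        est = SVC(kernel="rbf", C=1.0, gamma="scale", **overrides)
    elif name == "DT":
        est = DecisionTreeClassifier(criterion="gini", random_state=seed, **overrides)
    elif name == "KNN":
        est = KNeighborsClassifier(n_neighbors=overrides.pop("n_neighbors", 5), **overrides)
    elif name == "MLP":
        est = MLPClassifier(
            hidden_layer_sizes=overrides.pop("hidden_layer_sizes", (10,)),
            max_iter=overrides.pop("max_iter", 500),
            random_state=seed,
            **overrides,
        )
    else:
        raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
    return make_pipeline(StandardScaler(), est)


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def crossval_auc(
    table: pd.DataFrame,
    classifier_name: str,
    cfg: dict | None = None,
    seed: int = 0,
    grouped: bool = True,
    pooling: str = "pooled",
) -> CVResult:
    """Tenfold cross-validated AUC of one classifier on a feature table.

    The table needs columns ``trial_id``, ``subject_id``, ``group`` and the
    three feature columns; rows with missing features are dropped.  With
    ``grouped=True`` (default) folds are stratified by class and grouped by
    subject.  ``pooling`` is ``"pooled"`` (one ROC over all test-fold
    scores) or ``"per_fold_mean"``.
    """
    if pooling not in ("pooled", "per_fold_mean"):
        raise ParameterError(f"unknown pooling {pooling!r}")
    sub = table.dropna(subset=list(FEATURE_COLUMNS))
    X = sub[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = (sub["group"] == POSITIVE).to_numpy()
    groups = sub["subject_id"].to_numpy()
    trial_ids = sub["trial_id"].astype(str).to_numpy()
    for cls_present, label in ((y.sum(), POSITIVE), ((~y).sum(), "negative")):
        if cls_present == 0:
            raise FoldConstructionError(f"no {label} trials in the table")
    if grouped:
        n_sub = min(
            pd.unique(groups[y]).size,
            pd.unique(groups[~y]).size,
        )
        if n_sub < 2:
            raise FoldConstructionError("need >= 2 subjects per group for grouped CV")
        if pd.unique(groups).size < N_FOLDS:
            raise FoldConstructionError(
                f"grouped tenfold CV needs >= {N_FOLDS} subjects, "
                f"got {pd.unique(groups).size}"
            )
        splitter = StratifiedGroupKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
        splits = splitter.split(X, y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)

    fold_of: dict[str, int] = {}
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    fold_aucs: list[float] = []
    for fold, (tr, te) in enumerate(splits):
        if np.unique(y[tr]).size < 2:
            raise FoldConstructionError(f"fold {fold}: training split has a single class")
        model = _make_estimator(classifier_name, seed=seed, overrides=cfg)
        model.fit(X[tr], y[tr])
        s = _scores(model, X[te])
        pooled_scores.append(s)
        pooled_labels.append(y[te])
        for t in trial_ids[te]:
            fold_of[t] = fold
        if pooling == "per_fold_mean" and np.unique(y[te]).size == 2:
            fold_aucs.append(auc_from_scores(s, y[te]))

    if pooling == "pooled":
        auc = auc_from_scores(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    else:
        if not fold_aucs:
            raise FoldConstructionError("no two-class test fold for per-fold AUC")
        auc = float(np.mean(fold_aucs))
    return CVResult(
        classifier_name=classifier_name,
        auc=float(auc),
        fold_assignments=fold_of,
        config_used={
            "cfg": dict(cfg or {}),
            "seed": seed,
            "grouped": grouped,
            "pooling": pooling,
        },
    )


def evaluate_all(
    table: pd.DataFrame,
    seed: int = 0,
    grouped: bool = True,
    cfgs: dict | None = None,
    detailed: bool = False,
):
    """AUC of all four classifiers as a (classifier, auc) frame.

    With ``detailed=True`` also returns the per-classifier
    :class:`CVResult` objects (fold maps, configs) keyed by name.
    """
    cfgs = cfgs or {}
    results = {
        name: crossval_auc(table, name, cfg=cfgs.get(name), seed=seed, grouped=grouped)
        for name in CLASSIFIERS
    }
    frame = pd.DataFrame(
        [{"classifier": name, "auc": res.auc} for name, res in results.items()]
    )
    return (frame, results) if detailed else frame
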