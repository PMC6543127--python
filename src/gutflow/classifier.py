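"""CAG-based case/control discrimination.

The cohort is split 80/20 stratified by group; a random forest is trained
on the training portion, features are ranked once by permutation importance
(mean decrease in accuracy), and the misclassification error of the top-k
feature subsets is charted by 5 trials of stratified 10-fold
cross-validation. Discrimination is summarised by ROC AUC with a DeLong
95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "split_train_test",
    "rank_features",
    "cv_error_curve",
    "evaluate_roc",
    "auc_ci",
    "classify_report",
    "ClassifierReport",
]

DEFAULT_KS = (5, 10, 20, 50, 70, 100, 200, 500, 1000)
DEFAULT_TREES = 500


@dataclass
class ClassifierReport:
    train_ids: list[str]
    test_ids: list[str]
    importance: pd.Series
    cv_curve: pd.Series
    k_selected: int
    train_auc: float
    train_ci: tuple[float, float]
    test_auc: float
    test_ci: tuple[float, float]
    test_scores: pd.Series
    extra: dict = field(default_factory=dict)


def _encode(y) -> np.ndarray:
    y = np.asarray(y)
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValueError(f"need exactly two classes, got {list(levels)}")
    positive = "case" if "case" in levels else levels[1]
    return (y == positive).astype(int)


def split_train_test(
    sample_ids, meta: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of sample ids, deterministic under seed."""
    ids = list(sample_ids)
    groups = meta.loc[ids, "group"].to_numpy()
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each group needs at least 2 samples")
    train, test = train_test_split(
        ids, train_size=train_fraction, stratify=groups, random_state=seed
    )
    return sorted(train), sorted(test)


def rank_features(
    X: pd.DataFrame, y, n_trees: int = DEFAULT_TREES, n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance (mean decrease in accuracy) of each feature,
    from one forest fit on the full input, sorted descending."""
    yb = _encode(y)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X.to_numpy(), yb)
    imp = permutation_importance(
        forest, X.to_numpy(), yb, n_repeats=n_repeats,
        random_state=seed, scoring="accuracy",
    )
    ranked = pd.Series(imp.importances_mean, index=X.columns)
    return ranked.sort_values(ascending=False, kind="mergesort")


def cv_error_curve(
    X: pd.DataFrame,
    y,
    ks=DEFAULT_KS,
    trials: int = 5,
    folds: int = 10,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    importance: pd.Series | None = None,
) -> tuple[pd.Series, int]:
    """Mean CV misclassification error vs number of top-ranked features.

    Features are ranked once on the full input (the chart's design);
    for each k the error is averaged over ``trials`` reshuffled stratified
    ``folds``-fold cross-validations. Returns the curve and the error-
    minimising k (ties toward the smallest k).
    """
    yb = _encode(y)
    if len(yb) < folds:
        raise ValueError("fewer samples than folds")
    if importance is None:
        importance = rank_features(X, y, n_trees=n_trees, seed=seed)
    ranked_features = list(importance.index)
    curve = {}
    for k in ks:
        if k > len(ranked_features):
            continue
        cols = ranked_features[:k]
        Xk = X[cols].to_numpy()
        errors = []
        for trial in range(trials):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed * 1000 + trial)
            for tr, te in skf.split(Xk, yb):
                forest = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed + trial
                )
                forest.fit(Xk[tr], yb[tr])
                errors.append(1.0 - forest.score(Xk[te], yb[te]))
        curve[k] = float(np.mean(errors))
    if not curve:
        raise ValueError("no feasible k (all exceed the feature count)")
    cv_curve = pd.Series(curve).sort_index()
    k_selected = int(cv_curve.index[np.argmin(cv_curve.to_numpy())])
    return cv_curve, k_selected


def evaluate_roc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC by the rank (Mann-Whitney) formulation plus the ROC step curve."""
    s = np.asarray(scores, dtype=float)
    yb = _encode(labels)
    n_pos, n_neg = int(yb.sum()), int((1 - yb).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to evaluate a ROC curve")
    ranks = stats.rankdata(s)
    auc = (ranks[yb == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(yb, s)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), roc


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float, bool]:
    """DeLong confidence interval for the AUC, truncated to [0, 1].

    Returns ``(lower, upper, degenerate)``; ``degenerate`` flags a zero
    variance estimate (e.g. perfect separation), where the interval
    collapses to the point estimate.
    """
    s = np.asarray(scores, dtype=float)
    yb = _encode(labels)
    pos, neg = s[yb == 1], s[yb == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 samples per class")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # structural components V10
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # V01
    var = np.var(v_pos, ddof=1) / m + np.var(v_neg, ddof=1) / n
    if var <= 0:
        return float(auc), float(auc), True
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half)), False


def classify_report(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    ks=DEFAULT_KS,
    trials: int = 5,
    folds: int = 10,
    n_trees: int = DEFAULT_TREES,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> ClassifierReport:
    """Full discrimination stage on a samples x features table.

    The training AUC is estimated from the final forest's out-of-bag class
    votes (an honest within-training estimate); the test AUC from held-out
    predicted probabilities.
    """
    y = meta.loc[X.index, "group"]
    train_ids, test_ids = split_train_test(X.index, meta, train_fraction, seed)
    X_tr, X_te = X.loc[train_ids], X.loc[test_ids]
    y_tr, y_te = y.loc[train_ids], y.loc[test_ids]
    importance = rank_features(X_tr, y_tr, n_trees=n_trees, seed=seed)
    cv_curve, k_selected = cv_error_curve(
        X_tr, y_tr, ks=ks, trials=trials, folds=folds,
        n_trees=n_trees, seed=seed, importance=importance,
    )
    cols = list(importance.index[:k_selected])
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True
    )
    forest.fit(X_tr[cols].to_numpy(), _encode(y_tr))
    oob = forest.oob_decision_function_[:, 1]
    train_auc, _ = evaluate_roc(oob, y_tr)
    tr_lo, tr_hi, _ = auc_ci(oob, y_tr)
    test_scores = forest.predict_proba(X_te[cols].to_numpy())[:, 1]
    test_auc, _ = evaluate_roc(test_scores, y_te)
    te_lo, te_hi, _ = auc_ci(test_scores, y_te)
    return ClassifierReport(
        train_ids=train_ids,
        test_ids=test_ids,
        importance=importance,
        cv_curve=cv_curve,
        k_selected=k_selected,
        train_auc=train_auc,
        train_ci=(tr_lo, tr_hi),
        test_auc=test_auc,
        test_ci=(te_lo, te_hi),
        test_scores=pd.Series(test_scores, index=test_ids),
    )
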