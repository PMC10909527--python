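"""Validation of the retained dimensions by classification and clustering.

A priori (theory-driven): a random forest predicts the stimulus valence class
(negative/neutral/positive) from the retained dimension scores; reported are
out-of-bag and held-out accuracy, one-vs-rest AUC per class, permutation
variable importance (mean decrease in accuracy) per dimension, and a
chi-square test of the held-out confusion matrix against independence.

A posteriori (data-driven): k-means over a range of k with many restarts,
the solution chosen by maximum mean silhouette; reported are the silhouette,
the percent between-cluster variance, the cluster-by-class contingency
chi-square (when labels are supplied) and per-cluster profiles of the
standardized input variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix, roc_auc_score, silhouette_score
from sklearn.model_selection import train_test_split

__all__ = [
    "ForestParams",
    "ClassificationReport",
    "ClusteringReport",
    "ValidationReport",
    "classify_space",
    "cluster_space",
    "validate_space",
]


@dataclass
class ForestParams:
    """Random-forest hyperparameters (recorded in the report)."""

    n_estimators: int = 500
    max_features: str = "sqrt"
    test_size: float = 0.3
    n_importance_repeats: int = 10


@dataclass
class ClassificationReport:
    oob_accuracy: float
    test_accuracy: float
    auc_per_class: dict[str, float]
    macro_auc: float
    importance: pd.Series  # mean decrease in accuracy per dimension
    confusion: pd.DataFrame
    chi2: float
    chi2_df: int
    chi2_p: float
    params: ForestParams


@dataclass
class ClusteringReport:
    chosen_k: int
    silhouette: float
    silhouette_by_k: dict[int, float]
    pct_between_variance: float
    pct_between_by_k: dict[int, float]
    contingency: pd.DataFrame | None
    chi2: float | None
    chi2_df: int | None
    chi2_p: float | None
    profiles: pd.DataFrame | None


@dataclass
class ValidationReport:
    classification: ClassificationReport
    clustering: ClusteringReport
    extras: dict = field(default_factory=dict)


def classify_space(
    scores: pd.DataFrame,
    labels: pd.Series,
    params: ForestParams | None = None,
    seed: int | None = None,
) -> ClassificationReport:
    """Random-forest classification of class labels from dimension scores."""
    params = params or ForestParams()
    if not 0.0 < params.test_size < 1.0:
        raise ValueError("test_size must lie in (0, 1)")
    y = pd.Series(labels).reindex(scores.index)
    if y.isna().any():
        raise ValueError("labels undefined for some rows of the score matrix")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    rs = int(rng.integers(0, 2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        scores, y, test_size=params.test_size, stratify=y, random_state=rs
    )
    if len(np.unique(y_tr)) < len(classes):
        raise ValueError("a class is absent from the training split")
    forest = RandomForestClassifier(
        n_estimators=params.n_estimators,
        max_features=params.max_features,
        oob_score=True,
        random_state=rs,
        n_jobs=1,
    )
    forest.fit(X_tr, y_tr)
    oob = float(forest.oob_score_)
    test_acc = float(forest.score(X_te, y_te))

    proba = forest.predict_proba(X_te)
    auc = {}
    for i, cls in enumerate(forest.classes_):
        auc[str(cls)] = float(roc_auc_score((y_te == cls).astype(int), proba[:, i]))
    macro = float(np.mean(list(auc.values())))

    imp = permutation_importance(
        forest, X_te, y_te, n_repeats=params.n_importance_repeats,
        random_state=rs, scoring="accuracy",
    )
    importance = pd.Series(imp.importances_mean, index=scores.columns)

    cm = confusion_matrix(y_te, forest.predict(X_te), labels=forest.classes_)
    confusion = pd.DataFrame(cm, index=forest.classes_, columns=forest.classes_)
    # chi-square of the confusion table against independence; columns with no
    # predictions are dropped to keep expected counts positive
    nonzero = cm.sum(axis=0) > 0
    chi2, p, df, _ = chi2_contingency(cm[:, nonzero])
    return ClassificationReport(
        oob_accuracy=oob,
        test_accuracy=test_acc,
        auc_per_class=auc,
        macro_auc=macro,
        importance=importance,
        confusion=confusion,
        chi2=float(chi2),
        chi2_df=int(df),
        chi2_p=float(p),
        params=params,
    )


def _between_variance_pct(X: np.ndarray, assign: np.ndarray) -> float:
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    between = 0.0
    for k in np.unique(assign):
        sub = X[assign == k]
        between += len(sub) * float(((sub.mean(axis=0) - grand) ** 2).sum())
    return 100.0 * between / total if total > 0 else 0.0


def cluster_space(
    scores: pd.DataFrame,
    k_range: range | list[int] = range(2, 9),
    labels: pd.Series | None = None,
    variables: pd.DataFrame | None = None,
    seed: int | None = None,
    n_init: int = 25,
) -> ClusteringReport:
    """K-means over a range of k; the solution with maximum silhouette wins.

    When ``labels`` are supplied the cluster-by-label contingency chi-square
    is reported; when ``variables`` are supplied the per-cluster means of the
    standardized variables (profile heatmap data) are included.
    """
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    ks = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    sil_by_k: dict[int, float] = {}
    pct_by_k: dict[int, float] = {}
    assign_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(0, 2**31 - 1)))
        assign = km.fit_predict(X)
        if len(np.unique(assign)) < k:
            continue  # degenerate solution for this k
        sil_by_k[k] = float(silhouette_score(X, assign))
        pct_by_k[k] = _between_variance_pct(X, assign)
        assign_by_k[k] = assign
    if not sil_by_k:
        raise RuntimeError("no non-degenerate clustering found in k_range")
    chosen = max(sil_by_k, key=lambda k: sil_by_k[k])
    assign = assign_by_k[chosen]

    contingency = chi2 = df = p = None
    if labels is not None:
        y = pd.Series(labels).reindex(scores.index)
        contingency = pd.crosstab(pd.Series(assign, index=scores.index, name="cluster"), y)
        chi2, p, df, _ = chi2_contingency(contingency.to_numpy())
        chi2, p, df = float(chi2), float(p), int(df)

    profiles = None
    if variables is not None:
        Z = (variables - variables.mean()) / variables.std(ddof=0)
        profiles = Z.groupby(pd.Series(assign, index=variables.index)).mean()
        profiles.index.name = "cluster"

    return ClusteringReport(
        chosen_k=chosen,
        silhouette=sil_by_k[chosen],
        silhouette_by_k=sil_by_k,
        pct_between_variance=pct_by_k[chosen],
        pct_between_by_k=pct_by_k,
        contingency=contingency,
        chi2=chi2,
        chi2_df=df,
        chi2_p=p,
        profiles=profiles,
    )


def validate_space(
    scores: pd.DataFrame,
    labels: pd.Series,
    variables: pd.DataFrame | None = None,
    params: ForestParams | None = None,
    k_range: range | list[int] = range(2, 9),
    seed: int | None = None,
) -> ValidationReport:
    """Run both validation analyses on the same retained-dimension scores."""
    root = np.random.SeedSequence(seed)
    s_cls, s_clu = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(2)]
    classification = classify_space(scores, labels, params=params, seed=s_cls)
    clustering = cluster_space(
        scores, k_range=k_range, labels=labels, variables=variables, seed=s_clu
    )
    return ValidationReport(classification=classification, clustering=clustering)
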