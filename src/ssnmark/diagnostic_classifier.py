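"""Tumor/normal diagnostic classification on a gene panel.

Because tumor cohorts dwarf their matched normals, tumors are first split
into random subgroups of roughly the normal-cohort size; each subgroup plus
the normals is classified with a Gaussian-kernel SVM under stratified
5-fold cross-validation. Held-out decision scores are pooled across
subgroups for one overall ROC/AUC; per-subgroup AUCs are reported as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import AnalysisError, ValidationError
from .io_formats import TUMOR, ExpressionMatrix


@dataclass
class ClassificationResult:
    subgroups: dict[str, int]  # tumor sample -> subgroup index
    scores: pd.Series  # held-out decision score per sample (pooled)
    labels: pd.Series  # 1 = tumor, 0 = normal
    auc: float
    auc_per_subgroup: dict[int, float]
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    seed: int


def make_balanced_subgroups(tumor_ids: list[str], n_normal: int, seed: int = 0) -> dict[str, int]:
    """Random partition of tumors into ceil(n_tumor / n_normal) subgroups
    with sizes differing by at most one; deterministic under ``seed``."""
    if n_normal < 2:
        raise ValidationError("need at least 2 normal samples to size subgroups")
    ids = list(tumor_ids)
    n_groups = max(1, math.ceil(len(ids) / n_normal))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    # round-robin assignment of a shuffled order gives a +/-1 balanced split
    return {ids[idx]: int(pos % n_groups) for pos, idx in enumerate(order)}


def crossval_auc(
    expr_subset: ExpressionMatrix,
    folds: int = 5,
    seed: int = 0,
    subgroups: dict[str, int] | None = None,
) -> ClassificationResult:
    """Stratified k-fold SVM classification, pooled ROC and AUC.

    ``expr_subset`` should already be restricted to the gene panel (for the
    pipeline, the core functional genes). Normals are reused in every tumor
    subgroup's cross-validation; each sample's held-out decision score is
    its score from its own subgroup's CV (normals: from the first subgroup).
    """
    y_all = (expr_subset.sample_class == TUMOR).astype(int)
    tumors = expr_subset.samples_of_class(TUMOR)
    normals = [s for s in expr_subset.sample_ids if s not in set(tumors)]
    if not tumors or not normals:
        raise AnalysisError("both tumor and normal samples are required")
    if subgroups is None:
        subgroups = make_balanced_subgroups(tumors, len(normals), seed=seed)
    n_groups = max(subgroups.values()) + 1

    pooled_scores: dict[str, float] = {}
    auc_per_subgroup: dict[int, float] = {}
    for g in range(n_groups):
        members = [s for s in tumors if subgroups[s] == g] + normals
        X = expr_subset.values[members].to_numpy(dtype=float).T
        y = y_all.loc[members].to_numpy()
        if min(np.bincount(y, minlength=2)) < folds:
            raise AnalysisError("a class has fewer samples than folds; stratification impossible")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + g)
        scores = np.empty(len(members))
        for train, test in skf.split(X, y):
            scaler = StandardScaler().fit(X[train])
            clf = SVC(kernel="rbf", gamma="scale", C=1.0)
            clf.fit(scaler.transform(X[train]), y[train])
            scores[test] = clf.decision_function(scaler.transform(X[test]))
        auc_per_subgroup[g] = float(metrics.roc_auc_score(y, scores))
        for sid, sc in zip(members, scores):
            pooled_scores.setdefault(sid, float(sc))

    score_series = pd.Series(pooled_scores)
    labels = y_all.loc[score_series.index]
    fpr, tpr, thr = metrics.roc_curve(labels, score_series)
    auc = float(metrics.auc(fpr, tpr))
    return ClassificationResult(
        subgroups=subgroups,
        scores=score_series,
        labels=labels,
        auc=auc,
        auc_per_subgroup=auc_per_subgroup,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        seed=seed,
    )


def hierarchical_cluster(expr_subset: ExpressionMatrix, method: str = "average"):
    """Agglomerative clustering of samples on 1 - Pearson correlation.

    Returns ``(linkage_matrix, leaf_order)`` in scipy's linkage convention,
    for heat-map export.
    """
    X = expr_subset.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise AnalysisError("need at least two samples to cluster")
    if np.any(X.std(axis=0) == 0):
        raise AnalysisError("constant sample vector: correlation distance undefined")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = [expr_subset.sample_ids[i] for i in hierarchy.leaves_list(Z)]
    return Z, order
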