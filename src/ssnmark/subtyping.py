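"""Consensus-clustering tumor subtypes and their molecular signatures.

Subtypes come from Monti-style consensus clustering: many rounds of
hierarchical Ward clustering on random 80% sample subsets, accumulating how
often each sample pair lands in the same cluster when co-sampled; the final
partition clusters 1 - consensus. Per-subtype signatures are one-vs-rest
Welch t-test top up/down gene lists, pruned to genes unique to a single
subtype. Subtype-feature association uses Fisher/chi-square contingency
tests, and subtype survival a multi-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import AnalysisError, ValidationError
from .io_formats import ClinicalTable, ExpressionMatrix, MutationTable


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # samples x samples co-clustering proportion
    assignments: pd.Series  # sample -> cluster label 1..k
    co_sampled: pd.DataFrame  # times each pair was drawn together
    iterations: int
    subsample_fraction: float
    seed: int
    iteration_log: list | None = None  # optional (sample indices, labels) per iteration


def _pearson_condensed(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between the columns of X."""
    corr = np.corrcoef(X.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False)


def consensus_cluster(
    expr_tumors: ExpressionMatrix,
    k: int,
    iterations: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    linkage_method: str = "ward",
    keep_log: bool = False,
) -> ConsensusResult:
    """Consensus matrix and final assignment at one value of k.

    Each iteration draws ``floor(subsample_fraction * m)`` samples without
    replacement, Ward-clusters them on 1 - Pearson correlation and cuts at
    k; consensus(i, j) = co-clustered / co-sampled. The final partition is
    average-linkage clustering of 1 - consensus cut at k.
    """
    ids = expr_tumors.sample_ids
    m = len(ids)
    sub = int(np.floor(subsample_fraction * m))
    if sub < k:
        raise ValidationError(f"subsample of {sub} samples cannot form k={k} clusters")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    X = expr_tumors.values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    together = np.zeros((m, m))
    co_sampled = np.zeros((m, m))
    log = [] if keep_log else None
    for _ in range(iterations):
        idx = rng.choice(m, size=sub, replace=False)
        d = _pearson_condensed(X[:, idx])
        Z = hierarchy.linkage(d, method=linkage_method)
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        co_sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
        if keep_log:
            log.append((idx.copy(), labels.copy()))
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), np.nan)
    np.fill_diagonal(consensus, 1.0)
    cons_df = pd.DataFrame(consensus, index=ids, columns=ids)

    filled = np.nan_to_num(consensus, nan=0.0)  # never-co-sampled pairs: no evidence
    d_final = squareform(np.clip(1.0 - (filled + filled.T) / 2.0, 0.0, None), checks=False)
    Zf = hierarchy.linkage(d_final, method="average")
    assignments = pd.Series(hierarchy.fcluster(Zf, t=k, criterion="maxclust"), index=ids)
    return ConsensusResult(
        k=k, consensus=cons_df, assignments=assignments,
        co_sampled=pd.DataFrame(co_sampled, index=ids, columns=ids),
        iterations=iterations, subsample_fraction=subsample_fraction, seed=seed,
        iteration_log=log,
    )


def consensus_cluster_range(
    expr_tumors: ExpressionMatrix, k_range=range(2, 11), **kwargs
) -> dict[int, ConsensusResult]:
    return {k: consensus_cluster(expr_tumors, k, **kwargs) for k in k_range}


@dataclass
class SubtypeSignature:
    """Per-subtype unique top up/down differential genes."""

    up: dict[str, pd.DataFrame]  # subtype -> frame(gene, t, p), t > 0
    down: dict[str, pd.DataFrame]  # t < 0
    dropped_shared: set[str]  # genes selected by more than one subtype

    def genes(self, subtype: str) -> set[str]:
        return set(self.up[subtype]["gene"]) | set(self.down[subtype]["gene"])


def representative_degs(
    expr_tumors: ExpressionMatrix,
    assignments: pd.Series,
    top_n: int = 100,
    equal_var: bool = False,
) -> SubtypeSignature:
    """One-vs-rest two-sided t-tests per gene; top up/down lists per subtype,
    then genes picked by more than one subtype are dropped everywhere.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled-variance variant). Genes with zero variance in both groups are
    skipped.
    """
    subtypes = sorted(assignments.unique())
    counts = assignments.value_counts()
    small = [s for s in subtypes if counts[s] < 2]
    if small:
        raise AnalysisError(f"subtypes with fewer than 2 samples: {small}")
    X = expr_tumors.values[assignments.index]
    up_raw, down_raw = {}, {}
    for s in subtypes:
        members = assignments.index[assignments == s]
        rest = assignments.index[assignments != s]
        a = X[members].to_numpy(dtype=float)
        b = X[rest].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        frame = pd.DataFrame({"gene": X.index, "t": t, "p": p}).dropna()
        up = frame[frame["t"] > 0].nsmallest(top_n, "p").reset_index(drop=True)
        down = frame[frame["t"] < 0].nsmallest(top_n, "p").reset_index(drop=True)
        up_raw[s], down_raw[s] = up, down
    # uniqueness filter after per-subtype selection
    picks: dict[str, int] = {}
    for s in subtypes:
        for g in pd.concat([up_raw[s]["gene"], down_raw[s]["gene"]]):
            picks[g] = picks.get(g, 0) + 1
    shared = {g for g, c in picks.items() if c > 1}
    up = {s: f[~f["gene"].isin(shared)].reset_index(drop=True) for s, f in up_raw.items()}
    down = {s: f[~f["gene"].isin(shared)].reset_index(drop=True) for s, f in down_raw.items()}
    return SubtypeSignature(up=up, down=down, dropped_shared=shared)


def subtype_feature_association(
    assignments: pd.Series,
    clinical: ClinicalTable | None = None,
    mutations: MutationTable | None = None,
    clinical_features=("sex", "pathologic_stage", "retrospective_indicator",
                       "race", "microsatellite_status"),
) -> pd.DataFrame:
    """Per feature-level x subtype one-vs-rest enrichment.

    For every categorical feature level and every subtype a 2x2 table
    (level/other x subtype/rest) is tested with Fisher's exact test; the
    log odds ratio gives the enrichment direction. Mutated genes enter as
    binary mutated/not features. Single-level features are skipped.
    """
    features: dict[str, pd.Series] = {}
    if clinical is not None:
        for col in clinical_features:
            features[col] = clinical.data[col].reindex(assignments.index)
    if mutations is not None and len(mutations):
        for gene, grp in mutations.data.groupby("Hugo_Symbol"):
            mutated = set(grp["Tumor_Sample_Barcode"])
            features[f"mut:{gene}"] = pd.Series(
                ["mutated" if s in mutated else "wt" for s in assignments.index],
                index=assignments.index,
            )
    rows = []
    for feat, values in features.items():
        mask = values.notna()
        levels = sorted(values[mask].unique())
        if len(levels) < 2:
            continue
        for level in levels:
            is_level = values[mask] == level
            for sub in sorted(assignments.unique()):
                in_sub = assignments[mask] == sub
                table = np.array([
                    [int((is_level & in_sub).sum()), int((is_level & ~in_sub).sum())],
                    [int((~is_level & in_sub).sum()), int((~is_level & ~in_sub).sum())],
                ])
                odds, p = stats.fisher_exact(table)
                rows.append({
                    "feature": feat, "level": level, "subtype": sub,
                    "n_level_in_subtype": table[0, 0], "n_subtype": int(in_sub.sum()),
                    "odds_ratio": odds, "p": p,
                    "direction": "enriched" if odds > 1 else "depleted",
                })
    columns = ["feature", "level", "subtype", "n_level_in_subtype", "n_subtype",
               "odds_ratio", "p", "direction"]
    return pd.DataFrame(rows, columns=columns)


def subtype_survival(assignments: pd.Series, clinical: ClinicalTable):
    """Multi-group log-rank test across subtypes plus per-subtype KM input.

    Returns ``(chi2, p, km_frames)`` where ``km_frames`` maps subtype to a
    step-function DataFrame (time, survival) from the Kaplan-Meier
    estimator.
    """
    common = assignments.index.intersection(clinical.data.index)
    data = clinical.data.loc[common]
    groups = assignments.loc[common]
    if data["event"].sum() < 1:
        raise AnalysisError("no events observed; log-rank test undefined")
    if groups.nunique() < 2:
        raise AnalysisError("need at least two subtypes with samples")
    res = multivariate_logrank_test(data["survival_time"], groups, data["event"])
    from lifelines import KaplanMeierFitter

    km_frames = {}
    for sub in sorted(groups.unique()):
        members = groups.index[groups == sub]
        kmf = KaplanMeierFitter()
        kmf.fit(data.loc[members, "survival_time"], data.loc[members, "event"])
        sf = kmf.survival_function_
        km_frames[sub] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return float(res.test_statistic), float(res.p_value), km_frames


def subtype_proportions(assignments: pd.Series) -> pd.DataFrame:
    """Subtype case counts and their percentage of all tumors (2 decimals)."""
    counts = assignments.value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame({
        "subtype": counts.index,
        "n": counts.to_numpy(),
        "percent": np.round(100.0 * counts.to_numpy() / total, 2),
    })
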