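"""Prognostic screening of functional genes and functional interactions.

Each candidate marker — a functional gene's expression, or a functional
edge's per-patient differential correlation (dPCC, taken from that
patient's SSN, 0 when the edge is absent) — is dichotomized at its median;
the low/high groups are compared by Kaplan-Meier/log-rank, and the group
indicator is fit in univariate and confounder-adjusted multivariate Cox
proportional-hazards models. Markers significant (p < 0.05) in both Cox
models are reported as prognostic biomarkers; no multiple-testing
correction is applied by default, with an optional Benjamini-Hochberg
column for readers who want it. LASSO-penalized Cox with cross-validated
deviance selects the most informative marker subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ValidationError
from .functional_network import FunctionalNetwork
from .io_formats import ClinicalTable, ExpressionMatrix
from .ssn_core import SampleSpecificNetwork

CONFOUNDERS = (
    "sex",
    "pathologic_stage",
    "retrospective_indicator",
    "race",
    "year_of_diagnosis",
    "age_at_diagnosis",
    "microsatellite_status",
)

_CATEGORICAL_CONFOUNDERS = {
    "sex", "pathologic_stage", "retrospective_indicator", "race", "microsatellite_status",
}


@dataclass
class SurvivalGroupSplit:
    marker_id: str
    median: float
    groups: pd.Series  # patient -> "low" / "high"


@dataclass
class CoxResult:
    beta: float
    hr: float
    p: float
    converged: bool = True
    n_used: int = 0


@dataclass
class BiomarkerScreenResult:
    marker_id: str
    marker_kind: str  # "gene" or "edge"
    logrank_p: float
    univariate: CoxResult
    multivariate: CoxResult | None

    @property
    def passes(self) -> bool:
        return (
            self.univariate.converged
            and self.univariate.p < 0.05
            and self.multivariate is not None
            and self.multivariate.converged
            and self.multivariate.p < 0.05
        )


def median_split(values: pd.Series, marker_id: str = "") -> SurvivalGroupSplit:
    """Dichotomize at the median; ties go to the low group (value <= median)."""
    v = values.dropna()
    if len(v) < 2:
        raise AnalysisError("need at least two observed values to split")
    med = float(v.median())
    groups = pd.Series(np.where(v <= med, "low", "high"), index=v.index)
    if groups.nunique() < 2:
        raise AnalysisError(f"degenerate split for {marker_id or 'marker'}: all values tie")
    return SurvivalGroupSplit(marker_id=marker_id, median=med, groups=groups)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    times = pd.Series(times)
    events = pd.Series(events, index=times.index)
    groups = pd.Series(groups, index=times.index)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    a, b = (groups == levels[0]), (groups == levels[1])
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("one group is empty")
    if events.sum() < 1:
        raise AnalysisError("no events; log-rank undefined")
    res = _ll_logrank(times[a], times[b], events[a], events[b])
    return float(res.test_statistic), float(res.p_value)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival step function (time, survival)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def _fit_cox(df: pd.DataFrame, marker_col: str) -> CoxResult:
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="survival_time", event_col="event")
    except Exception:
        return CoxResult(beta=np.nan, hr=np.nan, p=np.nan, converged=False, n_used=len(df))
    beta = float(cph.params_[marker_col])
    return CoxResult(
        beta=beta,
        hr=float(np.exp(beta)),
        p=float(cph.summary.loc[marker_col, "p"]),
        converged=True,
        n_used=len(df),
    )


def _marker_indicator(marker_values: pd.Series, marker_id: str, binary: bool) -> pd.Series:
    if binary:
        split = median_split(marker_values, marker_id)
        return (split.groups == "high").astype(float)
    v = marker_values.dropna()
    if v.std() == 0:
        raise AnalysisError(f"marker {marker_id or '?'} is constant")
    return (v - v.mean()) / v.std()


def cox_univariate(
    marker_values: pd.Series, clinical: ClinicalTable, binary: bool = True
) -> CoxResult:
    """Single-covariate Cox fit of the marker's high/low indicator
    (``binary=False`` uses the standardized continuous value instead)."""
    marker = _marker_indicator(marker_values, str(marker_values.name), binary)
    common = marker.index.intersection(clinical.data.index)
    df = clinical.data.loc[common, ["survival_time", "event"]].copy()
    df["marker"] = marker.loc[common]
    df = df.dropna()
    if df["event"].sum() < 1:
        raise AnalysisError("no events among patients with marker values")
    if df["marker"].nunique() < 2:
        raise AnalysisError("marker indicator constant on the analyzable patients")
    return _fit_cox(df, "marker")


def _dummy_code(df: pd.DataFrame, columns) -> pd.DataFrame:
    """One-hot encode categoricals dropping each column's most frequent level."""
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            continue
        ref = out[col].mode().iloc[0]
        levels = [lv for lv in out[col].unique() if lv != ref]
        for lv in levels:
            out[f"{col}={lv}"] = (out[col] == lv).astype(float)
        out = out.drop(columns=col)
    return out


def cox_multivariate(
    marker_values: pd.Series,
    clinical: ClinicalTable,
    confounders=CONFOUNDERS,
    binary: bool = True,
) -> CoxResult:
    """Confounder-adjusted Cox fit; complete cases only (no imputation).

    Categorical confounders are dummy-coded against their most frequent
    level; numeric confounders are standardized. The returned p-value is
    the marker indicator's adjusted Wald p.
    """
    marker = _marker_indicator(marker_values, str(marker_values.name), binary)
    cols = ["survival_time", "event", *confounders]
    common = marker.index.intersection(clinical.data.index)
    df = clinical.data.loc[common, cols].copy()
    df["marker"] = marker.loc[common]
    df = df.dropna()
    if len(df) < 3 or df["event"].sum() < 1:
        raise AnalysisError("too few complete cases with events for multivariate Cox")
    df = _dummy_code(df, [c for c in confounders if c in _CATEGORICAL_CONFOUNDERS])
    for col in df.columns:
        if col in ("survival_time", "event", "marker"):
            continue
        sd = df[col].std()
        if sd == 0:
            df = df.drop(columns=col)  # single-level after complete-case filter
        elif col in ("year_of_diagnosis", "age_at_diagnosis"):
            df[col] = (df[col] - df[col].mean()) / sd
    if df["marker"].nunique() < 2:
        raise AnalysisError("marker indicator constant on the complete cases")
    return _fit_cox(df, "marker")


def edge_delta_matrix(
    ssns: dict[str, SampleSpecificNetwork], edges, samples=None
) -> pd.DataFrame:
    """Per-patient signed dPCC for each edge, 0 when the edge is absent
    from that patient's SSN. Rows are ``geneA|geneB`` edge ids."""
    edge_ids = {tuple(sorted(e)): f"{min(e)}|{max(e)}" for e in edges}
    samples = list(samples) if samples is not None else list(ssns)
    mat = pd.DataFrame(0.0, index=list(edge_ids.values()), columns=samples)
    for sid in samples:
        table = ssns[sid].table
        if table.empty:
            continue
        for a, b, d in zip(table["gene_a"], table["gene_b"], table["delta_pcc"]):
            key = tuple(sorted((a, b)))
            if key in edge_ids:
                mat.loc[edge_ids[key], sid] = d
    return mat


def screen_biomarkers(
    functional_net: FunctionalNetwork,
    ssns: dict[str, SampleSpecificNetwork],
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    confounders=CONFOUNDERS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split + log-rank + univariate and multivariate Cox for every
    functional gene (expression) and functional edge (dPCC).

    Returns one row per marker with all statistics, a ``passes`` flag
    (both Cox p < alpha), and BH-adjusted univariate p-values as an
    optional extra column (the pass rule itself is uncorrected).
    Markers whose tests degenerate (constant values, no events) are
    reported with NaN statistics and ``passes=False``.
    """
    tumor_ids = [s for s in expr.samples_of_class("tumor") if s in clinical.data.index]
    markers: list[tuple[str, str, pd.Series]] = []
    for g in sorted(functional_net.genes):
        markers.append((g, "gene", expr.values.loc[g, tumor_ids]))
    delta = edge_delta_matrix(ssns, functional_net.edges, samples=tumor_ids)
    for eid in delta.index:
        markers.append((eid, "edge", delta.loc[eid]))

    rows = []
    for mid, kind, values in markers:
        values = values.rename(mid)
        row = {"marker": mid, "kind": kind, "logrank_p": np.nan,
               "uni_beta": np.nan, "uni_hr": np.nan, "uni_p": np.nan,
               "multi_beta": np.nan, "multi_hr": np.nan, "multi_p": np.nan,
               "n_complete": np.nan, "passes": False}
        try:
            split = median_split(values, mid)
            common = split.groups.index.intersection(clinical.data.index)
            chi2, lr_p = logrank_test(
                clinical.data.loc[common, "survival_time"],
                clinical.data.loc[common, "event"],
                split.groups.loc[common],
            )
            row["logrank_p"] = lr_p
            uni = cox_univariate(values, clinical)
            row.update(uni_beta=uni.beta, uni_hr=uni.hr, uni_p=uni.p)
            if uni.converged and uni.p < alpha:
                multi = cox_multivariate(values, clinical, confounders)
                row.update(
                    multi_beta=multi.beta, multi_hr=multi.hr, multi_p=multi.p,
                    n_complete=multi.n_used,
                )
                row["passes"] = bool(multi.converged and multi.p < alpha)
        except AnalysisError:
            pass
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        finite = out["uni_p"].notna()
        out["uni_p_bh"] = np.nan
        if finite.any():
            out.loc[finite, "uni_p_bh"] = multipletests(out.loc[finite, "uni_p"], method="fdr_bh")[1]
    return out


def _partial_loglik(beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of fixed coefficients on a dataset."""
    lp = X @ beta
    order = np.argsort(-times)  # decreasing time: risk sets grow as we walk
    lp_o, t_o, e_o = lp[order], times[order], events[order]
    log_cum = np.logaddexp.accumulate(lp_o)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = log_cum[j]  # everyone with time >= t_o[i]
        for idx in range(i, j + 1):
            if e_o[idx]:
                ll += lp_o[idx] - denom
        i = j + 1
    return float(ll)


def lasso_cox_select(
    marker_matrix: pd.DataFrame,
    clinical: ClinicalTable,
    seed: int = 0,
    n_folds: int = 10,
    n_alphas: int = 50,
):
    """L1-penalized Cox path with the penalty chosen by cross-validated
    partial-likelihood deviance at its minimum; the selected markers are
    refit unpenalized and the joint likelihood-ratio p reported.

    ``marker_matrix`` is patients x markers. Returns
    ``(selected_markers, joint_p, detail_dict)``; an empty selection
    returns ``([], nan, ...)``.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if marker_matrix.shape[1] < 2:
        raise ValidationError("need at least two candidate markers")
    common = marker_matrix.index.intersection(clinical.data.index)
    df = clinical.data.loc[common, ["survival_time", "event"]].join(marker_matrix.loc[common])
    df = df.dropna()
    X = df[marker_matrix.columns].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    times = df["survival_time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01)
    path.fit(X, y)
    alphas = path.alphas_

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    folds = np.array_split(order, n_folds)
    deviance = np.zeros((n_folds, len(alphas)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        import warnings as _warnings

        with _warnings.catch_warnings():
            # folds of an all-null problem legitimately keep every coefficient 0
            _warnings.filterwarnings("ignore", message="all coefficients are zero")
            fit.fit(X[train_idx], y[train_idx])
        n_fit = fit.coef_.shape[1]  # the path may stop early on a fold
        for a_i, alpha in enumerate(alphas):
            beta = fit.coef_[:, min(a_i, n_fit - 1)]
            ll = _partial_loglik(beta, X[test_idx], times[test_idx], events[test_idx])
            deviance[f, a_i] = -2.0 * ll
    mean_dev = deviance.mean(axis=0)
    best = int(np.argmin(mean_dev))
    beta_best = path.coef_[:, best]
    selected = [m for m, b in zip(marker_matrix.columns, beta_best) if b != 0]
    detail = {
        "alphas": alphas, "mean_deviance": mean_dev, "best_alpha": float(alphas[best]),
        "n_used": len(df),
    }
    if not selected:
        return [], float("nan"), detail

    refit_df = df[["survival_time", "event", *selected]]
    cph = CoxPHFitter()
    cph.fit(refit_df, duration_col="survival_time", event_col="event")
    joint_p = float(cph.log_likelihood_ratio_test().p_value)
    detail["refit"] = cph.summary
    return selected, joint_p, detail
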