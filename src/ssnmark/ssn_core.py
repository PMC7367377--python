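"""Sample-specific network (SSN) construction.

An SSN measures how adding one sample to a reference cohort perturbs each
edge of a background co-expression network. For edge (i, j) with Pearson
correlation ``PCC_n`` over the n reference samples and ``PCC_{n+1}`` over
the reference plus the single query sample,

    dPCC = PCC_{n+1} - PCC_n
    z    = dPCC / ((1 - PCC_n^2) / (n - 1))

and z is referred to a standard normal null (two-sided). Edges with
``p < alpha`` form the sample's SSN. The statistic follows from the
sampling behaviour of a correlation coefficient under a single-sample
perturbation: the perturbation a lone extra observation can induce in a
PCC estimated from n samples has standard deviation (1 - PCC^2)/(n - 1)
under the null that the new sample comes from the reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ValidationError
from .io_formats import ExpressionMatrix, ScoredEdgeList


@dataclass
class ReferenceNetwork:
    """Background edges annotated with reference-cohort Pearson correlation.

    Edges whose statistic would be undefined (a constant endpoint or
    |pcc_ref| = 1) are excluded from ``edges``/``pcc_ref`` and counted in
    ``n_degenerate``.
    """

    gene_ids: list[str]
    edge_index: np.ndarray  # (E, 2) integer rows into gene_ids
    pcc_ref: np.ndarray | None = None  # (E,) or None before fitting
    n_ref: int = 0
    n_degenerate: int = 0

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    def edge_pairs(self) -> list[tuple[str, str]]:
        g = self.gene_ids
        return [tuple(sorted((g[i], g[j]))) for i, j in self.edge_index]


@dataclass
class SampleSpecificNetwork:
    """Edges of one sample's SSN with their differential-correlation stats."""

    sample_id: str
    alpha: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene_a, gene_b, pcc_ref, pcc_perturbed, delta_pcc, z, p

    @property
    def edges(self) -> set[tuple[str, str]]:
        if self.table.empty:
            return set()
        return {
            tuple(sorted((a, b)))
            for a, b in zip(self.table["gene_a"], self.table["gene_b"])
        }

    def __len__(self) -> int:
        return len(self.table)


def filter_expressed_genes(expr: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop genes not expressed (value > 0) in at least ``min_fraction`` of samples.

    A gene is removed only when its zero fraction strictly exceeds
    ``1 - min_fraction``; a gene expressed in exactly half the samples
    survives the default filter.
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must be in (0, 1]")
    frac_expressed = (expr.values > 0).mean(axis=1)
    keep = frac_expressed >= min_fraction
    if not keep.any():
        raise AnalysisError("expression filter removed every gene")
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_class)


def build_background(edges: ScoredEdgeList, expr: ExpressionMatrix) -> ReferenceNetwork:
    """Restrict a score-filtered edge list to pairs with expression data."""
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [
        (gene_pos[a], gene_pos[b])
        for a, b in sorted(edges.edges)
        if a in gene_pos and b in gene_pos
    ]
    if not rows:
        raise AnalysisError("no background edge has both endpoints in the expression matrix")
    return ReferenceNetwork(gene_ids=list(expr.gene_ids), edge_index=np.asarray(rows, dtype=np.int64))


def _edge_pcc(values: np.ndarray, edge_index: np.ndarray) -> np.ndarray:
    """Pearson correlation per edge over the columns of ``values``."""
    centered = values - values.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    i, j = edge_index[:, 0], edge_index[:, 1]
    num = np.einsum("ij,ij->i", centered[i], centered[j])
    denom = np.sqrt(ss[i] * ss[j])
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / denom


def compute_reference_pcc(skeleton: ReferenceNetwork, expr_ref: ExpressionMatrix) -> ReferenceNetwork:
    """Annotate the background with per-edge PCC over the reference samples.

    Edges with a constant endpoint or |pcc| = 1 are dropped from testing
    (the z statistic is undefined there) and counted.
    """
    n_ref = expr_ref.n_samples
    if n_ref < 3:
        raise AnalysisError(f"need >= 3 reference samples, got {n_ref}")
    values = expr_ref.values.loc[skeleton.gene_ids].to_numpy(dtype=float)
    pcc = _edge_pcc(values, skeleton.edge_index)
    ok = np.isfinite(pcc) & (np.abs(pcc) < 1.0)
    return ReferenceNetwork(
        gene_ids=skeleton.gene_ids,
        edge_index=skeleton.edge_index[ok],
        pcc_ref=pcc[ok],
        n_ref=n_ref,
        n_degenerate=int((~ok).sum()),
    )


def ssn_statistic(pcc_ref, delta_pcc, n_ref: int):
    """z and two-sided p for a differential correlation dPCC.

    ``z = dPCC / ((1 - pcc_ref^2)/(n_ref - 1))``, referred to N(0, 1).
    Accepts scalars or arrays. Undefined at |pcc_ref| = 1.
    """
    pcc_ref = np.asarray(pcc_ref, dtype=float)
    delta_pcc = np.asarray(delta_pcc, dtype=float)
    if n_ref < 3:
        raise AnalysisError(f"need n_ref >= 3, got {n_ref}")
    if np.any(np.abs(pcc_ref) >= 1.0):
        raise AnalysisError("ssn_statistic undefined at |pcc_ref| = 1 (degenerate edge)")
    z = delta_pcc * (n_ref - 1) / (1.0 - pcc_ref**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def build_ssn(
    expr_ref: ExpressionMatrix,
    sample: pd.Series,
    skeleton: ReferenceNetwork,
    alpha: float = 0.05,
    sample_id: str | None = None,
) -> SampleSpecificNetwork:
    """Construct the SSN of one sample against the reference cohort.

    ``sample`` is an expression vector indexed by gene id covering the
    skeleton's genes. For every testable edge the perturbed PCC over the
    n_ref + 1 columns is recomputed from scratch, dPCC formed, and edges
    with two-sided p < alpha retained. No multiple-testing correction is
    applied (alpha is per-edge).
    """
    if skeleton.pcc_ref is None:
        raise AnalysisError("skeleton lacks reference PCCs; run compute_reference_pcc first")
    missing = [g for g in skeleton.gene_ids if g not in sample.index]
    if missing:
        raise ValidationError(f"query sample missing genes: {missing[:5]}")
    sid = sample_id if sample_id is not None else str(sample.name)

    ref = expr_ref.values.loc[skeleton.gene_ids].to_numpy(dtype=float)
    query = sample.loc[skeleton.gene_ids].to_numpy(dtype=float)[:, None]
    perturbed = np.hstack([ref, query])
    pcc_pert = _edge_pcc(perturbed, skeleton.edge_index)
    delta = pcc_pert - skeleton.pcc_ref
    z, p = ssn_statistic(skeleton.pcc_ref, delta, skeleton.n_ref)

    keep = np.isfinite(pcc_pert) & (p < alpha)
    idx = skeleton.edge_index[keep]
    genes = np.asarray(skeleton.gene_ids, dtype=object)
    table = pd.DataFrame(
        {
            "gene_a": genes[idx[:, 0]],
            "gene_b": genes[idx[:, 1]],
            "pcc_ref": skeleton.pcc_ref[keep],
            "pcc_perturbed": pcc_pert[keep],
            "delta_pcc": delta[keep],
            "z": z[keep],
            "p": p[keep],
        }
    )
    return SampleSpecificNetwork(sample_id=sid, alpha=alpha, table=table)


def build_all_ssns(
    expr: ExpressionMatrix,
    skeleton: ReferenceNetwork,
    alpha: float = 0.05,
    reference_label: str = "normal",
    leave_one_out: bool = False,
) -> dict[str, SampleSpecificNetwork]:
    """SSNs for every sample in ``expr``, using all reference-class samples
    as the reference cohort for every query.

    By default a reference-class sample's own SSN is built against the full
    reference, itself included. With ``leave_one_out=True`` each reference
    sample is instead removed from the cohort before its own SSN is built
    (the reference PCCs are refit per sample).
    """
    ref_ids = expr.samples_of_class(reference_label)
    expr_ref = expr.subset_samples(ref_ids)
    fitted = compute_reference_pcc(skeleton, expr_ref)
    out = {}
    for sid in expr.sample_ids:
        if leave_one_out and sid in ref_ids:
            loo = expr.subset_samples([s for s in ref_ids if s != sid])
            loo_fit = compute_reference_pcc(skeleton, loo)
            out[sid] = build_ssn(loo, expr.values[sid], loo_fit, alpha=alpha, sample_id=sid)
        else:
            out[sid] = build_ssn(expr_ref, expr.values[sid], fitted, alpha=alpha, sample_id=sid)
    return out
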