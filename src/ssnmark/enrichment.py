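"""Hypergeometric over-representation of gene sets.

For a universe of N genes, a known set of size A, a query of size n and an
overlap of k genes, the enrichment p-value is the upper hypergeometric tail

    p = 1 - sum_{i=0}^{k-1} C(A, i) C(N-A, n-i) / C(N, n) = P(X >= k),

computed through the survival function of the hypergeometric distribution
(log-space internally, so deep tails do not overflow). When the exact value
underflows double precision the p-value is reported as 0.0 and the log10
p-value is retained alongside.

The universe size N is a modelling choice and must always be passed
explicitly (for a whole-transcriptome query universe such as the one the
pipeline's expression filter starts from, N is the pre-filter gene count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .functional_network import FunctionalNetwork
from .io_formats import GeneSetCollection

STAR_BINS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class EnrichmentQuery:
    """The four counts of the over-representation test."""

    N: int  # universe size
    A: int  # known-set size
    n: int  # query-set size
    k: int  # overlap

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.A, self.n)):
            raise ValidationError(f"overlap k={self.k} outside [0, min(A, n)]")
        if self.A > self.N or self.n > self.N:
            raise ValidationError("set sizes cannot exceed the universe size")
        if min(self.N, self.A, self.n) < 0:
            raise ValidationError("counts must be nonnegative")


@dataclass
class EnrichmentResult:
    set_name: str
    query: EnrichmentQuery
    p_value: float
    log10_p: float
    overlap_genes: frozenset[str] = frozenset()

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def stars(self) -> str:
        for cutoff, marker in STAR_BINS:
            if self.p_value < cutoff:
                return marker
        return ""


def hypergeometric_pvalue(query: EnrichmentQuery) -> tuple[float, float]:
    """Upper-tail p-value P(X >= k) and its log10, for an EnrichmentQuery."""
    if query.k == 0:
        return 1.0, 0.0
    # sf(k-1) = P(X >= k); logsf covers the underflow regime
    p = float(stats.hypergeom.sf(query.k - 1, query.N, query.A, query.n))
    log10p = float(stats.hypergeom.logsf(query.k - 1, query.N, query.A, query.n) / np.log(10))
    return p, log10p


def enrich_collection(
    query_genes: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """One over-representation test per set in the collection.

    ``collection.universe_size`` must be set. If an explicit ``universe``
    membership is given, query genes outside it are dropped from n with a
    warning (keeping the counts consistent with N).
    """
    if collection.universe_size is None:
        raise ValidationError("collection.universe_size must be set before enrichment")
    N = collection.universe_size
    query = set(query_genes)
    if universe is not None:
        outside = query - universe
        if outside:
            warnings.warn(
                f"{len(outside)} query genes outside the declared universe were dropped",
                stacklevel=2,
            )
            query &= universe
    results = []
    for name, members in collection.sets.items():
        overlap = query & members
        q = EnrichmentQuery(N=N, A=len(members), n=len(query), k=len(overlap))
        p, log10p = hypergeometric_pvalue(q)
        results.append(
            EnrichmentResult(
                set_name=name, query=q, p_value=p, log10_p=log10p,
                overlap_genes=frozenset(overlap),
            )
        )
    return results


def ranked_subset_enrichment(
    net: FunctionalNetwork,
    collection: GeneSetCollection,
    degree_thresholds: tuple[int, ...] = (19, 9, 7, 5, 3, 1),
) -> pd.DataFrame:
    """Enrichment of degree-ranked functional-gene subsets.

    For each threshold t (strictly decreasing) the subset is the functional
    genes with degree strictly greater than t, plus a final row for the full
    functional gene set. Rows whose subset is empty are flagged.
    """
    if any(a <= b for a, b in zip(degree_thresholds, degree_thresholds[1:])):
        raise ValidationError("degree_thresholds must be strictly decreasing")
    rows = []
    subsets = [(f"degree>{t}", net.core_genes(t)) for t in degree_thresholds]
    subsets.append(("all", net.genes))
    for label, genes in subsets:
        if not genes:
            for name in collection.sets:
                rows.append({"subset": label, "set": name, "n": 0, "k": 0,
                             "p": np.nan, "stars": "", "empty": True})
            continue
        for res in enrich_collection(genes, collection):
            rows.append({
                "subset": label, "set": res.set_name, "n": res.query.n,
                "k": res.query.k, "p": res.p_value, "stars": res.stars,
                "empty": False,
            })
    return pd.DataFrame(rows)
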