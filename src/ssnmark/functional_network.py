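"""Aggregation of tumor SSNs into a cancer functional network.

Edges seen in any normal sample's SSN are subtracted from each tumor SSN
(tumor-specific SSNs); an edge recurring in strictly more than a frequency
threshold of tumor SSNs (default 90%) joins the functional network. Nodes
of the functional network are the *functional genes*; those whose degree
strictly exceeds a threshold (default 3) are the *core* functional genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .ssn_core import SampleSpecificNetwork

Edge = tuple[str, str]


@dataclass
class FunctionalNetwork:
    """Recurrent tumor-specific edges with their SSN frequency and degrees."""

    edge_frequency: dict[Edge, float]
    n_tumors: int
    freq_threshold: float
    degree: Counter = field(init=False)

    def __post_init__(self) -> None:
        self.degree = Counter()
        for a, b in self.edge_frequency:
            self.degree[a] += 1
            self.degree[b] += 1

    @property
    def edges(self) -> set[Edge]:
        return set(self.edge_frequency)

    @property
    def genes(self) -> set[str]:
        return set(self.degree)

    def core_genes(self, degree_threshold: int = 3) -> set[str]:
        """Genes with degree strictly greater than ``degree_threshold``."""
        if degree_threshold < 0:
            raise ValidationError("degree_threshold must be >= 0")
        return {g for g, d in self.degree.items() if d > degree_threshold}

    def genes_table(self, degree_threshold: int = 3) -> pd.DataFrame:
        core = self.core_genes(degree_threshold)
        rows = sorted(self.degree.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {"gene": [g for g, _ in rows],
             "degree": [d for _, d in rows],
             "is_core": [g in core for g, _ in rows]}
        )

    def edges_table(self) -> pd.DataFrame:
        rows = sorted(self.edge_frequency.items())
        return pd.DataFrame(
            {"gene_a": [a for (a, _b), _ in rows],
             "gene_b": [b for (_a, b), _ in rows],
             "frequency": [f for _, f in rows]}
        )


def tumor_specific_ssn(
    tumor_ssn: SampleSpecificNetwork, normal_ssns: list[SampleSpecificNetwork]
) -> SampleSpecificNetwork:
    """Remove from a tumor SSN every edge seen in *any* normal sample's SSN."""
    if not normal_ssns:
        raise ValidationError("need at least one normal SSN to subtract")
    normal_union: set[Edge] = set()
    for ssn in normal_ssns:
        normal_union |= ssn.edges
    if tumor_ssn.table.empty:
        return tumor_ssn
    keep = [
        tuple(sorted((a, b))) not in normal_union
        for a, b in zip(tumor_ssn.table["gene_a"], tumor_ssn.table["gene_b"])
    ]
    return SampleSpecificNetwork(
        sample_id=tumor_ssn.sample_id,
        alpha=tumor_ssn.alpha,
        table=tumor_ssn.table.loc[keep].reset_index(drop=True),
    )


def aggregate_functional_network(
    specific_ssns: list[SampleSpecificNetwork], freq_threshold: float = 0.9
) -> FunctionalNetwork:
    """Keep edges present in strictly more than ``freq_threshold`` of tumor SSNs.

    The denominator is the number of tumor samples, including those whose
    specific SSN came out empty.
    """
    if not specific_ssns:
        raise ValidationError("need at least one tumor-specific SSN")
    if not 0 < freq_threshold < 1:
        raise ValidationError("freq_threshold must be in (0, 1)")
    n = len(specific_ssns)
    counts: Counter = Counter()
    for ssn in specific_ssns:
        counts.update(ssn.edges)
    kept = {e: c / n for e, c in counts.items() if c / n > freq_threshold}
    return FunctionalNetwork(edge_frequency=kept, n_tumors=n, freq_threshold=freq_threshold)


def degree_distribution(net: FunctionalNetwork) -> dict[int, int]:
    """Histogram of node degrees; counts sum to the number of functional genes."""
    return dict(sorted(Counter(net.degree.values()).items()))
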