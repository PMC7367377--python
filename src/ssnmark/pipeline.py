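"""End-to-end composition of the SSN stages.

Thin orchestration over the per-stage modules so analysis drivers, the CLI
and the test suite run the identical path: expression filter -> background
mapping -> reference PCC -> per-sample SSNs -> normal-edge subtraction ->
frequency aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .functional_network import (
    FunctionalNetwork,
    aggregate_functional_network,
    tumor_specific_ssn,
)
from .io_formats import NORMAL, TUMOR, ExpressionMatrix, ScoredEdgeList
from .ssn_core import ReferenceNetwork, SampleSpecificNetwork, build_all_ssns, build_background, filter_expressed_genes


@dataclass
class SsnPipelineResult:
    expression: ExpressionMatrix  # after the expressed-gene filter
    skeleton: ReferenceNetwork
    ssns: dict[str, SampleSpecificNetwork]
    specific_ssns: dict[str, SampleSpecificNetwork]  # tumor SSNs minus normal edges
    functional_network: FunctionalNetwork


def run_ssn_pipeline(
    expr: ExpressionMatrix,
    edges: ScoredEdgeList,
    alpha: float = 0.05,
    freq_threshold: float = 0.9,
    min_expressed_fraction: float = 0.5,
    leave_one_out: bool = False,
) -> SsnPipelineResult:
    """Run the full SSN stage on one cohort and aggregate the functional
    network from the tumor-specific SSNs."""
    filtered = filter_expressed_genes(expr, min_expressed_fraction)
    skeleton = build_background(edges, filtered)
    ssns = build_all_ssns(filtered, skeleton, alpha=alpha, reference_label=NORMAL,
                          leave_one_out=leave_one_out)
    normal_ssns = [ssns[s] for s in filtered.samples_of_class(NORMAL)]
    specific = {
        s: tumor_specific_ssn(ssns[s], normal_ssns)
        for s in filtered.samples_of_class(TUMOR)
    }
    net = aggregate_functional_network(list(specific.values()), freq_threshold)
    return SsnPipelineResult(
        expression=filtered, skeleton=skeleton, ssns=ssns,
        specific_ssns=specific, functional_network=net,
    )
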