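"""Build per-sample SSNs and aggregate the tumor functional network.

Each sample's SSN keeps the background edges whose Pearson correlation is
significantly perturbed when that one sample joins the 40-normal reference.
Edges seen in any normal SSN are subtracted from the tumor SSNs, and edges
recurring in >90% of tumor SSNs form the functional network. Reports how
well the network recovers the planted dysregulated edges.

Outputs (results/network/): functional_edges.tsv, functional_genes.tsv,
degree_distribution.tsv, recovery_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SSN_ALPHA, load_pipeline, outdir

from ssnmark.functional_network import degree_distribution


def main() -> None:
    ds, res = load_pipeline()
    net = res.functional_network
    out = outdir("network")
    net.edges_table().to_csv(out / "functional_edges.tsv", sep="\t", index=False)
    net.genes_table(degree_threshold=3).to_csv(out / "functional_genes.tsv",
                                               sep="\t", index=False)
    hist = degree_distribution(net)
    with open(out / "degree_distribution.tsv", "w") as fh:
        fh.write("degree\tn_genes\n")
        for d, c in hist.items():
            fh.write(f"{d}\t{c}\n")

    planted = ds.planted_pairs
    recovery = len(planted & net.edges) / len(planted)
    false_edges = net.edges - planted
    summary = {
        "alpha": SSN_ALPHA,
        "n_background_edges": res.skeleton.n_edges,
        "n_functional_edges": len(net.edges),
        "n_functional_genes": len(net.genes),
        "n_core_genes": len(net.core_genes(3)),
        "planted_recovery": recovery,
        "n_false_edges": len(false_edges),
    }
    (out / "recovery_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"SSNs built for {len(res.ssns)} samples at per-edge alpha {SSN_ALPHA}")
    print(f"functional network: {len(net.edges)} edges over {len(net.genes)} genes "
          f"({len(net.core_genes(3))} core genes with degree > 3)")
    print(f"planted-edge recovery {recovery:.0%}, {len(false_edges)} false edges")


if __name__ == "__main__":
    main()
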