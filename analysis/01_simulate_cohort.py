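"""Generate the study cohort and write every input file the later stages read.

Outputs (results/cohort/): expression.tsv, sample_classes.tsv, edges.tsv,
gene_sets.gmt, clinical.tsv, mutations.tsv, truth.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_cohort, outdir

from ssnmark import io_formats as iof


def main() -> None:
    ds = load_cohort()
    out = outdir("cohort")
    iof.write_expression_table(ds.expression, out / "expression.tsv")
    with open(out / "sample_classes.tsv", "w") as fh:
        for sid, label in ds.expression.sample_class.items():
            fh.write(f"{sid}\t{label}\n")
    iof.write_scored_edges(ds.edge_list, out / "edges.tsv")
    iof.write_gmt(ds.gene_sets, out / "gene_sets.gmt")
    iof.write_clinical_table(ds.clinical, out / "clinical.tsv")
    iof.write_mutation_table(ds.mutations, out / "mutations.tsv")
    truth = {
        "planted_edges": sorted(map(list, ds.planted_pairs)),
        "subtype": ds.truth.subtype.to_dict(),
        "hazard_genes": ds.config.hazard_genes,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    n_norm = len(ds.expression.samples_of_class("normal"))
    n_tum = len(ds.expression.samples_of_class("tumor"))
    print(f"cohort: {ds.expression.n_genes} genes, {n_norm} normal + {n_tum} tumor samples")
    print(f"background network: {len(ds.model.edges)} edges "
          f"({len(ds.model.planted)} planted, carried by "
          f"{ds.config.planted_frequency:.0%} of tumors)")
    print(f"survival driven by {ds.config.hazard_genes}")
    summary = iof.summarize_mutations(ds.mutations)
    print("top mutated genes:", dict(summary["gene_ranking"].head(4)))
    print(f"wrote cohort files to {out}")


if __name__ == "__main__":
    main()
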