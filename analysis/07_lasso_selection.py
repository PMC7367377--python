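"""LASSO-Cox selection of the most informative prognostic gene panel.

Takes the genes passing the prognostic screen (stage 06), fits an
L1-penalized Cox path with the penalty chosen by 10-fold cross-validated
partial-likelihood deviance, refits the selected panel unpenalized, and
reports the joint likelihood-ratio p-value.

Outputs (results/survival/): lasso_selection.json, lasso_path.tsv.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_pipeline, outdir

from ssnmark.survival_biomarkers import lasso_cox_select, screen_biomarkers


def main() -> None:
    ds, res = load_pipeline()
    out = outdir("survival")
    screen = screen_biomarkers(res.functional_network, res.ssns,
                               res.expression, ds.clinical)
    genes = screen[(screen["kind"] == "gene") & screen["passes"]]["marker"].tolist()
    if len(genes) < 2:
        # too few screen hits to select among: fall back to all functional genes
        genes = sorted(res.functional_network.genes)
    tumor_ids = [s for s in res.expression.samples_of_class("tumor")
                 if s in ds.clinical.data.index]
    markers = res.expression.values.loc[genes, tumor_ids].T

    selected, joint_p, detail = lasso_cox_select(markers, ds.clinical, seed=0)
    pd.DataFrame({"alpha": detail["alphas"],
                  "cv_deviance": detail["mean_deviance"]}).to_csv(
        out / "lasso_path.tsv", sep="\t", index=False)
    (out / "lasso_selection.json").write_text(json.dumps({
        "candidates": genes, "selected": selected, "joint_p": joint_p,
        "best_alpha": detail["best_alpha"], "n_patients": detail["n_used"],
    }, indent=1))

    print(f"{len(genes)} candidate genes entered the LASSO-Cox selection")
    print(f"selected {len(selected)} genes: {selected}")
    print(f"joint unpenalized model: likelihood-ratio p = {joint_p:.3g} "
          f"(penalty {detail['best_alpha']:.4g}, n = {detail['n_used']})")
    truth = set(ds.config.hazard_genes)
    print(f"planted hazard genes among selected: {sorted(truth & set(selected))}")


if __name__ == "__main__":
    main()
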