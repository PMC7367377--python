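"""Shared study conditions for the analysis drivers.

One synthetic cohort stands in for a tumor/normal expression study:
200 genes over a background interaction network, 40 normal and 100 tumor
samples, 20 planted dysregulated edges carried by 95% of tumors, six
mean-shift subtypes, and proportional-hazards survival driven by three
planted-edge genes. All drivers derive their inputs deterministically from
this one configuration, so each script can be run independently.
"""

from pathlib import Path

from ssnmark import SimulationConfig, run_ssn_pipeline, simulate_dataset
from ssnmark.synthetic_data import make_reference_model

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: per-edge significance used throughout the run; the strict level is what
#: the delete-edges-in-any-normal-SSN rule demands (see docs/methods.md)
SSN_ALPHA = 1e-5

_BASE = dict(seed=11, perturb_shift=4.0, censoring_rate=0.4)


def study_config() -> SimulationConfig:
    """The cohort's generating conditions, with survival driven by three
    functional (planted-edge) genes so the prognostic screen has targets."""
    planted = sorted({g for p in make_reference_model(SimulationConfig(**_BASE)).planted_pairs
                      for g in p})
    hazard = {planted[0]: 1.0, planted[2]: -1.0, planted[4]: 0.8}
    return SimulationConfig(**_BASE, hazard_genes=hazard)


def load_cohort():
    return simulate_dataset(study_config())


def load_pipeline(dataset=None):
    ds = dataset if dataset is not None else load_cohort()
    return ds, run_ssn_pipeline(ds.expression, ds.edge_list, alpha=SSN_ALPHA)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
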