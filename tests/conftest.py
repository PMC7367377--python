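import pytest

from ssnmark import SimulationConfig, simulate_dataset, run_ssn_pipeline


@pytest.fixture(scope="session")
def strong_dataset():
    """Desk-scale cohort in the strong-dysregulation regime (sign-flip
    decorrelation plus +/-4 SD endpoint shift on planted edges)."""
    return simulate_dataset(SimulationConfig(seed=1, perturb_shift=4.0))


@pytest.fixture(scope="session")
def strong_pipeline(strong_dataset):
    """Full SSN pipeline on the strong cohort at the strict per-edge alpha
    the normal-union subtraction requires."""
    return run_ssn_pipeline(strong_dataset.expression, strong_dataset.edge_list, alpha=1e-5)


@pytest.fixture(scope="session")
def tumor_expression(strong_dataset):
    ds = strong_dataset
    return ds.expression.subset_samples(ds.expression.samples_of_class("tumor"))
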