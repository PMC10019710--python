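import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cometa.cohort import ExpressionDataset
from cometa.simulate import SimulationConfig, simulate_cohorts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """Four modest synthetic cohorts with a planted 40-gene signature."""
    cfg = SimulationConfig(
        seed=11, n_datasets=4, sizes=((30, 30), (25, 20), (40, 30), (30, 25)),
        n_genes=300, n_signature_up=20, n_signature_down=20,
        true_effect=0.8, tau2=0.05, dropout_fraction=0.1,
    )
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-scale default simulation (7 heterogeneous cohorts)."""
    return simulate_cohorts(SimulationConfig(seed=0))


def make_dataset(values, labels, dataset_id="DS1", genes=None):
    """Tiny ExpressionDataset from a nested list (genes x samples)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    lab = pd.Series(labels, index=samples)
    return ExpressionDataset(dataset_id=dataset_id, expr=expr, labels=lab)


@pytest.fixture
def toy_dataset():
    """3 genes x 6 samples, clear case/control separation in G0."""
    return make_dataset(
        [[5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
         [2.0, 2.5, 2.2, 2.1, 2.4, 2.3],
         [1.0, 3.0, 2.0, 4.0, 2.5, 3.5]],
        ["case"] * 3 + ["control"] * 3,
    )
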