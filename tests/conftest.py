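import numpy as np
import pandas as pd
import pytest

from epidriver import SimulationConfig, simulate_cohort, simulate_network, simulate_omics
from epidriver.containers import OmicsMatrix


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def omics_bundle(default_config):
    """One simulated omics data set shared across tests (seed fixed)."""
    expr, beta, annotations, genes, labels = simulate_omics(default_config)
    return {
        "expr": expr,
        "beta": beta,
        "annotations": annotations,
        "genes": genes,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def network_bundle(default_config, omics_bundle):
    net = simulate_network(default_config, omics_bundle["labels"])
    return {"net": net, "labels": omics_bundle["labels"]}


@pytest.fixture(scope="session")
def cohort(default_config):
    return simulate_cohort(default_config)


def make_matrix(values, groups, index=None):
    """Small OmicsMatrix helper for hand-built examples."""
    df = pd.DataFrame(values, index=index)
    df.columns = list(groups.keys())
    return OmicsMatrix(df, pd.Series(groups))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
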