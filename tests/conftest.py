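import numpy as np
import pandas as pd
import pytest

import refstab as r


@pytest.fixture(scope="session")
def paper_config():
    return r.default_config_paper()


@pytest.fixture(scope="session")
def sim_result(paper_config):
    """One full simulated experiment (traces included), reused read-only."""
    return r.simulate_experiment(paper_config, seed=1)


@pytest.fixture(scope="session")
def quantified(sim_result):
    """Quantification of the session experiment's traces."""
    return r.quantify_traces(sim_result.traces)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_positive_matrix(rng, n_genes, n_samples, log2_sd=0.5):
    """Random positive expression matrix with multiplicative noise."""
    values = np.exp2(rng.normal(0.0, log2_sd, size=(n_genes, n_samples)))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
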