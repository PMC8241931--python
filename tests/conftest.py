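import logging

import numpy as np
import pytest

import rhizosip.io as rio
from rhizosip.models import GradientModel, SequencingModel
from rhizosip.pipeline import RunConfig, analyze_tables, partition_runs, pool_all
from rhizosip.synthetic import default_community_design, simulate_study

logging.getLogger("rhizosip").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gmodel():
    return GradientModel()


@pytest.fixture(scope="session")
def noiseless_smodel():
    return SequencingModel(library_size=50_000, qpcr_noise_cv=0.0)


@pytest.fixture(scope="session")
def dataset():
    """One default simulated study, shared across tests."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def pooled_counts(dataset):
    partitions = partition_runs(dataset.runs)
    return rio.pooled_counts_frame(pool_all(dataset.runs, partitions))


@pytest.fixture(scope="session")
def analysis(dataset, pooled_counts):
    return analyze_tables(pooled_counts, RunConfig(mode="synthetic", seed=1))


@pytest.fixture(scope="session")
def abundance_table(analysis):
    return analysis["table"]
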