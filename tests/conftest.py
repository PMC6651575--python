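"""Shared fixtures: a small simulated dataset reused across test modules."""

import pytest

from memlig.pipeline import build_dataset, encode_features
from memlig.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """30 simulated proteins with default planted signal."""
    return simulate(SimConfig(n_proteins=30, seed=7))


@pytest.fixture(scope="session")
def features_small(sim_small):
    return encode_features(sim_small.proteins, sim_small.profiles, sim_small.topologies)


@pytest.fixture(scope="session")
def dataset_small(sim_small, features_small):
    return build_dataset(sim_small.proteins, features_small)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete simulated fixture directory on disk (20 proteins)."""
    out = tmp_path_factory.mktemp("fixture")
    simulate(SimConfig(n_proteins=20, seed=3), outdir=out)
    return out
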