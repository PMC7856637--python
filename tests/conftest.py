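"""Shared fixtures.

Expensive artifacts (a default synthetic run, its ICA decomposition and voxel
analysis) are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

import tcmcorr as tc
from tcmcorr.config import PipelineConfig
from tcmcorr.pipeline import analyze_dataset


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def schedule():
    return tc.make_schedule(seed=42)


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic run (20x20x10x177) with ground truth."""
    return tc.simulate_collection(1, seed=3)[0]


@pytest.fixture(scope="session")
def decomp(default_run):
    return tc.decompose(default_run, seed=1)


@pytest.fixture(scope="session")
def analysis(default_run, config):
    return analyze_dataset([default_run], config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
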