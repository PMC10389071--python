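import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import randgen as rg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230751)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """200 uniform-random digit sequences with lengths 3..80."""
    out = []
    for _ in range(200):
        n = int(rng.integers(3, 81))
        out.append([int(d) for d in rng.integers(1, 11, size=n)])
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-participant synthetic cohort (3 ASD / 2 CTRL), fixed seed."""
    scenario = rg.GroupScenario(
        params_asd=rg.default_paper_like_params("ASD"),
        params_ctrl=rg.default_paper_like_params("CTRL"),
        n_asd=3,
        n_ctrl=2,
        seed=11,
    )
    return rg.sample_cohort(scenario)


@pytest.fixture(scope="session")
def paper_like_cohort():
    """A full-size (36/40) calibrated synthetic cohort, fixed seed."""
    return rg.sample_cohort(rg.default_scenario(seed=5))


@pytest.fixture(scope="session")
def paper_like_features(paper_like_cohort):
    return rg.feature_table(paper_like_cohort.sequences)
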