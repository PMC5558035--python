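import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from connfrag.io import Connectome
from connfrag.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A fast miniature cohort configuration for pipeline-level tests."""
    return SyntheticConfig(
        n_subjects=8,
        n_regions_per_hemisphere=20,
        rich_club_size=0,
        fi_n_runs=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture()
def two_dyads() -> Connectome:
    """Two disjoint unit-weight edges: (0,1) and (2,3)."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    return Connectome(("a", "b", "c", "d"), w)


@pytest.fixture()
def two_cliques() -> Connectome:
    """Two disjoint unit-weight 4-cliques."""
    w = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return Connectome(tuple("abcdefgh"), w)
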