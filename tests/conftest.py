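"""Shared fixtures.

The trained cohort is expensive (a few minutes per network), so it is
built once per session and shared by every test that needs trained
networks; analyses derived from it are likewise session-cached.
"""

import numpy as np
import pytest

from flexdec import pipeline

COHORT_SEED = 1
N_NETS = 5


@pytest.fixture(scope="session")
def trained_cohort():
    """Five independently initialized networks trained at default config."""
    return pipeline.train_cohort(N_NETS, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def trained_nets(trained_cohort):
    return [p for p, _ in trained_cohort]


@pytest.fixture(scope="session")
def batteries(trained_nets):
    """Intact-network test batteries at the untrained coherences."""
    return [pipeline.test_battery(p, seed=100 + i)
            for i, p in enumerate(trained_nets)]
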