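import logging

import numpy as np
import pytest

from embryopt.dataset import expand_replicates, load_treatment_means

# clipping warnings from moment-matched replicate reconstruction are expected
logging.getLogger("embryopt.dataset").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def treatment_means():
    return load_treatment_means()


@pytest.fixture(scope="session")
def replicates(treatment_means):
    """Canonical replicate-level table (seed 0) shared across tests."""
    return expand_replicates(treatment_means, n_reps=9, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
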