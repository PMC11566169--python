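import logging

import numpy as np
import pytest

import agestrata as ag

logging.getLogger("agestrata").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_survey():
    """A 400-record synthetic survey table with ground truth."""
    params = ag.paper_like_scenario(n=400, seed=11)
    return ag.generate_survey(params)


@pytest.fixture(scope="session")
def small_coded(small_survey):
    raw, truth = small_survey
    return ag.code_records(raw), truth


def two_class_indicators(seed: int, n: int = 2000, sep: float = 0.9, n_items: int = 3):
    """Binary indicator table from two well-separated latent classes."""
    rng = np.random.default_rng(seed)
    z = rng.random(n) < 0.5
    p = np.where(z[:, None], sep, 1.0 - sep)
    x = (rng.random((n, n_items)) < p).astype(int)
    return x, z
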