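import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from promise_mmi.seedmatch import SeedMatchMatrix
from promise_mmi.simulate import make_toy


@pytest.fixture
def toy():
    return make_toy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_system(rng, n_genes, n_mirnas, density=0.5):
    """Random seed matrix plus positive expression vectors."""
    counts = (rng.random((n_genes, n_mirnas)) < density) * rng.integers(
        1, 4, size=(n_genes, n_mirnas))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        C = SeedMatchMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"m{k}" for k in range(n_mirnas)],
            counts.astype(np.int64),
        )
    x = rng.lognormal(0.0, 1.0, n_genes)
    z = rng.lognormal(0.0, 1.0, n_mirnas)
    return C, x, z
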