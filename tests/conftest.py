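import numpy as np
import pytest

from clonotrace import make_dictionary, simulate_population


@pytest.fixture(scope="session")
def small_dict():
    """50 well-separated 18-mers: unique <=2-mismatch matching guaranteed."""
    return make_dictionary(n=50, length=18, min_dist=5, seed=11)


@pytest.fixture(scope="session")
def population(small_dict):
    return simulate_population(small_dict, n_clones=200, resistant_fraction=0.4, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_fate_counts(rng, n_timepoints=3, max_clones=60):
    """Random per-code clone counts over all nonzero occurrence codes."""
    import itertools

    codes = [
        "".join(b)
        for b in itertools.product("01", repeat=n_timepoints)
        if "1" in b
    ]
    return {c: int(rng.integers(0, max_clones)) for c in codes}
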