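import numpy as np
import pytest

from sascreen import simulate


@pytest.fixture(scope="session")
def small_screen():
    """A small synthetic depletion screen shared by read-only tests."""
    return simulate.simulate_screen(
        n_sites=800, genome_bp=60_000, seed=11,
        design=simulate.ScreenDesign(mode="depletion",
                                     n_replicates_per_condition=3,
                                     read_depth=300_000, generations=3.0),
    )


@pytest.fixture(scope="session")
def small_scores(small_screen):
    from sascreen import scoring
    return scoring.score_table(small_screen.counts, "depletion",
                               n_instances=64, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
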