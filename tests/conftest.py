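import numpy as np
import pytest

import poscreen as ps


@pytest.fixture(scope="session")
def full_library() -> ps.GuideLibrary:
    """Genome-wide default profile (122,756 records); generated once per session."""
    return ps.generate_library("gecko_v2_default", seed=1)


@pytest.fixture(scope="session")
def mini_library() -> ps.GuideLibrary:
    return ps.generate_library("mini", seed=1)


@pytest.fixture(scope="session")
def mini_screen(mini_library):
    """A small simulated screen shared across hit-calling tests."""
    truth = frozenset({"GENE00001", "GENE00002", "GENE00003", "GENE00010"})
    config = ps.ScreenConfig(
        n_cells=100_000, truth_genes=truth, read_depth=100_000, seed=3
    )
    countset, truth_rec = ps.simulate_screen(mini_library, config)
    return countset, truth_rec


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
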