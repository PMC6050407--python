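import numpy as np
import pytest

from qflow.synthetic import generate_beads, generate_cells, paperlike_scenario


@pytest.fixture(scope="session")
def paperlike_truth():
    return paperlike_scenario(seed=11)


@pytest.fixture(scope="session")
def paperlike_events(paperlike_truth):
    """One shared 20,000-event draw from the benchmark scenario."""
    events, truth_df = generate_cells(paperlike_truth, n=20_000, seed=11)
    return events, truth_df


@pytest.fixture(scope="session")
def paperlike_beads(paperlike_truth):
    return generate_beads(paperlike_truth, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
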