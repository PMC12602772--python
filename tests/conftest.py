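import numpy as np
import pytest

from owlbaci import synthetic as syn


@pytest.fixture(scope="session")
def tiny_landscape():
    fires = [
        syn.FireSpec(2020, (5000.0, 5000.0), 4000.0, 0.5),
        syn.FireSpec(2021, (11000.0, 11000.0), 4000.0, 0.56),
    ]
    return syn.simulate_landscape((16_000.0, 16_000.0), 20.0, fires, seed=11)


@pytest.fixture(scope="session")
def tiny_survey(tiny_landscape):
    return syn.simulate_survey(tiny_landscape, n_hex=8, seed=12)


@pytest.fixture(scope="session")
def tiny_truth():
    t = syn.TruthParams(seed=13)
    t.n_removals = 3
    return t


@pytest.fixture(scope="session")
def tiny_detections(tiny_survey, tiny_landscape, tiny_truth):
    det, info = syn.simulate_detections(
        tiny_survey, tiny_landscape, tiny_truth, "bo_tc",
        species="flammulated", seed=14)
    return det, info


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
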