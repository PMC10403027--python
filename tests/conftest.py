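import numpy as np
import pytest

import eolpathways as eol


def random_state_sequences(rng, n_pairs, min_len=1, max_len=30):
    """Random test sequences over the 5-state alphabet, varied lengths."""
    out = []
    for _ in range(n_pairs):
        length = int(rng.integers(min_len, max_len + 1))
        out.append(rng.integers(0, 5, size=length).astype(np.uint8))
    return out


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort shared by model-level tests."""
    model, truth = eol.CarePathwayModel.simulate(
        eol.CohortConfig(n_patients=120, seed=11),
        eol.ArchetypeConfig(mixture_weights=(0.5, 0.3, 0.2), seed=12),
        eol.CostConfig(seed=13),
    )
    return model, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150101)
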