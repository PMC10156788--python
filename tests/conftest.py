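import numpy as np
import pytest

from trpckit import synthetic as syn


@pytest.fixture
def gating_model():
    """A well-resolved two-state channel: slow gating, clean amplitude."""
    return syn.GatingModel(opening_rate=20.0, closing_rate=30.0,
                           unitary_current=-2.0, noise_sd=0.2,
                           duration=10.0, seed=11)


@pytest.fixture
def study_pattern_freqs():
    """Occupancy-pattern frequencies matching the reported stoichiometry
    distribution of the tetramer (1 / 2-trans / 2-cis / 3 / 4 bound)."""
    return syn.PatternFrequencies({
        "1": 0.338, "2-trans": 0.086, "2-cis": 0.291, "3": 0.223, "4": 0.062,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
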