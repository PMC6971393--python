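import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from locodyn import preprocess, synergies, synthetic_emg


@pytest.fixture(scope="session")
def reference():
    """Default 13-muscle, 4-synergy ground truth."""
    return synthetic_emg.make_reference_synergies()


@pytest.fixture(scope="session")
def events_30():
    """30 walking cycles with 20 ms timing jitter."""
    return synthetic_emg.make_gait_events(n_cycles=30, timing_jitter_sd_ms=20.0,
                                          seed=7)


@pytest.fixture(scope="session")
def trial_default(reference, events_30):
    """One synthesized trial at the default variability settings."""
    var = synthetic_emg.VariabilityParams(seed=7)
    return synthetic_emg.synthesize_trial(reference, events_30, var)


@pytest.fixture(scope="session")
def cycle_matrix(trial_default, events_30):
    env = preprocess.envelope(trial_default)
    return preprocess.segment_normalize(env, events_30)


@pytest.fixture(scope="session")
def synergy_set(cycle_matrix, reference):
    syn = synergies.nmf(cycle_matrix, 4, n_restarts=3, seed=0)
    return synergies.classify(syn, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
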