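import numpy as np
import pandas as pd
import pytest

from somnolearn import io as sio
from somnolearn import pipeline as pl
from somnolearn import simulate as sim


@pytest.fixture(scope="session")
def tiny_study():
    """Four participants, six blocks, 100 Hz, default planted effects."""
    config = sim.SimConfig(n_participants=4, n_blocks=6, fs=100.0, seed=7)
    recordings, truth = sim.simulate_study(config)
    return config, recordings, truth


@pytest.fixture(scope="session")
def tiny_epochs(tiny_study):
    _, recordings, _ = tiny_study
    ana = pl.AnalysisConfig()
    return [pl.prepare_epochs(rec, ana) for rec in recordings]


def make_epochs(data, fs=1000.0, conditions=None, blocks=None, reinforced=None):
    """Hand-built EpochSet around a (trials, channels, time) array."""
    n_tr, _, n_t = data.shape
    window = (-(n_t - 1) // 2, n_t - 1 - (n_t - 1) // 2)
    times = np.arange(window[0], window[1] + 1) * 1000.0 / fs
    events = pd.DataFrame({
        "onset_s": np.arange(n_tr) * 30.0 + 100.0,
        "tone_hz": 400,
        "condition": conditions if conditions is not None else ["CSu"] * n_tr,
        "reinforced": reinforced if reinforced is not None else [False] * n_tr,
        "block": blocks if blocks is not None else [1] * n_tr,
        "session": "night",
    })
    return sio.EpochSet(
        participant_id="toy", data=np.asarray(data, float), times_ms=times,
        channel_names=["C3", "C4"], fs=fs, events=events,
        included=np.ones(n_tr, bool),
        exclusion_reason=np.array([""] * n_tr, object),
        phase=np.array(["unassigned"] * n_tr, object),
    )


@pytest.fixture
def toy_epochs_factory():
    return make_epochs
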