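import numpy as np
import pandas as pd
import pytest

from flightload import (
    Recording,
    SimulationConfig,
    generate_events,
    generate_recording,
)
from flightload.recording_io import EpochSet


@pytest.fixture(scope="session")
def short_config():
    """Reduced-duration generator settings for fast module tests.

    Only the recording length and stimulus count are scaled down; effect
    sizes, noise level and artifact amplitudes are the package defaults.
    """
    return SimulationConfig(duration_per_condition=120.0, n_stimuli=40, seed=7)


@pytest.fixture(scope="session")
def short_session(short_config):
    """One low-load condition with artifacts, plus its ground truth."""
    events = generate_events(short_config, "low")
    recording, log = generate_recording(short_config, events, "low")
    return short_config, events, recording, log


@pytest.fixture(scope="session")
def clean_recording(short_config):
    """Artifact-free low-load recording (rates forced to zero)."""
    import dataclasses

    cfg = dataclasses.replace(
        short_config, artifact_rates={"blink": 0.0, "burst": 0.0}
    )
    events = generate_events(cfg, "low")
    recording, log = generate_recording(cfg, events, "low")
    assert len(log) == 0
    return cfg, events, recording


def make_epochs(data, tmin=0.0, fs=500.0, channels=None, conditions=None,
                stimuli=None):
    """Assemble an EpochSet from a raw (epochs × channels × samples) array."""
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, _ = data.shape
    channels = tuple(channels or [f"ch{i}" for i in range(n_ch)])
    metadata = pd.DataFrame(
        {
            "onset": np.arange(n_ep, dtype=float),
            "stimulus": stimuli if stimuli is not None else ["target"] * n_ep,
            "condition": conditions if conditions is not None else ["low"] * n_ep,
        }
    )
    return EpochSet(data, tmin, fs, channels, metadata)


@pytest.fixture
def toy_recording():
    rng = np.random.default_rng(0)
    return Recording(rng.standard_normal((3, 5000)), 500.0, ("Fz", "Cz", "Pz"))
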