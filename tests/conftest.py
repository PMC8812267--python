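"""Shared fixtures: small synthetic sessions and their processed products.

Session-scoped fixtures keep the suite fast: one 30-s-per-block session is
generated once and reused by the preprocessing/feature tests.
"""

import numpy as np
import pandas as pd
import pytest

from neuroload import SessionConfig
from neuroload import eeg_preproc, fnirs_preproc, synthgen
from neuroload.types import RawSession


@pytest.fixture(scope="session")
def small_config() -> SessionConfig:
    return SessionConfig(n_subjects=2, block_duration=30.0, seed=7)


@pytest.fixture(scope="session")
def session(small_config) -> "RawSession":
    return synthgen.generate_session(small_config, "S00")


@pytest.fixture(scope="session")
def eeg_epochs(session):
    return eeg_preproc.preprocess_eeg(session)


@pytest.fixture(scope="session")
def fnirs_epochs(session):
    return fnirs_preproc.preprocess_fnirs(session)


def tiny_session(values: dict, rate: float = 200.0, seconds: float = 6.0,
                 block_duration: float = 6.0,
                 events=None) -> RawSession:
    """Hand-built session: ``values`` maps channel label -> constant value
    or sample array of length rate*seconds."""
    n = int(rate * seconds)
    channels = list(values)
    eeg = np.zeros((len(channels), n))
    for i, ch in enumerate(channels):
        eeg[i, :] = values[ch]
    fnirs = np.zeros((2, 2, int(50 * seconds)))
    return RawSession(
        subject_id="tiny", eeg=eeg, eeg_channels=channels, eeg_rate=rate,
        fnirs=fnirs, fnirs_rate=50.0,
        events=events if events is not None else [(0.0, 1)],
        block_duration=block_duration)
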