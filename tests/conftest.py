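"""Shared fixtures: small synthetic sessions and a trained wake model.

Sessions are deliberately smaller than the full study design (8 wake
sequences instead of 70, short inter-block gaps) so the whole suite runs
quickly; signal amplitudes are high enough that the reduced trial counts
still support stable classification.
"""

import numpy as np
import pytest

import tmrdecode as td


@pytest.fixture(scope="session")
def wake_session():
    cfg = td.SynthConfig(
        seed=1, n_sequences=8, snr=5.0, sequences_per_block=4, interblock_s=30.0
    )
    return td.generate_wake_session(cfg)


@pytest.fixture(scope="session")
def wake_epochs(wake_session):
    return td.prepare_wake_epochs(
        wake_session.recording, wake_session.quiet_intervals, seed=7
    )


@pytest.fixture(scope="session")
def wake_eval(wake_epochs):
    return td.evaluate_repeated_splits(wake_epochs, repeats=2, seed=3, scan_limit=20)


@pytest.fixture(scope="session")
def trained_model(wake_eval):
    return wake_eval.models[0]


@pytest.fixture(scope="session")
def sleep_session():
    cfg = td.SynthConfig(
        seed=9, n_sequences=5, snr=5.0, sleep_latency_jitter_ms=200, interblock_s=20.0
    )
    return td.generate_sleep_session(cfg)


@pytest.fixture(scope="session")
def sleep_epochs(sleep_session):
    return td.segment_epochs(sleep_session.recording)


@pytest.fixture(scope="session")
def sleep_decoding(trained_model, sleep_epochs):
    return td.decode_session(trained_model, sleep_epochs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
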