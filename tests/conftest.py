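"""Shared fixtures: one small synthetic session carried through the pipeline.

Session-scoped so the generation and preprocessing cost is paid once; tests
must not mutate the fixture sessions (copy first if needed).
"""

import numpy as np
import pytest

import moveintent as mi


@pytest.fixture(scope="session")
def small_session():
    """24-trial synthetic session with the default ERD depths, plus truth."""
    cfg = mi.GeneratorConfig(n_trials=24, seed=7)
    return mi.generate_session(cfg) + (cfg,)


@pytest.fixture(scope="session")
def aligned_small(small_session):
    sess, truth, cfg = small_session
    return mi.screen_and_realign(sess)


@pytest.fixture(scope="session")
def clean_small(aligned_small):
    return mi.preprocess_session(aligned_small)


@pytest.fixture(scope="session")
def trimmed_small(clean_small):
    return mi.trim_common(clean_small)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def sinusoid_trial(freq, fs=256.0, duration=7.0, t0=-6.0, amp=10.0,
                   n_channels=1, time_ref="onset"):
    """Single- or multi-channel pure-tone trial for filter/TFR checks."""
    t = t0 + np.arange(int(round(duration * fs))) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return mi.Trial(eeg=np.tile(x, (n_channels, 1)), emg=None, fs=fs, t0=t0,
                    time_ref=time_ref, onset=0.0 if time_ref == "onset" else None)
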