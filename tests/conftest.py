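"""Shared fixtures: small synthetic datasets and rhythm series."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sp_signal

from emdcsp import synthgen
from emdcsp.io_cli import bandpass_rhythms


def bandpass_oracle(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Independent zero-phase band-pass reference used by several tests."""
    sos = sp_signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, x, axis=-1)


@pytest.fixture(scope="session")
def lateralized_config() -> synthgen.SynthConfig:
    """Classes differ in total (mu + beta) power, lateralized by hemisphere."""
    sources = (
        synthgen.SourceSpec(*synthgen.MU_BAND, amp_left_class=(1.2, 0.6),
                            amp_right_class=(0.6, 1.2)),
        synthgen.SourceSpec(*synthgen.BETA_BAND, amp_left_class=(1.2, 0.6),
                            amp_right_class=(0.6, 1.2)),
    )
    return synthgen.SynthConfig(n_trials_per_class=40, noise_sd=0.2, seed=7,
                                sources=sources)


@pytest.fixture(scope="session")
def lateralized_dataset(lateralized_config):
    return synthgen.generate_dataset(lateralized_config)


@pytest.fixture(scope="session")
def diff_only_config() -> synthgen.SynthConfig:
    sources = (
        synthgen.SourceSpec(*synthgen.MU_BAND, amp_left_class=(2.0, 0.4),
                            amp_right_class=(2.0, 0.4)),
        synthgen.SourceSpec(*synthgen.BETA_BAND),
    )
    base = synthgen.SynthConfig(n_trials_per_class=60, noise_sd=0.2, seed=11,
                                sources=sources, amp_jitter_sd=0.05)
    return synthgen.make_difference_only_config(base)


@pytest.fixture(scope="session")
def diff_only_dataset(diff_only_config):
    return synthgen.generate_dataset(diff_only_config)


@pytest.fixture(scope="session")
def diff_only_rhythms(diff_only_dataset):
    trials, _ = diff_only_dataset
    mu, beta = bandpass_rhythms(trials)
    return trials, mu, beta


@pytest.fixture(scope="session")
def lateralized_rhythms(lateralized_dataset):
    trials, _ = lateralized_dataset
    mu, beta = bandpass_rhythms(trials)
    return trials, mu, beta
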