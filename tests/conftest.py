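"""Shared fixtures: synthetic subjects generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from trunkmoment.study import prepare_subject
from trunkmoment.synthetic_data import generate_subject


@pytest.fixture(scope="session")
def noise_free_subject():
    """One subject with zero EMG and kinematic noise (exact-oracle world)."""
    return generate_subject(1, seed=101, emg_noise_sd=0.0, kin_noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_cache(noise_free_subject):
    return prepare_subject(noise_free_subject)


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject at the default noise levels."""
    return generate_subject(2, seed=202)


@pytest.fixture(scope="session")
def noisy_cache(noisy_subject):
    return prepare_subject(noisy_subject)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
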