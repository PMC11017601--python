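"""Shared fixtures: subjects, simulation profiles, small recordings."""

import dataclasses

import numpy as np
import pytest

import tugkit as tk

RATE = 100.0


@pytest.fixture
def subject():
    return tk.SubjectProfile(height=1.70, weight=75.0)


@pytest.fixture
def quiet_profile():
    """Healthy preset without sensor noise (deterministic signal checks)."""
    return dataclasses.replace(
        tk.healthy_profile(), noise_sd=0.0, gyro_noise_sd=0.0
    )


@pytest.fixture
def tone_profile(quiet_profile):
    """Noise-free preset with pure-sinusoid sway (closed-form checks)."""
    return dataclasses.replace(quiet_profile, pure_tone_sway=True)


@pytest.fixture
def static_recording():
    """4 s of a motionless device: gravity on the body CC axis."""
    n = 400
    t = np.arange(n) / RATE
    acc = np.zeros((n, 3))
    acc[:, 2] = -tk.signal_model.G
    return tk.IMURecording(
        timestamps=t, acc=acc, gyro=np.zeros((n, 3)),
        nominal_rate=RATE, mounting="identity",
    )


def make_recording(t, acc, gyro, mounting="identity", rate=RATE):
    return tk.IMURecording(
        timestamps=t, acc=acc, gyro=gyro, nominal_rate=rate, mounting=mounting
    )
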