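"""Shared fixtures: a default synthetic patient, a prompted training task,
and decoders trained on it.  Session-scoped because training sessions are
the most expensive objects the suite builds."""

from __future__ import annotations

import pytest

import tremorloop as tl


@pytest.fixture(scope="session")
def patient_cfg() -> tl.PatientConfig:
    return tl.PatientConfig()


@pytest.fixture(scope="session")
def quiet_cfg() -> tl.PatientConfig:
    """Noise-free patient: only the deterministic beta/tremor components."""
    return tl.PatientConfig(
        pink_noise_scale_uv=0.0,
        gyro_noise_scale_dps=0.0,
        emg_noise_scale_mv=0.0,
        accel_noise_scale_mps2=0.0,
        compass_noise_scale_au=0.0,
        movement_lowfreq_amp_dps=0.0,
        artifact_floor_gain_uv_per_v=0.0,
    )


@pytest.fixture(scope="session")
def train_sessions(patient_cfg):
    """Stim-off and stim-on prompted-task recordings of the same task."""
    sched = tl.make_prompt_schedule(120.0, 5, (8.0, 12.0), seed=11)
    off = tl.simulate_session(patient_cfg, sched, stim=None, seed=101)
    on = tl.simulate_session(
        patient_cfg, sched, stim=patient_cfg.therapeutic_voltage_v, seed=102
    )
    return off, on


@pytest.fixture(scope="session")
def classifier_pair(train_sessions):
    off, on = train_sessions
    return tl.train_distributed_pair(off, on)


@pytest.fixture(scope="session")
def embedded_clf(train_sessions):
    off, on = train_sessions
    return tl.train_embedded_from_sessions(off, on)


@pytest.fixture(scope="session")
def stim_params() -> tl.StimParameters:
    return tl.StimParameters()
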