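import numpy as np
import pytest

from tribogait import (ParticipantProfile, SensorGeometry, TengResponseParams,
                       aligned_trial_from_frames, simulate_trial)


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry.default()


@pytest.fixture(scope="session")
def params():
    return TengResponseParams()


def make_profile(pid="P000", age=30.0, sex="M", cadence=100.6, asym=0.0,
                 flatfoot="none", history="knee pain"):
    return ParticipantProfile(
        participant_id=pid, age=age, sex=sex, height_m=1.79, mass_kg=75.9,
        history_text=history, true_cadence=cadence, true_asymmetry_pct=asym,
        flatfoot=flatfoot, category_truth=frozenset({"knee"}))


@pytest.fixture(scope="session")
def profile_factory():
    return make_profile


def simulate_aligned(profile, geometry, params, duration_s=120.0, seed=0,
                     noise_scale=1.0, sample_rate=100.0):
    insole, imu, truth = simulate_trial(
        profile, geometry, params, duration_s=duration_s,
        sample_rate=sample_rate, seed=seed, noise_scale=noise_scale)
    return aligned_trial_from_frames(insole, imu, target_rate=sample_rate), truth


@pytest.fixture(scope="session")
def simulate_aligned_factory():
    return simulate_aligned


@pytest.fixture(scope="session")
def default_trial(geometry, params):
    """One default noisy 2MWT trial plus its ground truth (shared)."""
    return simulate_aligned(make_profile(), geometry, params, seed=11)
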