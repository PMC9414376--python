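import numpy as np
import pytest

from enosekit import (
    AromaProfile,
    SensorSpec,
    SimulationConfig,
    default_profiles,
    default_sensor_array,
    generate_dataset,
    simulate_measurement,
)


@pytest.fixture(scope="session")
def sensors():
    return default_sensor_array()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture
def quiet_sensor():
    """One noiseless, drift-free sensor for closed-form checks."""
    return SensorSpec(
        name="TGS2600",
        baseline_v=1.0,
        rise_tau_s=50.0,
        fall_tau_s=100.0,
        noise_sd_v=0.0,
        drift_v_per_s=0.0,
        humidity_coeff=0.5,
    )


@pytest.fixture
def short_config():
    """A scaled-down protocol (200 s, exposure 50-150 s) for fast tests."""
    return SimulationConfig(
        duration_s=200.0, exposure_start_s=50.0, exposure_end_s=150.0, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(sensors):
    """Two well-separated classes, 6 recordings each, scaled-down timing."""
    profiles = (
        AromaProfile(label="A", amplitudes_v=(1.0, 0.5, 0.8, 0.6, 1.2, 0.9, 1.1, 2.0)),
        AromaProfile(label="B", amplitudes_v=(0.4, 1.3, 0.5, 1.1, 0.7, 1.4, 0.6, 2.6)),
    )
    cfg = SimulationConfig(duration_s=200.0, exposure_start_s=50.0, exposure_end_s=150.0)
    return generate_dataset(profiles, 6, sensors, cfg, seed=11)
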