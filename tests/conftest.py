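import numpy as np
import pytest

from fiberflow import (
    ISOSBESTIC,
    SENSOR_465,
    SENSOR_565,
    PhotometryRecording,
    SimulationConfig,
)


@pytest.fixture
def small_recording() -> PhotometryRecording:
    """12 s dual-sensor recording at 100 Hz with known structure."""
    rng = np.random.default_rng(42)
    t = np.arange(1200) / 100.0
    iso = 0.6 + 0.01 * np.sin(2 * np.pi * 0.2 * t) + 0.001 * rng.standard_normal(t.size)
    return PhotometryRecording(
        time=t,
        channels={
            SENSOR_465: 1.0 + 0.02 * np.sin(2 * np.pi * 0.5 * t)
            + 0.002 * rng.standard_normal(t.size),
            SENSOR_565: 0.9 + 0.015 * np.cos(2 * np.pi * 0.3 * t)
            + 0.002 * rng.standard_normal(t.size),
            ISOSBESTIC: iso,
        },
        session_id="fixture",
    )


@pytest.fixture
def fast_sim_config() -> SimulationConfig:
    """Scaled-down simulation used where many replicates are needed."""
    return SimulationConfig(
        duration=60.0,
        trial_start=10.0,
        trial_end=60.0,
        sampling_rate=50.0,
        n_events=5,
        n_edge_events=0,
        event_duration_range=(0.5, 2.0),
        refractory=2.0,
        gap_fraction=0.0,
        seed=0,
    )
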