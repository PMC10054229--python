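import numpy as np
import pytest

from pbmwound.config import (
    CohortConfig,
    GroupKinetics,
    ReflectanceSceneConfig,
    ThermalSessionConfig,
)


@pytest.fixture
def noiseless_cohort_config():
    """Deterministic cohort: no measurement noise, no gaping transient."""
    return CohortConfig(
        noise_cv=0.0,
        gaping_amplitude=0.0,
        kinetics={
            g: GroupKinetics(100.0, 30.0, 0.10)
            for g in ("control", "red", "green", "blue")
        },
        seed=7,
    )


@pytest.fixture
def noiseless_thermal_config():
    return ThermalSessionConfig(noise_sd=0.0, core_sd=0.0, seed=7)


@pytest.fixture
def noiseless_scene_config():
    return ReflectanceSceneConfig(
        noise_sd=0.0,
        true_wound_reflectance={"red": 0.54, "green": 0.54, "blue": 0.54},
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
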