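import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from biogasdlm import PlantScenario, PlantSeries, generate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_series(
    solid, biogas, liquid=None, start="2018-01-01T00:00:00", digester_id="T"
) -> PlantSeries:
    """Build a PlantSeries from raw arrays on a fresh hourly grid."""
    solid = np.asarray(solid, dtype=float)
    return PlantSeries(
        timestamps=pd.date_range(start, periods=len(solid), freq="h"),
        solid_feed=solid,
        biogas=np.asarray(biogas, dtype=float),
        liquid_feed=None if liquid is None else np.asarray(liquid, dtype=float),
        digester_id=digester_id,
    )


@pytest.fixture(scope="session")
def noisy_year():
    """Default synthetic digester-year (noise 5 m³ h⁻¹) with ground truth."""
    return generate(PlantScenario(seed=20180101))


@pytest.fixture(scope="session")
def noiseless_short():
    """Short noise-free series: the exact-recovery oracle for the lag model."""
    return generate(PlantScenario(seed=7, duration=1500, noise_sd=0.0))
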