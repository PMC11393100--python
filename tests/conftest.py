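import numpy as np
import pandas as pd
import pytest

from doflux import SyntheticConfig, generate_site
from doflux.qc import WaterQualitySeries


@pytest.fixture(scope="session")
def short_site():
    """60-day default-config synthetic site (multiplicative heavy-tailed noise)."""
    return generate_site(SyntheticConfig(n_days=60, seed=3))


@pytest.fixture(scope="session")
def two_year_site():
    """Two calendar years of synthetic DO, for annual-peak spectral checks."""
    return generate_site(SyntheticConfig(n_days=731, seed=5, start="2020-01-01"))


def make_periodic_series(seed: int = 7, n_days: int = 60) -> WaterQualitySeries:
    """Tidal-shaped forecast fixture: half-day fundamental plus its first
    harmonic (tidal asymmetry) plus a diel (24 h) photosynthesis cycle and
    small Gaussian noise.  Exactly 96-step periodic apart from the noise."""
    n = 96 * n_days
    idx = pd.date_range("2021-01-01", periods=n, freq="15min")
    t = np.arange(n)
    rng = np.random.default_rng(seed)
    do = (
        9.0
        + 1.2 * np.cos(2 * np.pi * t / 48)
        + 0.5 * np.cos(4 * np.pi * t / 48 + 0.7)
        + 0.5 * np.cos(2 * np.pi * t / 96 + 1.0)
        + 0.05 * rng.standard_normal(n)
    )
    data = pd.DataFrame(
        {
            "do_mgl": do,
            "temp_c": 12.0,
            "cond_uscm": 500.0,
            "ph": 7.8,
            "ammonium_mgl": 0.1,
            "turbidity_ntu": 10.0,
            "rainfall_mm": 0.0,
        },
        index=idx.rename("timestamp"),
    )
    return WaterQualitySeries("FIX", data, dist_to_sea_km=10.0)


@pytest.fixture(scope="session")
def periodic_series():
    return make_periodic_series()
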