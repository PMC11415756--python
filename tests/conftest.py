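import numpy as np
import pytest

from coldstun_drift import (GridAxes, GriddedField, LandMask, ScenarioSpec,
                            make_tidal_channel, make_uniform)


@pytest.fixture(scope="session")
def short_spec():
    """A 12-day, daily-slice box used by most integration fixtures."""
    return ScenarioSpec(t_end=12 * 86400.0, dt_field=86400.0)


@pytest.fixture(scope="session")
def uniform_fieldset(short_spec):
    return make_uniform(short_spec, 0.1, 0.0)


@pytest.fixture(scope="session")
def channel_fieldset():
    spec = ScenarioSpec(t_end=12 * 86400.0, dt_field=3600.0, coast="channel",
                        mean_u=0.1, tidal_amp=0.3)
    return make_tidal_channel(spec)


@pytest.fixture
def unit_cell_field():
    """One cell, corner values (0, 1, 2, 3) row-major (lat, lon), two time
    slices offset by +10."""
    axes = GridAxes([0.0, 1.0], [0.0, 1.0], [0.0, 1.0])
    base = np.array([[0.0, 1.0], [2.0, 3.0]])
    data = np.stack([base, base + 10.0])
    return GriddedField(axes, data=data, units="degC")


@pytest.fixture
def east_coast_mask():
    """Straight north-south coast: land in the two easternmost columns."""
    axes = GridAxes(0.1 * np.arange(6), 50.0 + 0.1 * np.arange(6))
    is_land = np.zeros((axes.nlat, axes.nlon), dtype=bool)
    is_land[:, -2:] = True
    return LandMask(axes, is_land)
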