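import numpy as np
import pytest

from voyage_eb.config import RunConfig
from voyage_eb.synthetic_env import EnvFieldSet, GridSpec


def make_uniform_fieldset(ta_c=25.0, wind=(0.0, 0.0), solar=0.0, cur=(0.0, 0.0),
                          lat=(-45.0, 25.0), lon=(170.0, 235.0), resolution=5.0,
                          days=60.0, atmos_step=6.0, sat_lat_gradient=0.0):
    """Hand-built fieldset with spatially uniform (optionally lat-linear SAT) fields."""
    grid = GridSpec(lat_min=lat[0], lat_max=lat[1], lon_min=lon[0], lon_max=lon[1],
                    resolution=resolution, time_start=0.0, time_end=days * 24.0,
                    atmos_step=atmos_step, ocean_step=24.0)
    lats, lons = grid.lats, grid.lons
    na, no = grid.atmos_times.size, grid.ocean_times.size
    shape_a = (na, lats.size, lons.size)
    shape_o = (no, lats.size, lons.size)
    sat = np.full(shape_a, ta_c, dtype=np.float32)
    if sat_lat_gradient:
        sat += (sat_lat_gradient * lats)[None, :, None].astype(np.float32)
    return EnvFieldSet(
        grid=grid, lats=lats, lons=lons,
        t_atmos=grid.atmos_times, t_ocean=grid.ocean_times,
        sat=sat,
        wind_u=np.full(shape_a, wind[0], dtype=np.float32),
        wind_v=np.full(shape_a, wind[1], dtype=np.float32),
        solar=np.full(shape_a, solar, dtype=np.float32),
        cur_u=np.full(shape_o, cur[0], dtype=np.float32),
        cur_v=np.full(shape_o, cur[1], dtype=np.float32),
    )


@pytest.fixture
def uniform_fieldset():
    return make_uniform_fieldset()


@pytest.fixture(scope="session")
def demo_result():
    """One full demo-profile analysis shared by the structural acceptance tests."""
    from voyage_eb.pipeline import run_analysis

    return run_analysis(RunConfig.for_profile("demo", seed=1))
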