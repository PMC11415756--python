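"""Composite leeway velocity, RK4 stepping, anti-beaching, and the runner."""

from dataclasses import replace

import numpy as np
import pytest

from coldstun_drift import (ConfigurationError, GridAxes, GriddedField,
                            LandMask, FieldSet, ScenarioSpec,
                            SimulationConfig, Stranding, TrajectoryEnsemble,
                            anti_beach, composite_velocity, make_uniform,
                            release_positions, run_backtrack)
from coldstun_drift.coldstun_events import haversine_km
from coldstun_drift.grid_fields import EARTH_RADIUS_M


def _const_fieldset(uc, us, uw, spec=None):
    """Uniform fieldset with distinct currents/stokes/wind vectors."""
    spec = spec or ScenarioSpec(t_end=12 * 86400.0, dt_field=86400.0)
    fs = make_uniform(spec, *uc)
    ax = fs.stokes.axes
    shape = (ax.ntime, ax.nlat, ax.nlon)

    def vec(u, v):
        return GriddedField(ax, u=np.full(shape, float(u)),
                            v=np.full(shape, float(v)), units="m s-1")

    return FieldSet(currents=fs.currents, stokes=vec(*us), wind10m=vec(*uw),
                    sst=fs.sst, mask=fs.mask)


class TestConfig:
    def test_output_interval_must_be_multiple_of_dt(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(dt=700.0, output_interval=86400.0)

    def test_windage_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(windage=0.2)

    def test_defaults_are_production_settings(self):
        cfg = SimulationConfig()
        assert (cfg.n_particles, cfg.dt, cfg.duration_days) == (10_000, 600.0, 120.0)
        assert cfg.output_interval == 86400.0
        assert cfg.thresholds == (10.0, 12.0, 14.0)


class TestCompositeVelocity:
    def test_direct_sum_with_one_percent_windage(self):
        fs = _const_fieldset((0.1, 0.0), (0.05, 0.0), (10.0, 0.0))
        u, v = composite_velocity(fs, 0.01, 4.0, 52.0, 86400.0)
        assert u == pytest.approx(0.25)
        assert v == 0.0

    def test_zero_windage_is_currents_plus_stokes(self):
        fs = _const_fieldset((0.1, 0.02), (0.05, 0.01), (10.0, -5.0))
        u, v = composite_velocity(fs, 0.0, 4.0, 52.0, 86400.0)
        assert (u, v) == (pytest.approx(0.15), pytest.approx(0.03))

    def test_windage_scales_wind_vector(self):
        fs = _const_fieldset((0.0, 0.0), (0.0, 0.0), (0.0, -10.0))
        u, v = composite_velocity(fs, 0.03, 4.0, 52.0, 86400.0)
        assert (u, v) == (0.0, pytest.approx(-0.3))


class TestAntiBeach:
    def test_displacement_is_600_m_for_600_s_step(self, east_coast_mask):
        # land cell (3, 4) on a straight north-south coast: push due west
        lon0, lat0 = 0.4, 50.3
        lon1, lat1, no_norm = anti_beach(lon0, lat0, east_coast_mask, 600.0)
        assert not no_norm
        assert lat1 == lat0
        assert lon1 < lon0
        dist_m = haversine_km(lon0, lat0, lon1, lat1) * 1000.0
        assert dist_m == pytest.approx(600.0, abs=1e-3)

    def test_push_direction_follows_shoreline_normal(self, east_coast_mask):
        lon1, lat1, _ = anti_beach(0.4, 50.2, east_coast_mask, 600.0)
        assert lat1 == 50.2  # due west, no meridional component

    def test_landlocked_pocket_flags_no_normal(self):
        axes = GridAxes(0.1 * np.arange(5), 50.0 + 0.1 * np.arange(5))
        is_land = np.ones((5, 5), dtype=bool)
        is_land[0, 0] = False
        mask = LandMask(axes, is_land)
        lon1, lat1, no_norm = anti_beach(0.3, 50.3, mask, 600.0)
        assert no_norm
        assert (lon1, lat1) == (0.3, 50.3)  # unmoved; caller beaches it


class TestReleasePositions:
    def test_all_positions_inside_one_ocean_cell(self, east_coast_mask):
        st = Stranding("s", 0.42, 50.31, 0.0)  # on land; nearest ocean col 3
        lon, lat = release_positions(st, east_coast_mask, 500, seed=1)
        i, j = east_coast_mask.cell_of(lon, lat)
        assert np.all(i == 3) and np.all(j == 3)
        assert not east_coast_mask.is_land[3, 3]

    def test_same_seed_reproduces_positions(self, east_coast_mask):
        st = Stranding("s", 0.42, 50.31, 0.0)
        a = release_positions(st, east_coast_mask, 100, seed=7)
        b = release_positions(st, east_coast_mask, 100, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_ocean_stranding_cell_is_chosen(self, east_coast_mask):
        st = Stranding("s", 0.11, 50.11, 0.0)  # already in ocean cell (1, 1)
        lon, lat = release_positions(st, east_coast_mask, 50, seed=3)
        i, j = east_coast_mask.cell_of(lon, lat)
        assert np.all(i == 1) and np.all(j == 1)

    def test_edge_adjacent_mode_picks_neighbouring_ocean_cell(
            self, east_coast_mask):
        st = Stranding("s", 0.42, 50.31, 0.0)
        lon, lat = release_positions(st, east_coast_mask, 50, seed=3,
                                     mode="edge-adjacent")
        i, j = east_coast_mask.cell_of(lon, lat)
        assert np.all(i == 3) and np.all(j == 3)

    def test_no_reachable_water_raises(self):
        axes = GridAxes(0.1 * np.arange(5), 50.0 + 0.1 * np.arange(5))
        is_land = np.ones((5, 5), dtype=bool)
        is_land[0, 0] = False
        mask = LandMask(axes, is_land)
        st = Stranding("s", 0.3, 50.3, 0.0)
        with pytest.raises(ConfigurationError):
            release_positions(st, mask, 10, seed=1, mode="edge-adjacent")


class TestRunBacktrack:
    def test_record_count_and_status_monotonicity(self, channel_fieldset):
        st = Stranding("c", 4.0, 52.5, 10 * 86400.0)
        cfg = SimulationConfig(n_particles=40, duration_days=5.0, seed=8)
        ens = run_backtrack(channel_fieldset, st, cfg)
        status = ens.ds["status"].values
        assert status.shape[1] == 6  # 1 + duration/output_interval
        for p in range(ens.n_particles):
            recorded = np.flatnonzero(status[p] >= 0)
            # records form a prefix: none after a particle stops drifting
            assert np.array_equal(recorded, np.arange(recorded.size))

    def test_sst_records_equal_independent_reinterpolation(
            self, channel_fieldset):
        st = Stranding("c", 4.0, 52.5, 10 * 86400.0)
        cfg = SimulationConfig(n_particles=25, duration_days=4.0, seed=8)
        ens = run_backtrack(channel_fieldset, st, cfg)
        for r, t in enumerate(ens.ds["time"].values):
            ok = np.isfinite(ens.sst[:, r])
            again = channel_fieldset.sst.interp(
                ens.lon[ok, r], ens.lat[ok, r], t,
                out_of_range="nan", masked="nan")
            assert np.array_equal(ens.sst[ok, r], again)

    def test_identical_seed_gives_bit_identical_ensembles(
            self, channel_fieldset):
        st = Stranding("c", 4.5, 52.0, 10 * 86400.0)
        cfg = SimulationConfig(n_particles=30, duration_days=3.0, seed=12)
        e1 = run_backtrack(channel_fieldset, st, cfg)
        e2 = run_backtrack(channel_fieldset, st, cfg)
        for v in ("lon", "lat", "sst"):
            assert np.array_equal(e1.ds[v].values, e2.ds[v].values,
                                  equal_nan=True)

    def test_windage_merged_field_trajectories_bit_match(self):
        alpha = 0.02
        uc, us, uw = (0.1, 0.03), (0.02, 0.01), (6.0, -3.0)
        fs_a = _const_fieldset(uc, us, uw)
        merged = (uc[0] + alpha * uw[0], uc[1] + alpha * uw[1])
        fs_b = _const_fieldset(merged, us, (0.0, 0.0))
        st = Stranding("w", 4.0, 52.0, 10 * 86400.0)
        cfg_a = SimulationConfig(n_particles=50, duration_days=3.0, seed=13,
                                 windage=alpha)
        cfg_b = replace(cfg_a, windage=0.0)
        e_a = run_backtrack(fs_a, st, cfg_a)
        e_b = run_backtrack(fs_b, st, cfg_b)
        assert np.array_equal(e_a.lon, e_b.lon)
        assert np.array_equal(e_a.lat, e_b.lat)

    def test_domain_exit_marks_beached_and_accounting_sums_to_n(self):
        spec = ScenarioSpec(t_end=12 * 86400.0, dt_field=86400.0)
        fs = make_uniform(spec, 0.5, 0.0)  # fast flow exits the box westward
        st = Stranding("x", 2.3, 52.0, 10 * 86400.0)
        cfg = SimulationConfig(n_particles=30, duration_days=8.0, seed=14)
        ens = run_backtrack(fs, st, cfg)
        assert ens.beached_fraction() == 1.0
        reasons = ens.ds["beach_reason"].values
        assert np.all(reasons == 3)  # domain_exit
        assert ens.n_particles == 30

    def test_dead_end_bay_beaches_all(self):
        # a one-cell-wide inlet surrounded by land: pushed particles cannot
        # reach water and run out of patience
        axes = GridAxes(0.1 * np.arange(7), 50.0 + 0.1 * np.arange(7))
        nlat, nlon = axes.nlat, axes.nlon
        is_land = np.ones((nlat, nlon), dtype=bool)
        is_land[3, 3] = False  # the bay
        mask = LandMask(axes, is_land)
        time = np.array([0.0, 20 * 86400.0])
        ax_t = GridAxes(axes.lon, axes.lat, time)
        shape = (2, nlat, nlon)

        def vec(u, v):
            return GriddedField(ax_t, u=np.full(shape, u), v=np.full(shape, v),
                                units="m s-1")

        # 2 m/s backward drift moves 1200 m/step westward into land, more
        # than the 600 m push can undo: patience runs out and all beach
        fs = FieldSet(currents=vec(2.0, 0.0), stokes=vec(0.0, 0.0),
                      wind10m=vec(0.0, 0.0),
                      sst=GriddedField(ax_t, data=np.full(shape, 12.0),
                                       units="degC"),
                      mask=mask)
        st = Stranding("bay", 0.33, 50.33, 10 * 86400.0)
        cfg = SimulationConfig(n_particles=20, duration_days=2.0, seed=15)
        ens = run_backtrack(fs, st, cfg)
        assert ens.beached_fraction() == 1.0

    def test_netcdf_roundtrip_preserves_records_and_metadata(
            self, channel_fieldset, tmp_path):
        st = Stranding("c", 4.0, 52.5, 10 * 86400.0)
        cfg = SimulationConfig(n_particles=15, duration_days=3.0, seed=16,
                               windage=0.01)
        ens = run_backtrack(channel_fieldset, st, cfg)
        p = tmp_path / "traj.nc"
        ens.to_netcdf(p)
        back = TrajectoryEnsemble.from_netcdf(p)
        assert np.array_equal(ens.lon, back.lon, equal_nan=True)
        assert np.array_equal(ens.sst, back.sst, equal_nan=True)
        assert back.config == cfg
        assert back.stranding == st
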