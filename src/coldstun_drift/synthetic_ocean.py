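"""Seeded synthetic forcing scenarios with closed-form oracles.

Real runs of this pipeline are driven by reanalysis surface currents, Stokes
drift, 10 m wind and SST for the European North West Shelf.  Those archives
are large and external, so every downstream stage is developed and tested
against the analytic scenarios generated here:

* uniform flow (constant-velocity closed form),
* solid-body rotation (circular-orbit oracle for integrator order checks),
* a tidal channel: mean flow plus an M2-period sinusoidal oscillation
  between two coasts, emulating the tidally dominated southern North Sea,
* a linear cooling SST front whose threshold-crossing time is exactly
  computable, emulating the winter coastal cooling that drives cold
  stunning of juvenile sea turtles,
* the five Dutch Kemp's ridley stranding records used as release fixtures.

All generators are deterministic given a :class:`ScenarioSpec`; two calls
produce bit-identical fields.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid_fields import (EARTH_RADIUS_M, FieldSet, GridAxes, GriddedField,
                          LandMask)

__all__ = [
    "M2_PERIOD_S",
    "ScenarioSpec",
    "make_uniform",
    "make_solid_body_rotation",
    "solid_body_position",
    "make_tidal_channel",
    "make_sst_front",
    "sst_front_crossing_day",
    "make_stranding_fixture",
]

#: Principal lunar semi-diurnal tidal period (seconds).  Shelf-sea currents
#: "include the effect of tides" without a named constituent; M2 dominates
#: the southern North Sea so it is the default oscillation.
M2_PERIOD_S = 44_712.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic forcing scenario.

    The defaults describe a winter southern-North-Sea-like box: a weak
    north-eastward mean drift with a strong M2 tidal oscillation,
    south-westerly wind and Stokes drift, and an SST field that starts at
    14 degC offshore and cools through the 10-14 degC cold-stunning band
    over the 120-day window (0.05 degC/day -> a 6 degC drop, bottoming out
    near the ~8 degC winter minimum of the region).
    """

    lon_min: float = 2.0
    lon_max: float = 6.0
    lat_min: float = 50.5
    lat_max: float = 54.0
    dlon: float = 0.1
    dlat: float = 0.1
    t_start: float = 0.0
    t_end: float = 120 * 86400.0
    dt_field: float = 3600.0          # hourly slices resolve the M2 tide
    mean_u: float = 0.1               # m/s, along-channel / eastward
    mean_v: float = 0.0
    tidal_amp: float = 0.5            # m/s
    tidal_period: float = M2_PERIOD_S
    stokes_u: float = 0.02            # m/s, spatially uniform by default so
    stokes_v: float = 0.01            # windage-linearity is isolated
    wind_u: float = 8.0               # m/s at 10 m
    wind_v: float = 4.0
    sst_offshore: float = 14.0        # degC at the coast reference x_coast
    sst_gradient: float = 0.5         # degC per degree of cross-shore lon
    cooling_rate: float = 0.05        # degC per day
    coast: str = "none"               # none | half-plane | channel
    coast_lon: float = 5.5            # land at lon >= coast_lon (half-plane)
    channel_lat: tuple = (51.5, 53.5)  # ocean band (channel coastline)
    seed: int = 0

    def __post_init__(self):
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValueError("grid spacing must be positive")
        if self.dt_field <= 0:
            raise ValueError("field time step must be positive")
        for p in (self.sst_offshore, self.sst_gradient, self.cooling_rate):
            if not np.isfinite(p):
                raise ValueError("SST parameters must be finite")
        if self.coast not in ("none", "half-plane", "channel"):
            raise ValueError(f"unknown coastline tag {self.coast!r}")


def _axes(spec: ScenarioSpec, with_time=True) -> GridAxes:
    lon = np.arange(spec.lon_min, spec.lon_max + 0.5 * spec.dlon, spec.dlon)
    lat = np.arange(spec.lat_min, spec.lat_max + 0.5 * spec.dlat, spec.dlat)
    time = None
    if with_time:
        time = np.arange(spec.t_start, spec.t_end + 0.5 * spec.dt_field,
                         spec.dt_field)
    return GridAxes(lon, lat, time)


def _mask(spec: ScenarioSpec) -> LandMask:
    ax = _axes(spec, with_time=False)
    is_land = np.zeros((ax.nlat, ax.nlon), dtype=bool)
    if spec.coast == "half-plane":
        is_land[:, ax.lon >= spec.coast_lon] = True
    elif spec.coast == "channel":
        lo, hi = spec.channel_lat
        is_land[(ax.lat < lo) | (ax.lat > hi), :] = True
    return LandMask(ax, is_land)


def _const_vector(ax: GridAxes, u0: float, v0: float, name: str) -> GriddedField:
    shape = (ax.ntime, ax.nlat, ax.nlon)
    return GriddedField(ax, u=np.full(shape, float(u0)),
                        v=np.full(shape, float(v0)), units="m s-1", name=name)


def make_uniform(spec: ScenarioSpec, u0: float, v0: float) -> FieldSet:
    """Constant currents (u0, v0) everywhere and everywhen; zero Stokes and
    wind; constant SST; no land.  The constant-velocity closed form
    ``displacement = v * t`` is the oracle for the integrator."""
    ax = _axes(spec)
    shape = (ax.ntime, ax.nlat, ax.nlon)
    return FieldSet(
        currents=_const_vector(ax, u0, v0, "currents"),
        stokes=_const_vector(ax, 0.0, 0.0, "stokes"),
        wind10m=_const_vector(ax, 0.0, 0.0, "wind10m"),
        sst=GriddedField(ax, data=np.full(shape, spec.sst_offshore),
                         units="degC", name="sst"),
        mask=_mask(replace(spec, coast="none")),
    )


def make_solid_body_rotation(spec: ScenarioSpec, omega: float,
                             center: tuple) -> FieldSet:
    """Static rotating flow: v = omega x r about ``center`` in a local
    planar metric with the cos(lat) factor frozen at the centre latitude.

    Trajectories of the exact flow are circles of period 2*pi/omega; the
    oracle is :func:`solid_body_position`.  Integrate with the planar
    metric referenced at ``center[1]`` so integrator and oracle share one
    geometry (the field is then bilinear, hence interpolated exactly).
    """
    if omega == 0:
        raise ValueError("omega must be nonzero")
    lon_c, lat_c = center
    ax = _axes(spec, with_time=False)
    static = GridAxes(ax.lon, ax.lat, np.array([spec.t_start]))
    deg2rad = np.pi / 180.0
    cosc = np.cos(lat_c * deg2rad)
    x = EARTH_RADIUS_M * cosc * (ax.lon - lon_c) * deg2rad   # metres east
    y = EARTH_RADIUS_M * (ax.lat - lat_c) * deg2rad          # metres north
    xx, yy = np.meshgrid(x, y)
    u = (-omega * yy)[np.newaxis]
    v = (omega * xx)[np.newaxis]
    shape = (1, ax.nlat, ax.nlon)
    zeros = np.zeros(shape)
    return FieldSet(
        currents=GriddedField(static, u=u, v=v, units="m s-1", name="currents"),
        stokes=GriddedField(static, u=zeros, v=zeros.copy(), units="m s-1",
                            name="stokes"),
        wind10m=GriddedField(static, u=zeros.copy(), v=zeros.copy(),
                             units="m s-1", name="wind10m"),
        sst=GriddedField(static, data=np.full(shape, spec.sst_offshore),
                         units="degC", name="sst"),
        mask=_mask(replace(spec, coast="none")),
    )


def solid_body_position(lon0, lat0, omega, center, t_elapsed):
    """Analytic position after rotating for ``t_elapsed`` seconds (may be
    negative for backward integration) in the planar metric of
    :func:`make_solid_body_rotation`."""
    lon_c, lat_c = center
    deg2rad = np.pi / 180.0
    cosc = np.cos(lat_c * deg2rad)
    x = EARTH_RADIUS_M * cosc * (np.asarray(lon0) - lon_c) * deg2rad
    y = EARTH_RADIUS_M * (np.asarray(lat0) - lat_c) * deg2rad
    ang = omega * t_elapsed
    xr = x * np.cos(ang) - y * np.sin(ang)
    yr = x * np.sin(ang) + y * np.cos(ang)
    return (lon_c + xr / (EARTH_RADIUS_M * cosc) / deg2rad,
            lat_c + yr / EARTH_RADIUS_M / deg2rad)


def make_shelf_sea(spec: ScenarioSpec) -> FieldSet:
    """Mean flow plus a sinusoidal tidal oscillation, with the coastline
    geometry taken from ``spec.coast``.

    ``u(t) = mean_u + tidal_amp * sin(2 pi t / tidal_period)``, v = mean_v;
    SST from :func:`make_sst_front`; constant wind and Stokes drift.  With
    zero mean flow the net displacement over an integer number of tidal
    periods is ~zero (bounded by the time-interpolation and integration
    error).
    """
    ax = _axes(spec)
    tide = spec.tidal_amp * np.sin(2 * np.pi * (ax.time - spec.t_start)
                                   / spec.tidal_period)
    u = np.broadcast_to((spec.mean_u + tide)[:, None, None],
                        (ax.ntime, ax.nlat, ax.nlon)).copy()
    v = np.full((ax.ntime, ax.nlat, ax.nlon), float(spec.mean_v))
    return FieldSet(
        currents=GriddedField(ax, u=u, v=v, units="m s-1", name="currents"),
        stokes=_const_vector(ax, spec.stokes_u, spec.stokes_v, "stokes"),
        wind10m=_const_vector(ax, spec.wind_u, spec.wind_v, "wind10m"),
        sst=make_sst_front(spec),
        mask=_mask(spec),
    )


def make_tidal_channel(spec: ScenarioSpec) -> FieldSet:
    """:func:`make_shelf_sea` with a channel coastline (land above and
    below the ``channel_lat`` band)."""
    return make_shelf_sea(replace(spec, coast="channel"))


def make_sst_front(spec: ScenarioSpec) -> GriddedField:
    """Linearly cooling SST with a cross-shore gradient.

    ``SST(lon, t) = sst_offshore + g * (lon - coast_lon) - c * t_days``
    with g in degC per degree longitude and c = ``cooling_rate`` in degC
    per day.  For a stationary particle at lon = x_p the field drops below
    a threshold T_c exactly ``(sst_offshore + g*(x_p - coast_lon) - T_c)/c``
    days after ``t_start`` (:func:`sst_front_crossing_day`), which is the
    oracle for the cold-stun event detector.
    """
    if spec.cooling_rate < 0:
        raise ValueError("cooling rate must be >= 0")
    ax = _axes(spec)
    t_days = (ax.time - spec.t_start) / 86400.0
    cross_shore = spec.sst_offshore + spec.sst_gradient * (ax.lon - spec.coast_lon)
    data = (cross_shore[None, None, :]
            - spec.cooling_rate * t_days[:, None, None])
    data = np.broadcast_to(data, (ax.ntime, ax.nlat, ax.nlon)).copy()
    return GriddedField(ax, data=data, units="degC", name="sst")


def sst_front_crossing_day(spec: ScenarioSpec, x_p: float, t_c: float):
    """Closed-form day (since ``t_start``) when the front at lon ``x_p``
    drops below ``t_c``; None if it never does (zero cooling and field
    already at/above threshold)."""
    start = spec.sst_offshore + spec.sst_gradient * (x_p - spec.coast_lon)
    if spec.cooling_rate == 0:
        return None if start >= t_c else 0.0
    return (start - t_c) / spec.cooling_rate


def make_stranding_fixture() -> pd.DataFrame:
    """The five recorded Dutch strandings of juvenile Kemp's ridley turtles
    (2007-2021), as a DataFrame with columns location, latitude, longitude,
    date (datetime64)."""
    with importlib.resources.files("coldstun_drift.data").joinpath(
            "strandings.csv").open("r") as fh:
        df = pd.read_csv(fh, parse_dates=["date"])
    return df
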