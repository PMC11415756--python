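"""Backward-in-time ensemble particle integrator with leeway drift.

Cold-stunned turtles float passively, so they are modelled as virtual
particles advected by a composite surface velocity

    v = v_currents + alpha * v_wind10m + v_stokes,

where ``alpha`` is the windage factor (the fraction of the 10 m wind felt
by the floating body; sensitivity settings 0, 0.1, 1, 2 and 3 %).  An
ensemble is released in the coastal grid cell adjacent to a stranding site
and integrated backward from the stranding date with classical RK4 at a
10-minute step for 120 days, recording position and interpolated SST daily.

Particles that enter a land cell are pushed back toward water at 1 m/s
perpendicular to the shoreline (600 m per 10-minute step); particles that
cannot be freed (convoluted coastline, islands) or that exit the regional
domain are marked beached and drop out of the integration.  Advection is
purely deterministic (no diffusion term): ensemble spread comes only from
the uniform release scatter within the release cell.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError
from .grid_fields import EARTH_RADIUS_M, FieldSet, LandMask

__all__ = [
    "PUSH_SPEED_MS",
    "BEACH_REASONS",
    "SimulationConfig",
    "Stranding",
    "composite_velocity",
    "rk4_step",
    "anti_beach",
    "release_positions",
    "run_backtrack",
    "TrajectoryEnsemble",
]

_DEG = 180.0 / np.pi
_RAD = np.pi / 180.0

#: Anti-beaching push speed (m/s); 1 m/s for a 600 s step gives the 600 m
#: shoreline-normal displacement of the unbeaching rule.
PUSH_SPEED_MS = 1.0

#: Terminal status codes per particle.
BEACH_REASONS = {0: "drifting", 1: "stuck", 2: "no_normal", 3: "domain_exit"}


@dataclass(frozen=True)
class SimulationConfig:
    """All run parameters of one backtracking ensemble.

    Defaults are the production settings: 10,000 particles, 10-minute RK4
    step, 120-day backward window, daily output, thresholds 10/12/14 degC.
    ``windage`` is dimensionless (0.01 = 1 % of the 10 m wind).
    ``beach_patience`` is the number of consecutive failed shoreline pushes
    before a particle is declared beached.  ``metric`` selects the m/s to
    degrees conversion: "spherical" (cos(lat) at each RK4 stage latitude,
    the default) or "plane" (frozen at ``ref_lat``; used with the
    solid-body-rotation oracle).
    """

    n_particles: int = 10_000
    dt: float = 600.0
    duration_days: float = 120.0
    windage: float = 0.0
    output_interval: float = 86_400.0
    thresholds: tuple = (10.0, 12.0, 14.0)
    seed: int = 0
    beach_patience: int = 3
    release_mode: str = "nearest"     # nearest | edge-adjacent
    metric: str = "spherical"
    ref_lat: float | None = None

    def __post_init__(self):
        if self.dt <= 0 or self.duration_days <= 0:
            raise ConfigurationError("dt and duration must be positive")
        if not 0.0 <= self.windage <= 0.05:
            raise ConfigurationError("windage factor outside [0, 0.05]")
        ratio = self.output_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ConfigurationError(
                "output_interval must be an integer multiple of dt")
        if self.n_particles < 1:
            raise ConfigurationError("need at least one particle")
        if self.metric not in ("spherical", "plane"):
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.metric == "plane" and self.ref_lat is None:
            raise ConfigurationError("plane metric needs ref_lat")


@dataclass(frozen=True)
class Stranding:
    """A stranding record: site name, position, and time t0 (seconds on the
    field time axis).  Reported dates carry no clock time; t0 is 00:00 UTC
    on the reported date when built from a calendar date."""

    name: str
    lon: float
    lat: float
    t0: float

    @classmethod
    def from_date(cls, name, lon, lat, date) -> "Stranding":
        t0 = pd.Timestamp(date).timestamp()
        return cls(name=name, lon=float(lon), lat=float(lat), t0=float(t0))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def composite_velocity(fieldset: FieldSet, alpha: float, lon, lat, t, *,
                       out_of_range="raise", masked="raise"):
    """Leeway velocity (u, v) in m/s at point(s) and time t.

    Componentwise ``(currents + alpha * wind10m) + stokes``, each term
    interpolated on its own grid; no directional rotation is applied (the
    windage formulation is a pure scalar fraction of the wind vector).
    """
    uc, vc = fieldset.currents.interp(lon, lat, t, out_of_range=out_of_range,
                                      masked=masked)
    uw, vw = fieldset.wind10m.interp(lon, lat, t, out_of_range=out_of_range,
                                     masked=masked)
    us, vs = fieldset.stokes.interp(lon, lat, t, out_of_range=out_of_range,
                                    masked=masked)
    return (uc + alpha * uw) + us, (vc + alpha * vw) + vs


def _ms_to_degs(u, v, lat, metric, ref_lat):
    """Convert (m/s, m/s) to (deg lon/s, deg lat/s) in the local metric."""
    if metric == "plane":
        cphi = np.cos(ref_lat * _RAD)
    else:
        cphi = np.cos(np.asarray(lat) * _RAD)
    return u * _DEG / (EARTH_RADIUS_M * cphi), v * _DEG / EARTH_RADIUS_M


def rk4_step(lon, lat, t, dt_signed, velocity_fn, *, metric="spherical",
             ref_lat=None):
    """One classical RK4 step of (lon, lat); dt_signed < 0 backtracks.

    ``velocity_fn(lon, lat, t) -> (u, v)`` in m/s; the conversion to
    degrees uses the Earth radius and the stage-point latitude (or the
    fixed ``ref_lat`` in plane metric).  Backward time is realised by the
    negative step, not by negating fields, so stage-time evaluation stays
    correct for time-varying forcing.  Vectorised over particle arrays.
    """

    def rhs(lo, la, tt):
        u, v = velocity_fn(lo, la, tt)
        return _ms_to_degs(u, v, la, metric, ref_lat)

    h = dt_signed
    k1x, k1y = rhs(lon, lat, t)
    k2x, k2y = rhs(lon + 0.5 * h * k1x, lat + 0.5 * h * k1y, t + 0.5 * h)
    k3x, k3y = rhs(lon + 0.5 * h * k2x, lat + 0.5 * h * k2y, t + 0.5 * h)
    k4x, k4y = rhs(lon + h * k3x, lat + h * k3y, t + h)
    new_lon = lon + h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_lat = lat + h / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    return new_lon, new_lat


def anti_beach(lon, lat, mask: LandMask, dt: float):
    """Push particle(s) sitting in a land cell 600 m toward water.

    The displacement is ``PUSH_SPEED_MS * dt`` metres along the shoreline
    normal of the occupied land cell.  Returns (new_lon, new_lat,
    no_normal) where ``no_normal`` flags cells whose 3x3 neighbourhood is
    landlocked (the caller marks those particles beached).  Positions with
    no usable normal are returned unchanged.
    """
    lon_q = np.atleast_1d(np.asarray(lon, dtype=np.float64))
    lat_q = np.atleast_1d(np.asarray(lat, dtype=np.float64))
    scalar_in = np.asarray(lon).ndim == 0
    i, j = mask.cell_of(lon_q, lat_q)
    i, j = np.atleast_1d(i), np.atleast_1d(j)
    nx, ny, ok = mask.normal_grid()
    good = ok[i, j]
    dist = PUSH_SPEED_MS * dt
    dlon = dist * nx[i, j] * _DEG / (EARTH_RADIUS_M * np.cos(lat_q * _RAD))
    dlat = dist * ny[i, j] * _DEG / EARTH_RADIUS_M
    new_lon = np.where(good, lon_q + dlon, lon_q)
    new_lat = np.where(good, lat_q + dlat, lat_q)
    if scalar_in:
        return float(new_lon[0]), float(new_lat[0]), bool(~good[0])
    return new_lon, new_lat, ~good


# ---------------------------------------------------------------------------
# release
# ---------------------------------------------------------------------------

def release_positions(stranding: Stranding, mask: LandMask, n: int, seed: int,
                      mode: str = "nearest"):
    """n release positions scattered uniformly in the coastal cell adjacent
    to the stranding site.

    ``mode="nearest"`` picks the ocean cell whose centre is closest (great
    circle) to the stranding coordinates, ties by lower flat index;
    ``mode="edge-adjacent"`` restricts the choice to ocean cells sharing an
    edge with the cell containing the stranding point (that cell itself if
    it is ocean).  Deterministic given (stranding, mask, n, seed).
    """
    from .coldstun_events import haversine_km

    ocean = ~mask.is_land
    if mode == "edge-adjacent":
        i0, j0 = mask.cell_of(stranding.lon, stranding.lat)
        cand = np.zeros_like(ocean)
        if ocean[i0, j0]:
            cand[i0, j0] = True
        else:
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i0 + di, j0 + dj
                if 0 <= ii < ocean.shape[0] and 0 <= jj < ocean.shape[1]:
                    cand[ii, jj] = ocean[ii, jj]
        ocean = cand
    if not ocean.any():
        raise ConfigurationError(
            f"no ocean cell available for release near {stranding.name!r}")
    ii, jj = np.nonzero(ocean)
    d = haversine_km(mask.axes.lon[jj], mask.axes.lat[ii],
                     stranding.lon, stranding.lat)
    k = int(np.argmin(d))        # ties resolve to the lower flat index
    i, j = int(ii[k]), int(jj[k])
    rng = np.random.default_rng(seed)
    lon = rng.uniform(mask.lon_edges[j], mask.lon_edges[j + 1], size=n)
    lat = rng.uniform(mask.lat_edges[i], mask.lat_edges[i + 1], size=n)
    return lon, lat


# ---------------------------------------------------------------------------
# ensemble runner
# ---------------------------------------------------------------------------

class TrajectoryEnsemble:
    """Daily records of a backtracked particle ensemble.

    Wraps an :class:`xarray.Dataset` with dimensions (particle, record):
    ``lon``, ``lat``, ``sst`` and per-record ``status`` (0 drifting,
    -1 missing, i.e. after beaching), per-particle terminal ``beached``
    flag, ``beach_reason`` and ``beach_time``, and the coordinate
    ``days_before`` (record index in days before stranding).  Metadata
    (stranding, config) travel in attrs and survive NetCDF round-trips.
    """

    def __init__(self, ds: xr.Dataset, stranding: Stranding,
                 config: SimulationConfig):
        self.ds = ds
        self.stranding = stranding
        self.config = config

    # -- accessors -----------------------------------------------------------

    @property
    def n_particles(self) -> int:
        return self.ds.sizes["particle"]

    @property
    def days_before(self) -> np.ndarray:
        return self.ds["days_before"].values

    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def sst(self) -> np.ndarray:
        return self.ds["sst"].values

    @property
    def beached(self) -> np.ndarray:
        return self.ds["beached"].values.astype(bool)

    def beached_fraction(self) -> float:
        return float(self.beached.mean())

    # -- I/O -----------------------------------------------------------------

    def to_netcdf(self, path):
        ds = self.ds.copy()
        ds.attrs["stranding"] = json.dumps(asdict(self.stranding))
        ds.attrs["config"] = json.dumps(asdict(self.config))
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "TrajectoryEnsemble":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            ds = ds.load()
        stranding = Stranding(**json.loads(ds.attrs["stranding"]))
        cfg = json.loads(ds.attrs["config"])
        cfg["thresholds"] = tuple(cfg["thresholds"])
        config = SimulationConfig(**cfg)
        return cls(ds, stranding, config)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form daily records (drops missing rows); for small ensembles."""
        df = self.ds[["lon", "lat", "sst", "status"]].to_dataframe().reset_index()
        return df[df["status"] >= 0].reset_index(drop=True)


def run_backtrack(fieldset: FieldSet, stranding: Stranding,
                  config: SimulationConfig) -> TrajectoryEnsemble:
    """Integrate one ensemble backward from the stranding date.

    Every particle starts at t0 = ``stranding.t0`` and is stepped with
    dt = -config.dt until t0 - duration or beaching; the anti-beaching push
    is applied after every step that lands in a land cell, and a record
    (t, lon, lat, sst, status) is stored every output interval, including
    at t0.  Particles leaving the regional domain are marked beached with
    reason "domain_exit" so the ensemble accounting always sums to n.
    """
    n = config.n_particles
    dt = config.dt
    n_steps = int(round(config.duration_days * 86400.0 / dt))
    rec_every = int(round(config.output_interval / dt))
    n_rec = n_steps // rec_every + 1

    lon, lat = release_positions(stranding, fieldset.mask, n, config.seed,
                                 config.release_mode)
    active = np.ones(n, dtype=bool)
    reason = np.zeros(n, dtype=np.int8)
    beach_time = np.full(n, np.nan)
    fails = np.zeros(n, dtype=np.int32)

    rec_lon = np.full((n, n_rec), np.nan)
    rec_lat = np.full((n, n_rec), np.nan)
    rec_sst = np.full((n, n_rec), np.nan)
    rec_status = np.full((n, n_rec), -1, dtype=np.int8)

    def vel(lo, la, tt):
        return composite_velocity(fieldset, config.windage, lo, la, tt,
                                  out_of_range="nan", masked="zero")

    def record(r, t):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            return
        sst = fieldset.sst.interp(lon[idx], lat[idx], t,
                                  out_of_range="nan", masked="nan")
        rec_lon[idx, r] = lon[idx]
        rec_lat[idx, r] = lat[idx]
        rec_sst[idx, r] = sst
        rec_status[idx, r] = 0

    mask = fieldset.mask
    has_land = mask.is_land.any()
    t = float(stranding.t0)
    record(0, t)

    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        new_lon, new_lat = rk4_step(lon[idx], lat[idx], t, -dt, vel,
                                    metric=config.metric, ref_lat=config.ref_lat)
        t_new = t - dt
        # a NaN stage means the particle (or a stage point) left the domain
        gone = ~np.isfinite(new_lon) | ~np.isfinite(new_lat)
        if gone.any():
            g = idx[gone]
            active[g] = False
            reason[g] = 3
            beach_time[g] = t_new
            idx, new_lon, new_lat = idx[~gone], new_lon[~gone], new_lat[~gone]
        lon[idx], lat[idx] = new_lon, new_lat

        if has_land and idx.size:
            in_mask = ((lon[idx] >= mask.lon_edges[0])
                       & (lon[idx] < mask.lon_edges[-1])
                       & (lat[idx] >= mask.lat_edges[0])
                       & (lat[idx] < mask.lat_edges[-1]))
            if not in_mask.all():
                out = idx[~in_mask]
                active[out] = False
                reason[out] = 3
                beach_time[out] = t_new
                idx = idx[in_mask]
            if idx.size == 0:
                t = t_new
                continue
            ci, cj = mask.cell_of(lon[idx], lat[idx])
            on_land = mask.is_land[ci, cj]
            if on_land.any():
                li = idx[on_land]
                plon, plat, no_norm = anti_beach(lon[li], lat[li], mask, dt)
                if no_norm.any():
                    dead = li[no_norm]
                    active[dead] = False
                    reason[dead] = 2
                    beach_time[dead] = t_new
                li, plon, plat = li[~no_norm], plon[~no_norm], plat[~no_norm]
                if li.size:
                    lon[li], lat[li] = plon, plat
                    in_dom = ((plon >= mask.lon_edges[0])
                              & (plon < mask.lon_edges[-1])
                              & (plat >= mask.lat_edges[0])
                              & (plat < mask.lat_edges[-1]))
                    if not in_dom.all():
                        out = li[~in_dom]
                        active[out] = False
                        reason[out] = 3
                        beach_time[out] = t_new
                        li = li[in_dom]
                    if li.size:
                        still = mask.is_land_at(lon[li], lat[li])
                        fails[li] = np.where(still, fails[li] + 1, 0)
                        stuck = li[fails[li] >= config.beach_patience]
                        active[stuck] = False
                        reason[stuck] = 1
                        beach_time[stuck] = t_new
            freed = idx[~on_land]
            fails[freed] = 0

        t = t_new
        if step % rec_every == 0:
            record(step // rec_every, t)

    days = np.arange(n_rec) * config.output_interval / 86400.0
    ds = xr.Dataset(
        {
            "lon": (("particle", "record"), rec_lon),
            "lat": (("particle", "record"), rec_lat),
            "sst": (("particle", "record"), rec_sst),
            "status": (("particle", "record"), rec_status),
            "beached": (("particle",), (~active).astype(np.int8)),
            "beach_reason": (("particle",), reason),
            "beach_time": (("particle",), beach_time),
        },
        coords={
            "particle": np.arange(n),
            "record": np.arange(n_rec),
            "days_before": ("record", days),
            "time": ("record", stranding.t0 - days * 86400.0),
        },
    )
    return TrajectoryEnsemble(ds, stranding, config)
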