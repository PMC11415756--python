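"""Gridded space-time fields on regular lon/lat grids.

This module is the data model shared by every stage of the pipeline: scalar
and vector fields with a time axis (surface currents, Stokes drift, 10 m
wind, SST), a rasterised land mask with shoreline normals for the
anti-beaching kernel, and CF-style NetCDF I/O.

Conventions
-----------
* Axes are 1-D, strictly increasing; field values are indexed
  ``[time, lat, lon]``.
* Interpolation is bilinear in space on the enclosing cell and linear in
  time between the two bracketing slices (the conventional choice for
  A-grid, i.e. collocated, ocean model output).
* Queries outside the time span are clamped to the nearest slice with a
  logged warning; queries outside the spatial bounding box raise
  :class:`~coldstun_drift.errors.DomainError` (or yield NaN in vectorised
  ``out_of_range="nan"`` mode used by the particle integrator).
* Point-in-cell uses half-open cells ``[west_edge, east_edge)`` x
  ``[south_edge, north_edge)`` so every point maps to exactly one cell, and
  a point on a shared edge belongs to the greater-index cell.
* Longitudes are treated as a plain Cartesian coordinate on a regional
  domain declared on a common [-180, 180) convention; no wraparound.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import DomainError, FieldLoadError, MaskedValueError

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "GridAxes",
    "GriddedField",
    "LandMask",
    "FieldSet",
    "read_fieldset",
    "write_fieldset",
    "DEFAULT_VAR_MAP",
]


def _as_axis(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size and not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} axis must be strictly increasing")
    return arr


@dataclass(frozen=True)
class GridAxes:
    """Coordinate axes of a regular lon/lat(/time) grid.

    Parameters
    ----------
    lon, lat : array-like
        Degrees east / degrees north, strictly increasing, length >= 2.
    time : array-like or None
        Seconds since a reference epoch, strictly increasing.  ``None`` or a
        single value denotes a static field (e.g. a land mask).
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray | None = None

    def __post_init__(self):
        lon = _as_axis(self.lon, "lon")
        lat = _as_axis(self.lat, "lat")
        if lon.size < 2 or lat.size < 2:
            raise ValueError("lon and lat axes need at least 2 nodes")
        if lon.min() < -180.0 or lon.max() >= 360.0:
            raise ValueError("lon axis outside [-180, 360)")
        if lat.min() < -90.0 or lat.max() > 90.0:
            raise ValueError("lat axis outside [-90, 90]")
        time = None if self.time is None else _as_axis(self.time, "time")
        if time is not None and time.size < 1:
            raise ValueError("time axis must have at least 1 entry")
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "time", time)

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def ntime(self) -> int:
        return 1 if self.time is None else self.time.size


def _cell_edges(centers: np.ndarray) -> np.ndarray:
    """Edges of half-open cells around node centres (uniform extrapolation
    by half a spacing at the boundaries)."""
    mid = 0.5 * (centers[:-1] + centers[1:])
    first = centers[0] - (mid[0] - centers[0])
    last = centers[-1] + (centers[-1] - mid[-1])
    return np.concatenate(([first], mid, [last]))


def _time_bracket(time_axis, t, label=""):
    """Indices/fraction of the two slices bracketing t, clamped to the span."""
    if time_axis is None or time_axis.size == 1:
        return 0, 0, 0.0
    if t < time_axis[0] or t > time_axis[-1]:
        logger.warning(
            "time %s outside field span [%s, %s]%s; clamping to nearest slice",
            t, time_axis[0], time_axis[-1], f" ({label})" if label else "",
        )
        t = min(max(t, time_axis[0]), time_axis[-1])
    i1 = int(np.searchsorted(time_axis, t, side="right"))
    i1 = min(max(i1, 1), time_axis.size - 1)
    i0 = i1 - 1
    ft = (t - time_axis[i0]) / (time_axis[i1] - time_axis[i0])
    return i0, i1, float(ft)


class GriddedField:
    """A time-stamped scalar or vector field on a regular lon/lat grid.

    Scalar fields carry one ``[time, lat, lon]`` array; vector fields carry
    eastward/northward component arrays on one shared :class:`GridAxes`.
    ``fill_mask`` marks invalid (land / fill-value) nodes.

    Spatially-uniform time slices are detected at construction and served
    through a fast path, which also guarantees that constant fields
    interpolate to exactly the constant.
    """

    def __init__(self, axes: GridAxes, data=None, u=None, v=None,
                 fill_mask=None, units: str = "", name: str = ""):
        if (data is None) == (u is None):
            raise ValueError("provide either data (scalar) or u and v (vector)")
        if (u is None) != (v is None):
            raise ValueError("vector fields need both u and v")
        self.axes = axes
        self.units = units
        self.name = name
        shape = (axes.ntime, axes.nlat, axes.nlon)

        def _check(arr, what):
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim == 2:
                arr = arr[np.newaxis]
            if arr.shape != shape:
                raise ValueError(f"{what} shape {arr.shape} != axes shape {shape}")
            return arr

        self._components = ((_check(data, "data"),) if data is not None
                            else (_check(u, "u"), _check(v, "v")))
        if fill_mask is not None:
            fill_mask = np.asarray(fill_mask, dtype=bool)
            if fill_mask.ndim == 2:
                fill_mask = np.broadcast_to(fill_mask[np.newaxis], shape)
            if fill_mask.shape != shape:
                raise ValueError("fill_mask shape inconsistent with axes")
        self.fill_mask = fill_mask
        self._uniform = self._detect_uniform()

    # -- construction helpers ------------------------------------------------

    @property
    def is_vector(self) -> bool:
        return len(self._components) == 2

    @property
    def values(self):
        """The raw component array(s): one array (scalar) or a (u, v) pair."""
        return self._components[0] if not self.is_vector else self._components

    def _detect_uniform(self):
        if self.fill_mask is not None and self.fill_mask.any():
            return None
        series = []
        for comp in self._components:
            flat = comp.reshape(comp.shape[0], -1)
            if not np.all(flat == flat[:, :1]):
                return None
            series.append(flat[:, 0].copy())
        return series

    # -- interpolation -------------------------------------------------------

    def interp(self, lon, lat, t, *, out_of_range="raise", masked="raise"):
        """Interpolate the field at point(s) (lon, lat) and scalar time t.

        Bilinear in space, linear in time.  1-3 masked enclosing nodes are
        handled by renormalising the bilinear weights over the unmasked
        nodes; all four masked is an error (``masked="raise"``), NaN
        (``"nan"``) or zero (``"zero"``, used for velocities inside land
        where the anti-beaching kernel takes over).

        Returns an array shaped like ``lon`` (scalar in, scalar out); vector
        fields return a (u, v) tuple.
        """
        lon_q = np.asarray(lon, dtype=np.float64)
        lat_q = np.asarray(lat, dtype=np.float64)
        scalar_in = lon_q.ndim == 0
        lon_q, lat_q = np.atleast_1d(lon_q), np.atleast_1d(lat_q)
        ax = self.axes

        inside = ((lon_q >= ax.lon[0]) & (lon_q <= ax.lon[-1])
                  & (lat_q >= ax.lat[0]) & (lat_q <= ax.lat[-1]))
        if out_of_range == "raise" and not inside.all():
            k = int(np.flatnonzero(~inside)[0])
            raise DomainError(
                f"point (lon={lon_q[k]}, lat={lat_q[k]}) outside field domain "
                f"lon [{ax.lon[0]}, {ax.lon[-1]}], lat [{ax.lat[0]}, {ax.lat[-1]}]")

        i0, i1, ft = _time_bracket(ax.time, float(t), self.name)

        if self._uniform is not None:
            out = []
            for series in self._uniform:
                a, b = series[i0], series[i1]
                val = a + ft * (b - a)
                res = np.full(lon_q.shape, val)
                res[~inside] = np.nan
                out.append(res)
        else:
            ix = np.clip(np.searchsorted(ax.lon, lon_q, side="right") - 1,
                         0, ax.nlon - 2)
            iy = np.clip(np.searchsorted(ax.lat, lat_q, side="right") - 1,
                         0, ax.nlat - 2)
            fx = (lon_q - ax.lon[ix]) / (ax.lon[ix + 1] - ax.lon[ix])
            fy = (lat_q - ax.lat[iy]) / (ax.lat[iy + 1] - ax.lat[iy])
            out = []
            for comp in self._components:
                va = self._bilinear(comp, i0, iy, ix, fy, fx)
                if i1 != i0 and ft != 0.0:
                    vb = self._bilinear(comp, i1, iy, ix, fy, fx)
                    va = va + ft * (vb - va)
                va = np.where(inside, va, np.nan)
                out.append(va)

        if self.fill_mask is not None:
            fully_masked = np.isnan(out[0]) & inside
            if fully_masked.any():
                if masked == "raise":
                    k = int(np.flatnonzero(fully_masked)[0])
                    raise MaskedValueError(
                        f"all enclosing nodes masked at "
                        f"(lon={lon_q[k]}, lat={lat_q[k]})")
                if masked == "zero":
                    out = [np.where(fully_masked, 0.0, o) for o in out]

        if scalar_in:
            out = [o[0] for o in out]
        return tuple(out) if self.is_vector else out[0]

    def _bilinear(self, comp, it, iy, ix, fy, fx):
        c00 = comp[it, iy, ix]
        c10 = comp[it, iy, ix + 1]
        c01 = comp[it, iy + 1, ix]
        c11 = comp[it, iy + 1, ix + 1]
        if self.fill_mask is None:
            v0 = c00 + fx * (c10 - c00)
            v1 = c01 + fx * (c11 - c01)
            return v0 + fy * (v1 - v0)
        m = self.fill_mask
        ok00 = ~m[it, iy, ix]
        ok10 = ~m[it, iy, ix + 1]
        ok01 = ~m[it, iy + 1, ix]
        ok11 = ~m[it, iy + 1, ix + 1]
        w00 = (1 - fx) * (1 - fy) * ok00
        w10 = fx * (1 - fy) * ok10
        w01 = (1 - fx) * fy * ok01
        w11 = fx * fy * ok11
        wt = w00 + w10 + w01 + w11
        num = (w00 * np.where(ok00, c00, 0.0) + w10 * np.where(ok10, c10, 0.0)
               + w01 * np.where(ok01, c01, 0.0) + w11 * np.where(ok11, c11, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(wt > 0, num / np.where(wt > 0, wt, 1.0), np.nan)


class LandMask:
    """A static land/ocean raster with half-open cells and shoreline normals.

    ``is_land`` is indexed ``[lat, lon]`` (i = lat row, j = lon column).
    """

    def __init__(self, axes: GridAxes, is_land):
        if axes.time is not None and axes.time.size > 1:
            raise ValueError("land mask must be static (no time axis)")
        is_land = np.asarray(is_land, dtype=bool)
        if is_land.shape != (axes.nlat, axes.nlon):
            raise ValueError("is_land shape inconsistent with axes")
        if not (~is_land).any():
            raise ValueError("mask has no ocean cell")
        self.axes = axes
        self.is_land = is_land
        self.lon_edges = _cell_edges(axes.lon)
        self.lat_edges = _cell_edges(axes.lat)
        self._normals = None

    # -- point-in-cell -------------------------------------------------------

    def cell_of(self, lon, lat):
        """(i, j) = (lat row, lon column) of the half-open cell holding the
        point(s); a point on a shared edge belongs to the greater-index cell."""
        lon_q = np.asarray(lon, dtype=np.float64)
        lat_q = np.asarray(lat, dtype=np.float64)
        scalar_in = lon_q.ndim == 0
        lon_q, lat_q = np.atleast_1d(lon_q), np.atleast_1d(lat_q)
        j = np.searchsorted(self.lon_edges, lon_q, side="right") - 1
        i = np.searchsorted(self.lat_edges, lat_q, side="right") - 1
        bad = (j < 0) | (j >= self.axes.nlon) | (i < 0) | (i >= self.axes.nlat)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise DomainError(
                f"point (lon={lon_q[k]}, lat={lat_q[k]}) outside mask bounding box")
        if scalar_in:
            return int(i[0]), int(j[0])
        return i, j

    def is_land_at(self, lon, lat):
        i, j = self.cell_of(lon, lat)
        return self.is_land[i, j]

    # -- shoreline geometry --------------------------------------------------

    def shoreline_normal(self, i: int, j: int):
        """Unit vector (east, north) from land cell (i, j) toward water.

        The normalised vector sum of unit offsets toward each ocean cell in
        the 3x3 neighbourhood; returns None when the neighbourhood is fully
        landlocked or the offsets cancel (no usable normal).
        """
        nx, ny, ok = self.normal_grid()
        if not ok[i, j]:
            return None
        return float(nx[i, j]), float(ny[i, j])

    def normal_grid(self):
        """Cached per-cell normals (east, north, valid) for every cell."""
        if self._normals is None:
            ocean = (~self.is_land).astype(np.float64)
            nlat, nlon = ocean.shape
            sx = np.zeros_like(ocean)
            sy = np.zeros_like(ocean)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    norm = float(np.hypot(di, dj))
                    shifted = np.zeros_like(ocean)
                    src_i = slice(max(di, 0), nlat + min(di, 0))
                    dst_i = slice(max(-di, 0), nlat + min(-di, 0))
                    src_j = slice(max(dj, 0), nlon + min(dj, 0))
                    dst_j = slice(max(-dj, 0), nlon + min(-dj, 0))
                    shifted[dst_i, dst_j] = ocean[src_i, src_j]
                    sx += shifted * (dj / norm)
                    sy += shifted * (di / norm)
            mag = np.hypot(sx, sy)
            ok = mag > 1e-12
            with np.errstate(invalid="ignore", divide="ignore"):
                nx = np.where(ok, sx / np.where(ok, mag, 1.0), 0.0)
                ny = np.where(ok, sy / np.where(ok, mag, 1.0), 0.0)
            self._normals = (nx, ny, ok)
        return self._normals


@dataclass
class FieldSet:
    """The forcing bundle: currents, Stokes drift, 10 m wind, SST, land mask.

    Each field lives on its own grid and is interpolated on that grid; the
    union of the fields' time spans should cover the simulation window
    (queries beyond a span clamp to the nearest slice, with a warning).
    """

    currents: GriddedField
    stokes: GriddedField
    wind10m: GriddedField
    sst: GriddedField
    mask: LandMask

    def __post_init__(self):
        for nm in ("currents", "stokes", "wind10m"):
            if not getattr(self, nm).is_vector:
                raise ValueError(f"{nm} must be a vector field")
        if self.sst.is_vector:
            raise ValueError("sst must be a scalar field")

    def time_span(self):
        """(earliest, latest) covered by the union of the four fields."""
        starts, ends = [], []
        for f in (self.currents, self.stokes, self.wind10m, self.sst):
            tax = f.axes.time
            if tax is not None:
                starts.append(tax[0])
                ends.append(tax[-1])
        if not starts:
            return (-np.inf, np.inf)
        return (min(starts), max(ends))


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style, scipy/NetCDF3 backend)
# ---------------------------------------------------------------------------

DEFAULT_VAR_MAP = {
    "currents": ("uo", "vo"),
    "stokes": ("uso", "vso"),
    "wind10m": ("u10", "v10"),
    "sst": "sst",
    "mask": "land",
}

_FILES = {
    "currents": "currents.nc",
    "stokes": "stokes.nc",
    "wind10m": "wind10m.nc",
    "sst": "sst.nc",
    "mask": "mask.nc",
}

_TIME_UNITS = "seconds since 1970-01-01 00:00:00"


def _field_to_dataset(fld: GriddedField, names) -> xr.Dataset:
    ax = fld.axes
    coords = {
        "lon": ("lon", ax.lon, {"units": "degrees_east"}),
        "lat": ("lat", ax.lat, {"units": "degrees_north"}),
        "time": ("time", ax.time if ax.time is not None else np.array([0.0]),
                 {"units": _TIME_UNITS}),
    }
    data_vars = {}
    comps = fld._components
    names = (names,) if isinstance(names, str) else names
    for nm, comp in zip(names, comps):
        data_vars[nm] = (("time", "lat", "lon"), comp, {"units": fld.units})
    if fld.fill_mask is not None:
        data_vars["fill_mask"] = (("time", "lat", "lon"),
                                  fld.fill_mask.astype(np.int8),
                                  {"long_name": "1 where node is invalid"})
    return xr.Dataset(data_vars, coords=coords)


def write_fieldset(fieldset: FieldSet, path) -> dict:
    """Write the five forcing files (NetCDF3 classic via scipy) under path.

    Emits exactly the dialect :func:`read_fieldset` consumes; returns the
    mapping of component name to file path.
    """
    os.makedirs(path, exist_ok=True)
    written = {}
    for key in ("currents", "stokes", "wind10m", "sst"):
        ds = _field_to_dataset(getattr(fieldset, key), DEFAULT_VAR_MAP[key])
        fp = os.path.join(path, _FILES[key])
        ds.to_netcdf(fp, engine="scipy")
        written[key] = fp
    mask = fieldset.mask
    ds = xr.Dataset(
        {DEFAULT_VAR_MAP["mask"]: (("lat", "lon"),
                                   mask.is_land.astype(np.int8),
                                   {"long_name": "1 where land"})},
        coords={"lon": ("lon", mask.axes.lon, {"units": "degrees_east"}),
                "lat": ("lat", mask.axes.lat, {"units": "degrees_north"})},
    )
    fp = os.path.join(path, _FILES["mask"])
    ds.to_netcdf(fp, engine="scipy")
    written["mask"] = fp
    return written


def _check_axis(ds, name, path):
    if name not in ds:
        raise FieldLoadError(f"{path}: missing coordinate '{name}'")
    vals = np.asarray(ds[name].values, dtype=np.float64)
    if vals.size > 1 and not np.all(np.diff(vals) > 0):
        raise FieldLoadError(f"{path}: '{name}' axis is not strictly increasing")
    return vals


_EXPECTED_UNITS = {
    "currents": ("m s-1", "m/s", "m s**-1", "meters per second"),
    "stokes": ("m s-1", "m/s", "m s**-1", "meters per second"),
    "wind10m": ("m s-1", "m/s", "m s**-1", "meters per second"),
    "sst": ("degc", "celsius", "degrees_celsius", "degree_celsius", "c"),
}


def _load_field(path, key, names) -> GriddedField:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        lon = _check_axis(ds, "lon", path)
        lat = _check_axis(ds, "lat", path)
        time = _check_axis(ds, "time", path) if "time" in ds else None
        names = (names,) if isinstance(names, str) else tuple(names)
        arrays = []
        units = ""
        for nm in names:
            if nm not in ds:
                raise FieldLoadError(f"{path}: missing variable '{nm}'")
            var = ds[nm]
            units = str(var.attrs.get("units", ""))
            expected = _EXPECTED_UNITS.get(key)
            if expected and units and units.lower() not in expected:
                raise FieldLoadError(
                    f"{path}: variable '{nm}' has units '{units}', "
                    f"expected one of {expected}")
            arrays.append(np.asarray(var.values, dtype=np.float64))
        fill = (np.asarray(ds["fill_mask"].values, dtype=bool)
                if "fill_mask" in ds else None)
    axes = GridAxes(lon, lat, time)
    if len(arrays) == 1:
        return GriddedField(axes, data=arrays[0], fill_mask=fill,
                            units=units, name=key)
    return GriddedField(axes, u=arrays[0], v=arrays[1], fill_mask=fill,
                        units=units, name=key)


def read_fieldset(path, var_map=None, mask_from="file") -> FieldSet:
    """Load a FieldSet from a directory of CF-style NetCDF files.

    ``var_map`` overrides variable names per component to accommodate source
    dialects (e.g. ``{"currents": ("u", "v")}``).  ``mask_from`` is either
    ``"file"`` (read mask.nc) or ``"currents"`` (derive land from the
    currents field's fill mask at the first time slice).
    """
    vm = dict(DEFAULT_VAR_MAP)
    if var_map:
        vm.update(var_map)
    fields = {}
    for key in ("currents", "stokes", "wind10m", "sst"):
        fields[key] = _load_field(os.path.join(path, _FILES[key]), key, vm[key])
    if mask_from == "currents":
        cur = fields["currents"]
        if cur.fill_mask is None:
            raise FieldLoadError("currents field has no fill mask to derive land from")
        axes = GridAxes(cur.axes.lon, cur.axes.lat, None)
        mask = LandMask(axes, cur.fill_mask[0])
    else:
        fp = os.path.join(path, _FILES["mask"])
        with xr.open_dataset(fp, engine="scipy", decode_times=False) as ds:
            lon = _check_axis(ds, "lon", fp)
            lat = _check_axis(ds, "lat", fp)
            nm = vm["mask"]
            if nm not in ds:
                raise FieldLoadError(f"{fp}: missing variable '{nm}'")
            is_land = np.asarray(ds[nm].values).astype(bool)
        mask = LandMask(GridAxes(lon, lat, None), is_land)
    return FieldSet(mask=mask, **fields)
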