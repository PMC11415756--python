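"""Cold-stunning event detection along particle temperature records.

A cold-stunning event is the most recent time before stranding at which the
SST interpolated along a particle's trajectory drops below a threshold
temperature T_c (10, 12 or 14 degC): above T_c the turtle is assumed to
swim actively, below it to drift passively, so only the latest downward
crossing matters.  Detection operates on the stored daily records (the
analysis resolution), hence t_cross is a whole number of output intervals.

Convention: a record counts as "stunned" when strictly below T_c and as
"not yet stunned" when at or above it, so a crossing is sst[k] < T_c with
sst[k-1] >= T_c in forward-time order.  Series that never go below T_c
yield no event; so do series below T_c at every record (such particles
never crossed within the window and are excluded, as are e.g. particles
arriving from cold coastal water without ever encountering warmer water).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "detect_last_crossing",
    "extract_events",
    "events_table",
    "EVENT_COLUMNS",
]

EARTH_RADIUS_KM = 6371.0

EVENT_COLUMNS = ["particle_id", "stranding", "windage", "T_c",
                 "days_before_stranding", "lon", "lat", "distance_km"]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (R = 6371 km); vectorised."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=np.float64))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = (np.sin(0.5 * dlat) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(0.5 * dlon) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def detect_last_crossing(sst_series, times, t_c):
    """Latest downward crossing of ``t_c`` in a forward-time SST series.

    Parameters
    ----------
    sst_series : sequence of float
        Temperatures in forward-time order (earliest first, stranding
        last); NaN marks missing records (before a beached particle's
        release into the record window) and is only permitted as a prefix.
    times : sequence of float
        Days before stranding for each entry, strictly decreasing to 0.
    t_c : float
        Threshold temperature, degC.

    Returns
    -------
    (t_cross_days, index) or None
        Days before stranding and forward-time index of the crossing, or
        None when no downward crossing exists.
    """
    sst = np.asarray(sst_series, dtype=np.float64)
    tms = np.asarray(times, dtype=np.float64)
    if sst.shape != tms.shape or sst.ndim != 1 or sst.size < 1:
        raise ValueError("sst series and times must be equal-length 1-D")
    if tms.size > 1 and not np.all(np.diff(tms) < 0):
        raise ValueError("times must be strictly decreasing toward stranding")
    finite = np.isfinite(sst)
    for k in range(sst.size - 1, 0, -1):
        if finite[k] and finite[k - 1] and sst[k] < t_c and sst[k - 1] >= t_c:
            return float(tms[k]), k
    return None


def extract_events(ensemble, t_c) -> pd.DataFrame:
    """One cold-stun event per particle whose daily record contains a
    downward crossing of ``t_c``; particles with none contribute nothing.

    Beached particles are scanned over their pre-beaching records only.
    Returns a DataFrame with :data:`EVENT_COLUMNS` (stranding and windage
    taken from the ensemble metadata).
    """
    sst = ensemble.sst              # (particle, record), record 0 = stranding
    days = ensemble.days_before
    finite = np.isfinite(sst)
    # record index r = days before stranding; forward time runs r decreasing.
    # Latest forward crossing = smallest r with sst[r] < t_c, sst[r+1] >= t_c.
    cross = (finite[:, :-1] & finite[:, 1:]
             & (sst[:, :-1] < t_c) & (sst[:, 1:] >= t_c))
    has = cross.any(axis=1)
    r = np.argmax(cross, axis=1)
    pid = np.flatnonzero(has)
    r = r[has]
    lon = ensemble.lon[pid, r]
    lat = ensemble.lat[pid, r]
    dist = haversine_km(lon, lat, ensemble.stranding.lon, ensemble.stranding.lat)
    return pd.DataFrame({
        "particle_id": pid,
        "stranding": ensemble.stranding.name,
        "windage": ensemble.config.windage,
        "T_c": float(t_c),
        "days_before_stranding": days[r],
        "lon": lon,
        "lat": lat,
        "distance_km": dist,
    }, columns=EVENT_COLUMNS)


def events_table(ensembles, thresholds) -> pd.DataFrame:
    """Stacked events over several ensembles and thresholds."""
    frames = [extract_events(ens, tc) for ens in ensembles for tc in thresholds]
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
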