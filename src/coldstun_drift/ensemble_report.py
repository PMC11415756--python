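"""Windage-sensitivity summaries of cold-stunning events.

Aggregates events and ensembles into the analysis surface: for each
(stranding-or-pooled group, windage factor, threshold T_c) the fraction of
released particles that crossed the threshold, the fraction beached, and
the distribution (mean and quantiles) of days-before-stranding and
great-circle distance-from-stranding at the crossing.

The denominator of the crossing fraction is all released particles in the
group (beached included), so five production releases of 10,000 particles
pool to n = 50,000.  Pooled moments are event-weighted (every event counts
once, strandings are not re-weighted); per-stranding tables can always be
emitted alongside.  Quantiles use linear interpolation between order
statistics (type 7), pinned for reproducibility.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["QUANTILES", "summarize", "beached_fraction", "report_tables"]

QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)

_QCOLS = [f"q{int(q * 100):02d}" for q in QUANTILES]


def beached_fraction(ensemble) -> float:
    """Fraction of released particles with terminal status beached."""
    return ensemble.beached_fraction()


def _stats(values: np.ndarray, prefix: str) -> dict:
    out = {}
    if values.size == 0:
        out[f"{prefix}_mean"] = np.nan
        for qc in _QCOLS:
            out[f"{prefix}_{qc}"] = np.nan
        return out
    out[f"{prefix}_mean"] = float(np.mean(values))
    qs = np.quantile(values, QUANTILES)  # linear interpolation (type 7)
    for qc, qv in zip(_QCOLS, qs):
        out[f"{prefix}_{qc}"] = float(qv)
    return out


def summarize(events: pd.DataFrame, ensembles, grouping: str = "pooled"
              ) -> pd.DataFrame:
    """Aggregate events into the per-(group, windage, T_c) summary table.

    Parameters
    ----------
    events : DataFrame
        Stacked event rows (``coldstun_events.events_table``); must derive
        from ``ensembles``.
    ensembles : iterable of TrajectoryEnsemble
        Supplies release counts, beached counts, and the windage settings
        (rows are emitted for every (group, windage, T_c) even when no
        event exists, flagged ``has_events=False`` rather than silently
        NaN).
    grouping : "pooled" or "per-stranding"
    """
    ensembles = list(ensembles)
    if grouping not in ("pooled", "per-stranding"):
        raise ValueError(f"unknown grouping {grouping!r}")

    meta = pd.DataFrame({
        "stranding": [e.stranding.name for e in ensembles],
        "windage": [e.config.windage for e in ensembles],
        "n": [e.n_particles for e in ensembles],
        "n_beached": [int(e.beached.sum()) for e in ensembles],
        "thresholds": [tuple(e.config.thresholds) for e in ensembles],
    })
    # configured thresholds keep their (possibly empty, flagged) rows even
    # when no particle anywhere crossed them
    thresholds = {tc for t in meta["thresholds"] for tc in t}
    if len(events):
        thresholds.update(float(tc) for tc in events["T_c"].unique())
    thresholds = sorted(thresholds)

    def group_key(name):
        return "pooled" if grouping == "pooled" else name

    meta["group"] = [group_key(s) for s in meta["stranding"]]
    ev = events.copy()
    if len(ev):
        ev["group"] = [group_key(s) for s in ev["stranding"]]

    rows = []
    for (grp, alpha), sub in meta.groupby(["group", "windage"], sort=True):
        n_total = int(sub["n"].sum())
        n_beached = int(sub["n_beached"].sum())
        for tc in thresholds:
            if len(ev):
                sel = ev[(ev["group"] == grp) & (ev["windage"] == alpha)
                         & (ev["T_c"] == tc)]
            else:
                sel = ev
            n_crossed = int(len(sel))
            row = {
                "group": grp,
                "windage": float(alpha),
                "T_c": float(tc),
                "n_total": n_total,
                "n_crossed": n_crossed,
                "frac_crossed": n_crossed / n_total,
                "n_beached": n_beached,
                "frac_beached": n_beached / n_total,
                "has_events": n_crossed > 0,
            }
            days = sel["days_before_stranding"].to_numpy() if n_crossed else np.array([])
            dist = sel["distance_km"].to_numpy() if n_crossed else np.array([])
            row.update(_stats(days, "days"))
            row.update(_stats(dist, "distance_km"))
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "windage", "T_c"]).reset_index(drop=True)


def report_tables(summaries: pd.DataFrame, out_path) -> dict:
    """Write the summary CSV and a human-readable digest under out_path.

    Ordering is deterministic: groups alphabetical, windage and T_c
    ascending.  Returns the written file paths.
    """
    os.makedirs(out_path, exist_ok=True)
    ordered = summaries.sort_values(["group", "windage", "T_c"]).reset_index(drop=True)
    csv_path = os.path.join(out_path, "summary.csv")
    ordered.to_csv(csv_path, index=False)

    lines = ["Cold-stunning windage sensitivity summary", ""]
    for grp, sub in ordered.groupby("group", sort=True):
        lines.append(f"group: {grp}")
        for alpha in sorted(sub["windage"].unique()):
            asub = sub[sub["windage"] == alpha]
            n_total = int(asub["n_total"].iloc[0])
            fb = float(asub["frac_beached"].iloc[0])
            lines.append(f"  windage {alpha * 100:.1f}%  "
                         f"(n = {n_total}, beached {fb * 100:.1f}%)")
            for _, r in asub.sort_values("T_c").iterrows():
                if r["has_events"]:
                    lines.append(
                        f"    T_c = {r['T_c']:.0f} degC: "
                        f"{r['frac_crossed'] * 100:.1f}% crossed; "
                        f"days before stranding mean {r['days_mean']:.1f} "
                        f"(median {r['days_q50']:.1f}); "
                        f"distance mean {r['distance_km_mean']:.1f} km "
                        f"(median {r['distance_km_q50']:.1f} km)")
                else:
                    lines.append(f"    T_c = {r['T_c']:.0f} degC: no crossings")
        lines.append("")
    digest_path = os.path.join(out_path, "digest.txt")
    with open(digest_path, "w") as fh:
        fh.write("\n".join(lines))
    return {"summary": csv_path, "digest": digest_path}
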