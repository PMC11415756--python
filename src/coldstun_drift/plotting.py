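"""Optional plotting sugar: violin plots of the windage-sensitivity surface.

The tested deliverable is the numeric summary table; these helpers render
the events table the way the sensitivity analysis is usually shown (one
violin per windage setting, panelled by threshold temperature).
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def violin_by_windage(events, value="days_before_stranding", ax=None):
    """Violin plot of ``value`` per windage setting for one threshold.

    ``events`` is an event DataFrame restricted to one T_c.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    settings = sorted(events["windage"].unique())
    data = [events.loc[events["windage"] == a, value].to_numpy()
            for a in settings]
    data = [d for d in data if d.size]
    labels = [f"{a * 100:.1f}%" for a, d in
              zip(settings, (events.loc[events["windage"] == a, value]
                             for a in settings)) if len(d)]
    if data:
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(data) + 1), labels)
    ax.set_xlabel("windage factor")
    ax.set_ylabel(value.replace("_", " "))
    return ax


def windage_panels(events, thresholds, value="days_before_stranding",
                   out_path=None):
    """One violin panel per threshold; optionally saved to ``out_path``."""
    fig, axes = plt.subplots(1, len(thresholds),
                             figsize=(4 * len(thresholds), 4), squeeze=False)
    for ax, tc in zip(axes[0], thresholds):
        violin_by_windage(events[events["T_c"] == tc], value=value, ax=ax)
        ax.set_title(f"T_c = {tc:g} degC")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
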