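"""Matplotlib helpers: DVH band graphs and box-and-whisker group comparisons."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .robustness import DVHBand
from .stats import boxplot_stats


def plot_dvh_band(band: DVHBand, ax=None, color="C0"):
    """Shaded min-max envelope across scenarios with the nominal curve."""
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(
        band.dose_gy,
        100 * band.envelope_low,
        100 * band.envelope_high,
        alpha=0.3,
        color=color,
        label=f"{band.structure} (13-scenario band)",
    )
    ax.plot(band.dose_gy, 100 * band.nominal, color=color, label="nominal")
    ax.set_xlabel("dose (Gy[RBE])")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax


def plot_group_boxes(metrics, context: str, indices=None, ax=None):
    """Side-by-side S-I vs R-L boxes (1.5-IQR whiskers) per DVH index.

    ``metrics`` is the long pipeline table (context, index, group, pair,
    value).
    """
    sub = metrics[metrics.context == context]
    indices = indices or sorted(sub["index"].unique())
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(indices) + 2, 4))
    colors = {"S-I": "C0", "R-L": "C8"}
    for i, index in enumerate(indices):
        for j, group in enumerate(("S-I", "R-L")):
            vals = sub[(sub["index"] == index) & (sub.group == group)].value.to_numpy()
            if vals.size == 0:
                continue
            s = boxplot_stats(vals)
            x = i + (j - 0.5) * 0.35
            ax.bxp(
                [
                    dict(
                        med=s["q2"], q1=s["q1"], q3=s["q3"],
                        whislo=s["whisker_low"], whishi=s["whisker_high"],
                        fliers=s["outliers"],
                    )
                ],
                positions=[x],
                widths=0.3,
                showfliers=True,
                boxprops=dict(color=colors[group]),
                medianprops=dict(color=colors[group]),
            )
    ax.set_xticks(range(len(indices)))
    ax.set_xticklabels(indices, rotation=45, ha="right")
    ax.set_title(context)
    return ax
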