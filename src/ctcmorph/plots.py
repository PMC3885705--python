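"""Quartile/box charts for cohort summaries (headless matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort import accepted

_LABELS = {"diameter_um": "Equivalent diameter (µm)",
           "nc_ratio": "N/C ratio", "ef": "Elongation factor"}


def per_sample_quartile_plot(df: pd.DataFrame, metric: str,
                             path: str | Path) -> Path:
    """Median with upper/lower quartile bars per sample, grouped by cohort."""
    acc = accepted(df).sort_values(["group", "sample_id"])
    samples = acc["sample_id"].unique()
    med, q1, q3, groups = [], [], [], []
    for sid in samples:
        vals = acc.loc[acc["sample_id"] == sid, metric]
        med.append(vals.median())
        q1.append(vals.quantile(0.25))
        q3.append(vals.quantile(0.75))
        groups.append(acc.loc[acc["sample_id"] == sid, "group"].iloc[0])
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(samples) + 2), 4))
    x = range(len(samples))
    colors = ["tab:red" if g == "ctc" else "tab:blue" for g in groups]
    lower = [max(m - lo, 0.0) for m, lo in zip(med, q1)]
    upper = [max(hi - m, 0.0) for m, hi in zip(q3, med)]
    ax.errorbar(x, med, yerr=[lower, upper], fmt="none", ecolor="gray", capsize=3)
    ax.scatter(x, med, c=colors, zorder=3)
    ax.set_xticks(list(x))
    ax.set_xticklabels(samples, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel(_LABELS.get(metric, metric))
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def group_boxplot(df: pd.DataFrame, metric: str, path: str | Path) -> Path:
    """Box plot of one metric by cohort group."""
    acc = accepted(df)
    groups = sorted(acc["group"].unique())
    data = [acc.loc[acc["group"] == g, metric].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(_LABELS.get(metric, metric))
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
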