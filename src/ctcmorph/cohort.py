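"""Cohort aggregation: per-sample summaries, group tests, shrinkage, QC report.

Works on the per-cell results table produced by the pipeline (one row per
tile; rejected tiles carry a rejection reason and are excluded from all
statistics).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CtcMorphError
from .morphometrics import QC_ACCEPTED

METRICS = ("diameter_um", "nc_ratio", "ef")


def accepted(df: pd.DataFrame) -> pd.DataFrame:
    """Rows that passed every QC rule."""
    return df[df["qc_status"] == QC_ACCEPTED]


@dataclass
class SampleSummary:
    """Median / quartile / mean / sd of each metric for one sample.

    Quartiles use linear interpolation between order statistics (the
    numpy/R type-7 default), documented here for reproducibility.
    """

    sample_id: str
    group: str
    n_cells: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_row(self) -> dict:
        row: dict = {"sample_id": self.sample_id, "group": self.group,
                     "n_cells": self.n_cells}
        for metric, vals in self.stats.items():
            for name, v in vals.items():
                row[f"{metric}_{name}"] = v
        return row


def summarize_sample(records: pd.DataFrame) -> SampleSummary | None:
    """Summarize one sample's accepted cells; None (with a warning) if empty."""
    acc = accepted(records)
    if len(acc) == 0:
        import warnings
        sid = records["sample_id"].iloc[0] if len(records) else "?"
        warnings.warn(f"sample {sid}: no accepted cells, summary omitted",
                      stacklevel=2)
        return None
    summary = SampleSummary(
        sample_id=str(acc["sample_id"].iloc[0]),
        group=str(acc["group"].iloc[0]),
        n_cells=int(len(acc)))
    for metric in METRICS:
        vals = acc[metric].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # type-7 interpolation
        summary.stats[metric] = {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return summary


def summarize_all(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample summary table over every sample present."""
    rows = []
    for _, sub in df.groupby("sample_id", sort=False):
        s = summarize_sample(sub)
        if s is not None:
            rows.append(s.to_row())
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Two-group test result for one metric."""

    metric: str
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float

    def to_row(self) -> dict:
        return self.__dict__.copy()


def compare_groups(a: Sequence[float], b: Sequence[float], metric: str,
                   method: str = "welch_t") -> GroupComparison:
    """Two-sided two-group comparison.

    ``welch_t`` (unequal-variance t test) suits diameter-like metrics;
    ``mann_whitney`` (rank-sum) suits the skewed EF and N/C distributions.
    Both are available for any metric.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CtcMorphError("each group needs at least 2 values")
    if method == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    else:
        raise CtcMorphError(f"unknown method {method!r}")
    return GroupComparison(
        metric=metric, method=method,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)))


def compare_groups_both(a, b, metric: str) -> list[GroupComparison]:
    """Welch t and Mann-Whitney rows for the same metric."""
    return [compare_groups(a, b, metric, m) for m in ("welch_t", "mann_whitney")]


def average_median(df: pd.DataFrame, metric: str) -> float:
    """Unweighted mean of per-sample medians (accepted cells only)."""
    acc = accepted(df)
    medians = acc.groupby("sample_id", sort=False)[metric].median()
    return float(medians.mean())


def shrinkage_analysis(t0: pd.DataFrame, t48: pd.DataFrame) -> dict[str, float]:
    """Percent change of mean cell and nuclear diameter between timepoints.

    Negative values mean shrinkage: pct = 100 * (mean_t48 - mean_t0) / mean_t0.
    """
    out = {}
    for key, col in (("cell_diameter_pct", "diameter_um"),
                     ("nuclear_diameter_pct", "nuc_diameter_um")):
        v0 = accepted(t0)[col].to_numpy(dtype=float)
        v1 = accepted(t48)[col].to_numpy(dtype=float)
        if len(v0) == 0 or len(v1) == 0:
            raise CtcMorphError("shrinkage analysis needs accepted cells at both "
                                "timepoints")
        out[key] = 100.0 * (v1.mean() - v0.mean()) / v0.mean()
    return out


@dataclass
class RejectionReport:
    """QC accounting: how many tiles were dropped, and why."""

    n_total: int
    n_rejected: int
    counts_per_reason: dict[str, int]

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def display_percent(self) -> str:
        """Fraction rounded to one decimal percent, display only."""
        return f"{100.0 * self.fraction_rejected:.1f}%"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"n_total": self.n_total, "n_rejected": self.n_rejected,
                   "fraction_rejected": self.fraction_rejected,
                   "display_percent": self.display_percent(),
                   "counts_per_reason": self.counts_per_reason}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def rejection_report(df: pd.DataFrame) -> RejectionReport:
    """Exact rejection counts; the fraction is rounded only at display time."""
    rejected = df[df["qc_status"] != QC_ACCEPTED]
    counts = rejected["qc_reason"].value_counts().to_dict()
    return RejectionReport(
        n_total=int(len(df)), n_rejected=int(len(rejected)),
        counts_per_reason={str(k): int(v) for k, v in counts.items()})


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) — scatter utility."""
    res = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
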