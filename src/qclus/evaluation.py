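"""Benchmark-evaluation computations.

Per method x sample summaries of four quality metrics over retained
droplets (unspliced fraction, mitochondrial percentage, total counts,
detected genes), per-sample standard scaling across methods, and three
failure rules: retaining too few nuclei relative to a comparator of
similar quality, retaining implausibly many, and retaining a low-quality
population when a comparator did substantially better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SUMMARY_METRICS = ("fraction_unspliced", "pct_mito", "total_counts", "n_genes")


@dataclass
class FailureThresholds:
    """Tunables for the failure rules, with the published defaults.

    Rule 1 (low_nuclei_count): flagged when fewer than ``low_count`` nuclei
    are retained while another method retains more than ``low_count_ratio``
    times as many at a mean unspliced fraction within
    ``low_count_unspliced_margin`` (absolute difference by default;
    ``margin_mode='relative'`` interprets the margin as a fraction of the
    comparator's value). Rule 2 (high_nuclei_count): more than
    ``high_count`` retained. Rule 3 (low_quality): median unspliced
    fraction below ``quality_floor`` while another method retains more
    nuclei with a median at least ``quality_margin`` higher.
    """

    low_count: int = 3000
    low_count_ratio: float = 4.0
    low_count_unspliced_margin: float = 0.10
    margin_mode: str = "absolute"
    high_count: int = 30000
    quality_floor: float = 0.30
    quality_margin: float = 0.20


def summarize(
    mask: np.ndarray, table: pd.DataFrame, method: str, sample: str
) -> dict:
    """Mean and median of the four quality metrics over retained droplets.

    An empty retained set yields ``n_retained`` 0 with NaN metrics.
    """
    mask = np.asarray(mask, dtype=bool)
    retained = table.loc[mask]
    row: dict = {"method": method, "sample": sample, "n_retained": int(mask.sum())}
    for metric in SUMMARY_METRICS:
        vals = retained[metric].to_numpy(dtype=float) if len(retained) else np.array([])
        row[f"mean_{metric}"] = float(np.mean(vals)) if len(vals) else np.nan
        row[f"median_{metric}"] = float(np.median(vals)) if len(vals) else np.nan
    return row


def standardize_across_methods(summaries: pd.DataFrame) -> pd.DataFrame:
    """Z-score each metric column across methods, per sample.

    Population scaling (ddof=0); a metric constant across methods maps to
    zeros. Non-metric columns (method, sample) pass through.
    """
    out = summaries.copy()
    value_cols = [
        c
        for c in summaries.columns
        if c not in ("method", "sample") and pd.api.types.is_numeric_dtype(summaries[c])
    ]
    out[value_cols] = out[value_cols].astype(float)
    for _, idx in summaries.groupby("sample").groups.items():
        block = out.loc[idx, value_cols].astype(float)
        mean, std = block.mean(axis=0), block.std(axis=0, ddof=0)
        std = std.replace(0.0, np.nan)
        z = (block - mean) / std
        out.loc[idx, value_cols] = z.fillna(0.0)
    return out


def flag_failures(
    summaries: pd.DataFrame, thresholds: FailureThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the three failure rules for every method x sample.

    Returns a long-format frame with columns method, sample, flag,
    comparator (the witnessing method for rules 1 and 3; '' for rule 2).
    Any other method on the same sample can witness; a method-sample can
    carry several flags.
    """
    th = thresholds or FailureThresholds()
    records = []
    for sample, block in summaries.groupby("sample"):
        for _, row in block.iterrows():
            others = block[block["method"] != row["method"]]
            if row["n_retained"] < th.low_count:
                for _, other in others.iterrows():
                    if other["n_retained"] <= th.low_count_ratio * row["n_retained"]:
                        continue
                    diff = abs(other["mean_fraction_unspliced"] - row["mean_fraction_unspliced"])
                    margin = th.low_count_unspliced_margin
                    if th.margin_mode == "relative":
                        margin = margin * abs(other["mean_fraction_unspliced"])
                    if diff <= margin:
                        records.append(
                            (row["method"], sample, "low_nuclei_count", other["method"])
                        )
                        break
            if row["n_retained"] > th.high_count:
                records.append((row["method"], sample, "high_nuclei_count", ""))
            if row["median_fraction_unspliced"] < th.quality_floor:
                for _, other in others.iterrows():
                    if (
                        other["n_retained"] > row["n_retained"]
                        and other["median_fraction_unspliced"]
                        >= row["median_fraction_unspliced"] + th.quality_margin
                    ):
                        records.append((row["method"], sample, "low_quality", other["method"]))
                        break
    return pd.DataFrame(records, columns=["method", "sample", "flag", "comparator"])
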