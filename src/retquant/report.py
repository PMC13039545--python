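"""Aggregation of per-run metrics into group summary tables.

Mirrors how per-animal metrics are presented: per group, the mean, the
standard error of the mean, the number of subjects, and the individual
values. No inferential statistics are computed here.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd


def summarize(values_by_group: dict[str, list[float]]) -> pd.DataFrame:
    """Group means with sem and individual values.

    sem is blank (NaN) for single-subject groups, where it is undefined.
    """
    rows = []
    for group, values in values_by_group.items():
        n = len(values)
        if n == 0:
            continue
        mean = sum(values) / n
        if n > 1:
            var = sum((v - mean) ** 2 for v in values) / (n - 1)
            sem = math.sqrt(var / n)
        else:
            sem = float("nan")
        rows.append(
            {
                "group": group,
                "mean": mean,
                "sem": sem,
                "n": n,
                "values": ";".join(f"{v:.6g}" for v in values),
            }
        )
    return pd.DataFrame(rows, columns=["group", "mean", "sem", "n", "values"])


def collect_runs(run_dirs, metric_file: str, metric: str, group_key: str = "group"
                 ) -> pd.DataFrame:
    """Gather one metric from completed run directories into group summaries.

    Each run directory must contain ``metric_file`` (a one-row CSV of
    metrics, with a ``group`` column when runs span several groups); runs
    whose metric files carry different column sets are rejected as
    incompatible stages.
    """
    run_dirs = [Path(d) for d in run_dirs]
    if not run_dirs:
        raise ValueError("need at least one completed run")
    frames = []
    columns = None
    for d in run_dirs:
        f = d / metric_file
        if not f.exists():
            raise FileNotFoundError(f"run {d} has no {metric_file}")
        df = pd.read_csv(f)
        if columns is None:
            columns = set(df.columns)
        elif set(df.columns) != columns:
            raise ValueError(f"run {d} metrics are incompatible with the others")
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)
    if metric not in allrows.columns:
        raise KeyError(f"metric {metric!r} not present in {metric_file}")
    if group_key in allrows.columns:
        grouped = {
            str(g): list(sub[metric].astype(float)) for g, sub in allrows.groupby(group_key)
        }
    else:
        grouped = {"all": list(allrows[metric].astype(float))}
    return summarize(grouped)
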