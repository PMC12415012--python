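"""Packaged reference tables from the published group analysis.

The original study's per-subject correlation matrices and group edge lists
are not redistributable, but its per-node results are: for each of the four
executive tasks, the per-node degree, strength, betweenness and closeness
of the group graph, the degree distribution, and the table of nodes absent
from at least one task. These are shipped as package data and drive the
classification and statistics stages without any raw data.

Node counts per task: initiation 55, inhibition 78, shifting 57, 2-back 54.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import TASKS, normalize_task

METRICS = ("degree", "strength", "betweenness", "closeness")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("efconn").joinpath(f"data/reference/{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_fixture(metric: str, task: str) -> pd.DataFrame:
    """Reference (roi_id, value) table for one metric and task."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    task = normalize_task(task)
    df = _read(metric)
    out = df.loc[df["task"] == task, ["roi_id", "value"]].reset_index(drop=True)
    if out["roi_id"].duplicated().any():
        raise ValueError(f"corrupt reference table {metric}/{task}: duplicate ids")
    return out


def load_metric_table(metric: str) -> pd.DataFrame:
    """Full reference table for one metric: columns task, roi_id, value."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return _read(metric)


def load_degree_distribution(task: str) -> pd.DataFrame:
    """Published degree distribution: columns degree, fraction."""
    task = normalize_task(task)
    df = _read("degree_distribution")
    return df.loc[df["task"] == task, ["degree", "fraction"]].reset_index(drop=True)


def load_distinct_nodes() -> pd.DataFrame:
    """Published table of nodes absent from at least one task graph.

    Columns: roi_id plus one degree column per task (NaN = absent). Shipped
    as printed; three shifting rows (167, 169, 175) are inconsistent with
    the shifting degree table and are documented, not corrected.
    """
    return _read("distinct_nodes")


def fixture_node_sets() -> dict[str, set[int]]:
    df = _read("strength")
    return {t: set(df.loc[df["task"] == t, "roi_id"].astype(int)) for t in TASKS}
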