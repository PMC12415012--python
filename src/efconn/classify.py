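"""Hub and influencer classification, and cross-task node comparison.

A *hub* is a node in the top 20% of both strength and betweenness within
its own task graph; an *influencer* is a node in the top 20% of expected
force. The 20% denominator is the number of nodes in that task's graph,
k = ceil(q·n), and the cutoff is tie-inclusive: every node at or above the
k-th largest value is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TASKS

DEFAULT_TOP_FRACTION = 0.20


def top_fraction(scores: Mapping, q: float = DEFAULT_TOP_FRACTION) -> set:
    """Nodes whose score reaches the k-th largest value, k = ceil(q·n)."""
    if not scores:
        raise ValueError("cannot take the top fraction of an empty score map")
    if not 0 < q <= 1:
        raise ValueError(f"q must lie in (0, 1], got {q}")
    values = sorted(scores.values(), reverse=True)
    k = math.ceil(q * len(values))
    cutoff = values[k - 1]
    return {node for node, v in scores.items() if v >= cutoff}


def _cutoff(scores: Mapping, q: float) -> float:
    values = sorted(scores.values(), reverse=True)
    return values[math.ceil(q * len(values)) - 1]


@dataclass
class HubSet:
    task: "str | None"
    members: set
    strength_cutoff: float
    betweenness_cutoff: float
    q: float


@dataclass
class InfluencerSet:
    task: "str | None"
    members: set
    exf_cutoff: float
    q: float


def classify_hubs(metrics: pd.DataFrame, q: float = DEFAULT_TOP_FRACTION,
                  task: "str | None" = None) -> HubSet:
    """Top-q strength ∩ top-q betweenness of one task's node-metric table."""
    strength = metrics["strength"].to_dict()
    betw = metrics["betweenness"].to_dict()
    members = top_fraction(strength, q) & top_fraction(betw, q)
    return HubSet(task, members, _cutoff(strength, q), _cutoff(betw, q), q)


def classify_influencers(exf: pd.DataFrame, q: float = DEFAULT_TOP_FRACTION,
                         task: "str | None" = None) -> InfluencerSet:
    """Top-q expected force (columns roi_id, expected_force)."""
    scores = dict(zip(exf["roi_id"], exf["expected_force"]))
    return InfluencerSet(task, top_fraction(scores, q), _cutoff(scores, q), q)


@dataclass
class CrossTaskComparison:
    shared_hubs: set
    shared_nodes: set
    distinct_nodes: pd.DataFrame  # roi_id + per-task degree (NaN = absent)


def cross_task_compare(metrics_by_task: Mapping[str, pd.DataFrame],
                       hubs_by_task: Mapping[str, HubSet]) -> CrossTaskComparison:
    """Shared hubs/nodes across tasks and the table of non-shared nodes.

    ``distinct_nodes`` lists every node absent from at least one task with
    its per-task degree (NaN marks absence), mirroring the published
    distinct-node table.
    """
    if len(metrics_by_task) < 2:
        raise ValueError("cross-task comparison needs at least 2 tasks")
    tasks = [t for t in TASKS if t in metrics_by_task] or list(metrics_by_task)
    node_sets = {t: set(metrics_by_task[t].index) for t in tasks}
    shared_nodes = set.intersection(*node_sets.values())
    shared_hubs = set.intersection(*(hubs_by_task[t].members for t in tasks
                                     if t in hubs_by_task))
    all_nodes = set.union(*node_sets.values())
    distinct = sorted(all_nodes - shared_nodes)
    rows = []
    for node in distinct:
        row = {"roi_id": node}
        for t in tasks:
            row[t] = (float(metrics_by_task[t].loc[node, "degree"])
                      if node in node_sets[t] else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["roi_id"] + tasks)
    return CrossTaskComparison(shared_hubs, shared_nodes, df)
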