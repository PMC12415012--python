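"""Synthetic multi-subject correlation cohorts with planted structure.

The generator emulates the *input* of the group-graph pipeline: one
symmetric correlation matrix per subject, for a 200-ROI / 17-network
atlas, such that after thresholding (r > 0.75), aggregation over ~144
subjects and the ≥10-participant edge filter, the group graph has planted
modules, planted cross-module hub nodes, weights spanning ~10–100+, sparse
density (~0.04) and near-zero transitivity — the regime of the real task
graphs.

Topology of the planted structure: each of the K modules is a circulant
lattice C(1, 3) — every member tied to its neighbours at distance 1 and 3
around a ring, giving a cohesive, triangle-free block of degree 4; each
hub gets three edges into a home module and five spread over the other
modules, making hubs the only inter-module connectors (high strength
*and* high betweenness, structurally separated from module members).
Correlations are sampled per pair — a suprathreshold pair draws from
``r_high`` (entirely above the threshold), any other from ``r_low``
(entirely below). Matrix-wide positive-definiteness is deliberately not
enforced: the pipeline consumes only elementwise threshold exceedances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import atlas as atlas_mod
from .atlas import AtlasTable, build_atlas_table, excluded_rois
from .io import SubjectConnectome


def make_synthetic_atlas(n_roi: int = 200) -> AtlasTable:
    """A Schaefer-style label table: LH ids 1..n/2, RH above, 17 networks."""
    if n_roi % 2:
        raise ValueError("n_roi must be even (two hemispheres)")
    nets = atlas_mod.SCHAEFER17_NETWORKS
    labels = []
    for hemi in ("LH", "RH"):
        counters: dict[str, int] = {}
        for k in range(n_roi // 2):
            net = nets[k % len(nets)]
            counters[net] = counters.get(net, 0) + 1
            labels.append(f"{hemi}_{net}_ROI_{counters[net]}")
    return build_atlas_table(labels)


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated cohort."""

    n_subjects: int = 144
    n_roi: int = 200
    n_modules: int = 5
    module_size: int = 12
    n_hubs: int = 6
    p_within: float = 0.6
    p_hub: float = 0.5
    p_background: float = 0.005
    r_high: tuple = (0.76, 0.95)
    r_low: tuple = (0.0, 0.70)
    r_threshold: float = 0.75
    excluded_networks: frozenset = field(
        default=atlas_mod.DEFAULT_EXCLUDED_NETWORKS)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_within", "p_hub", "p_background"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not self.r_high[0] > self.r_threshold:
            raise ValueError("r_high must lie entirely above the threshold")
        if not self.r_low[1] <= self.r_threshold:
            raise ValueError("r_low must lie entirely below the threshold")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    partition: dict            # roi_id -> module id (hubs get their home)
    hubs: set
    planted_edges: list        # (roi_i, roi_j, per-subject probability)
    atlas: AtlasTable


def _plant_structure(spec: SyntheticSpec, rng: np.random.Generator,
                     atlas: AtlasTable) -> GroundTruth:
    excl = excluded_rois(atlas, spec.excluded_networks)
    included = sorted(set(range(1, spec.n_roi + 1)) - excl)
    need = spec.n_modules * spec.module_size + spec.n_hubs
    if need > len(included):
        raise ValueError(f"planted structure needs {need} included ROIs, "
                         f"atlas provides {len(included)}")
    chosen = rng.choice(included, size=need, replace=False)
    partition: dict[int, int] = {}
    modules: list[list[int]] = []
    pos = 0
    for k in range(spec.n_modules):
        members = [int(r) for r in chosen[pos:pos + spec.module_size]]
        pos += spec.module_size
        modules.append(members)
        for r in members:
            partition[r] = k
    hubs = [int(r) for r in chosen[pos:]]

    edges: list[tuple[int, int, float]] = []
    for members in modules:
        # circulant lattice C_n(1, 3): degree 4, cohesive, triangle-free
        size = len(members)
        for step in (1, 3):
            if 2 * step > size:
                continue
            for a in range(size):
                u, v = members[a], members[(a + step) % size]
                edges.append((min(u, v), max(u, v), spec.p_within))
    # each module node receives at most one hub edge while slots last, so
    # hub strength (8 edges) separates cleanly from attachment nodes (4+1)
    pools = {k: list(members) for k, members in enumerate(modules)}

    def take(k: int) -> int:
        if not pools[k]:
            pools[k] = list(modules[k])
        return int(pools[k].pop(int(rng.integers(len(pools[k])))))

    for h_idx, h in enumerate(hubs):
        home = h_idx % spec.n_modules
        partition[h] = home
        targets = [take(home) for _ in range(min(3, spec.module_size))]
        others = [k for k in range(spec.n_modules) if k != home]
        for slot, k in enumerate(others):
            n_cross = 2 if slot == h_idx % max(len(others), 1) else 1
            targets.extend(take(k) for _ in range(n_cross))
        for t in targets:
            edges.append((min(h, t), max(h, t), spec.p_hub))
    edges = sorted(set(edges))
    bad = [e for e in edges if e[0] in excl or e[1] in excl]
    if bad:
        raise ValueError(f"planted edges touch excluded ROIs: {bad[:3]}")
    return GroundTruth(partition, set(hubs), edges, atlas)


def generate_cohort(spec: SyntheticSpec, task: str = "initiation",
                    ) -> tuple[list[SubjectConnectome], GroundTruth]:
    """Simulate one cohort (one task): per-subject correlation matrices."""
    rng = np.random.default_rng(spec.seed)
    atlas = make_synthetic_atlas(spec.n_roi)
    truth = _plant_structure(spec, rng, atlas)
    n = spec.n_roi
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    planted_idx = np.array(
        [(i - 1) * n + (j - 1) for i, j, _ in truth.planted_edges])
    flat_of_pair = iu[0] * n + iu[1]
    pos_in_upper = np.searchsorted(flat_of_pair, planted_idx)
    planted_p = np.array([p for _, _, p in truth.planted_edges])

    cohort = []
    for s in range(spec.n_subjects):
        vals = rng.uniform(spec.r_low[0], spec.r_low[1], size=n_pairs)
        hot = rng.random(n_pairs) < spec.p_background
        hot[pos_in_upper] = rng.random(planted_p.size) < planted_p
        vals[hot] = rng.uniform(spec.r_high[0], spec.r_high[1],
                                size=int(hot.sum()))
        m = np.zeros((n, n))
        m[iu] = vals
        m = m + m.T
        np.fill_diagonal(m, 1.0)
        cohort.append(SubjectConnectome(f"sub-{s + 1:03d}", task, m))
    return cohort, truth


@dataclass
class RecoveryReport:
    hub_precision: float
    hub_recall: float
    partition_ari: float
    edge_density: float


def recovery_report(graph: nx.Graph, detected_hubs: set,
                    partition, truth: GroundTruth) -> RecoveryReport:
    """Score pipeline outputs against the planted ground truth.

    ``partition`` is a CommunityPartition over the group graph's nodes;
    the ARI is computed on the detected nodes that carry a planted module
    label.
    """
    planted = truth.hubs
    tp = len(detected_hubs & planted)
    precision = tp / len(detected_hubs) if detected_hubs else 0.0
    recall = tp / len(planted) if planted else 1.0
    common = [nd for nd in graph.nodes if nd in truth.partition
              and nd in partition.mapping]
    if common:
        ari = float(adjusted_rand_score(
            [truth.partition[nd] for nd in common],
            [partition.mapping[nd] for nd in common]))
    else:
        ari = float("nan")
    return RecoveryReport(precision, recall, ari, float(nx.density(graph)))
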