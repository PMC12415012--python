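"""End-to-end orchestration: cohorts -> graphs -> metrics -> stats -> tables.

``run_pipeline`` executes the full analysis for each task from a config
mapping (or YAML file): build the group graph (from a directory of subject
matrices, or from the synthetic generator), compute node metrics, expected
force, communities (Louvain + divisive edge betweenness), global metrics
against a seeded random reference, classify hubs/influencers, then compare
tasks (shared/distinct nodes, Kruskal–Wallis and pairwise Wilcoxon on
shared-ROI strengths, KS vs null degrees). All randomness flows from one
root seed; rerunning a config is bit-for-bit reproducible.

``reanalyze_reference_tables`` is the no-raw-data mode: it recomputes the
classification and statistics stages directly from the packaged per-node
reference tables of the published analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import classify as classify_mod
from . import communities as comm_mod
from . import global_metrics as gm_mod
from . import metrics as metrics_mod
from . import reference
from . import stats as stats_mod
from . import synthetic as synth_mod
from .atlas import DEFAULT_EXCLUDED_NETWORKS, excluded_rois, load_atlas
from .graphs import build_from_cohort
from .influence import expected_force
from .io import TASKS, normalize_task, read_subject_matrix, write_graph

DEFAULT_CONFIG = {
    "r_threshold": 0.75,
    "min_subjects": 10,
    "excluded_networks": sorted(DEFAULT_EXCLUDED_NETWORKS),
    "q": 0.20,
    "path_scheme": "binary",
    "weighted_exf": True,
    "null_model": "er_gnm",
    "replicates": 100,
    "seed": 0,
    "tasks": list(TASKS),
}


@dataclass
class TaskResult:
    task: str
    graph: nx.Graph
    node_metrics: pd.DataFrame
    exf: pd.DataFrame
    global_metrics: gm_mod.GlobalMetricsTable
    louvain: comm_mod.CommunityPartition
    edge_betweenness: comm_mod.CommunityPartition
    dendrogram: comm_mod.Dendrogram
    hubs: classify_mod.HubSet
    influencers: classify_mod.InfluencerSet
    truth: "synth_mod.GroundTruth | None" = None


@dataclass
class ReportBundle:
    tasks: dict = field(default_factory=dict)      # task -> TaskResult
    cross: "classify_mod.CrossTaskComparison | None" = None
    kruskal: "stats_mod.TestResult | None" = None
    wilcoxon: "stats_mod.PairwiseResult | None" = None
    ks: dict = field(default_factory=dict)         # task -> TestResult
    config: dict = field(default_factory=dict)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = dict(DEFAULT_CONFIG)
    merged.update(config or {})
    if "input_dir" not in merged and "simulate" not in merged:
        raise ValueError("config must name either 'input_dir' (with 'atlas') "
                         "or a 'simulate' block")
    if "input_dir" in merged and "atlas" not in merged:
        raise ValueError("config with 'input_dir' is missing key 'atlas'")
    return merged


def _task_seed(root_seed: int, index: int) -> int:
    return int(np.random.default_rng([root_seed, index]).integers(2**31))


def _load_task_cohort(cfg: dict, task: str):
    d = Path(cfg["input_dir"])
    files = sorted(d.glob(f"{task}_*.csv")) + sorted(d.glob(f"{task}_*.tsv"))
    if not files:
        raise FileNotFoundError(f"no matrix files for task {task!r} in {d}")
    return [read_subject_matrix(f, task, f.stem.split("_", 1)[1])
            for f in files]


def analyze_task_graph(graph: nx.Graph, cfg: "dict | None" = None,
                       seed: "int | None" = None,
                       truth=None) -> TaskResult:
    """All single-task analyses on an already-built group graph."""
    cfg = {**DEFAULT_CONFIG, **(cfg or {})}
    seed = cfg["seed"] if seed is None else seed
    task = graph.graph.get("task")
    nm = metrics_mod.compute_node_metrics(graph, cfg["path_scheme"])
    exf = expected_force(graph, weighted=cfg["weighted_exf"])
    louv = comm_mod.louvain(graph, seed=seed)
    dendro, ebc = comm_mod.edge_betweenness_communities(graph)
    ref = gm_mod.random_reference(graph.number_of_nodes(),
                                  graph.number_of_edges(),
                                  replicates=cfg["replicates"], seed=seed,
                                  model="er_gnm")
    gmt = gm_mod.global_metrics(graph, louv, ref, cfg["path_scheme"])
    hubs = classify_mod.classify_hubs(nm, cfg["q"], task=task)
    infl = classify_mod.classify_influencers(exf, cfg["q"], task=task)
    return TaskResult(task, graph, nm, exf, gmt, louv, ebc, dendro,
                      hubs, infl, truth)


def run_pipeline(config) -> ReportBundle:
    """Execute the full multi-task analysis described by ``config``."""
    cfg = _load_config(config)
    bundle = ReportBundle(config=cfg)
    tasks = [normalize_task(t) for t in cfg["tasks"]]
    for idx, task in enumerate(tasks):
        seed = _task_seed(cfg["seed"], idx)
        truth = None
        if "simulate" in cfg:
            spec = synth_mod.SyntheticSpec(**{**cfg["simulate"], "seed": seed})
            cohort, truth = synth_mod.generate_cohort(spec, task)
            excl = excluded_rois(truth.atlas, spec.excluded_networks)
        else:
            cohort = _load_task_cohort(cfg, task)
            atlas = load_atlas(cfg["atlas"])
            excl = excluded_rois(atlas, set(cfg["excluded_networks"]))
        graph = build_from_cohort(cohort, excl, cfg["r_threshold"],
                                  cfg["min_subjects"], task)
        bundle.tasks[task] = analyze_task_graph(graph, cfg, seed, truth)
        bundle.ks[task] = stats_mod.ks_degree_vs_random(
            graph, cfg["null_model"], replicates=20, seed=seed)
    if len(tasks) >= 2:
        metrics_by_task = {t: r.node_metrics for t, r in bundle.tasks.items()}
        hubs_by_task = {t: r.hubs for t, r in bundle.tasks.items()}
        bundle.cross = classify_mod.cross_task_compare(metrics_by_task,
                                                       hubs_by_task)
        shared = sorted(bundle.cross.shared_nodes)
        if shared:
            groups = {t: [float(bundle.tasks[t].node_metrics.loc[n, "strength"])
                          for n in shared] for t in tasks}
            bundle.kruskal = stats_mod.kruskal_wallis(groups)
            bundle.wilcoxon = stats_mod.pairwise_wilcoxon(groups)
    return bundle


def export_tables(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write every result table as CSV/JSON/GraphML under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    for task, res in bundle.tasks.items():
        write_graph(res.graph, out / f"{task}_graph.graphml")
        written.append(out / f"{task}_graph.graphml")
        nm = res.node_metrics.reset_index()
        save(nm.sort_values("strength", ascending=False),
             f"{task}_node_metrics.csv")
        save(res.exf, f"{task}_expected_force.csv")
        save(metrics_mod.degree_distribution(res.graph),
             f"{task}_degree_distribution.csv")
        save(pd.DataFrame(sorted(res.louvain.mapping.items()),
                          columns=["roi_id", "community"]),
             f"{task}_louvain_communities.csv")
        save(pd.DataFrame(sorted(res.edge_betweenness.mapping.items()),
                          columns=["roi_id", "community"]),
             f"{task}_edge_betweenness_communities.csv")
        (out / f"{task}_dendrogram.json").write_text(
            json.dumps(res.dendrogram.records(), indent=1))
        written.append(out / f"{task}_dendrogram.json")
        save(pd.DataFrame({"roi_id": sorted(res.hubs.members)}),
             f"{task}_hubs.csv")
        save(pd.DataFrame({"roi_id": sorted(res.influencers.members)}),
             f"{task}_influencers.csv")
        gm = {k: (None if isinstance(v, float) and math.isnan(v) else v)
              for k, v in res.global_metrics.as_dict().items()}
        meta = {"task": task, "global_metrics": gm,
                "n_nodes": res.graph.number_of_nodes(),
                "n_edges": res.graph.number_of_edges(),
                "config": {k: v for k, v in bundle.config.items()
                           if k not in ("tasks",)}}
        (out / f"{task}_global_metrics.json").write_text(
            json.dumps(meta, indent=1, default=str))
        written.append(out / f"{task}_global_metrics.json")
    if bundle.cross is not None:
        save(bundle.cross.distinct_nodes, "distinct_nodes.csv")
        save(pd.DataFrame({"roi_id": sorted(bundle.cross.shared_hubs)}),
             "shared_hubs.csv")
    stats_report = {}
    if bundle.kruskal:
        stats_report["kruskal_wallis"] = vars(bundle.kruskal)
    if bundle.wilcoxon is not None:
        stats_report["pairwise_wilcoxon"] = {
            "adjust_method": bundle.wilcoxon.adjust_method,
            "adjusted": bundle.wilcoxon.adjusted.to_dict(),
            "raw": bundle.wilcoxon.raw.to_dict(),
        }
    stats_report["ks_degree_vs_random"] = {t: vars(r)
                                           for t, r in bundle.ks.items()}
    (out / "stats.json").write_text(json.dumps(stats_report, indent=1,
                                               default=str))
    written.append(out / "stats.json")
    return written


def reanalyze_reference_tables(q: float = 0.20,
                               adjust: str = stats_mod.DEFAULT_ADJUST) -> dict:
    """Classification + statistics recomputed from the packaged tables.

    Returns degree distributions, per-task hub sets, the shared hub set,
    influencer-set cardinalities implied by the top-20% rule, and the
    cross-task strength statistics, all derived from the published
    per-node tables rather than from raw data.
    """
    out: dict = {"degree_distribution": {}, "hubs": {}, "top_k": {}}
    metrics_by_task: dict[str, pd.DataFrame] = {}
    for task in TASKS:
        deg = reference.load_fixture("degree", task)
        out["degree_distribution"][task] = metrics_mod.degree_distribution(
            deg["value"])
        df = pd.DataFrame({
            "degree": reference.load_fixture("degree", task)
            .set_index("roi_id")["value"],
            "strength": reference.load_fixture("strength", task)
            .set_index("roi_id")["value"],
            "betweenness": reference.load_fixture("betweenness", task)
            .set_index("roi_id")["value"],
            "closeness": reference.load_fixture("closeness", task)
            .set_index("roi_id")["value"],
        })
        df.index.name = "roi_id"
        metrics_by_task[task] = df
        out["hubs"][task] = classify_mod.classify_hubs(df, q, task=task)
        out["top_k"][task] = math.ceil(q * len(df))
    hubs = {t: out["hubs"][t] for t in TASKS}
    out["cross"] = classify_mod.cross_task_compare(metrics_by_task, hubs)
    shared = sorted(out["cross"].shared_nodes)
    groups = {t: [float(metrics_by_task[t].loc[n, "strength"])
                  for n in shared] for t in TASKS}
    out["shared_strength_groups"] = groups
    out["kruskal"] = stats_mod.kruskal_wallis(groups)
    out["wilcoxon"] = stats_mod.pairwise_wilcoxon(groups, adjust=adjust)
    return out
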