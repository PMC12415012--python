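#!/usr/bin/env python
"""Run the full pipeline end-to-end on a simulated four-task cohort.

Simulates 144 subjects x 4 tasks under the default synthetic conditions
(5 planted modules, 6 planted hub connectors per task, r > 0.75 threshold,
>= 10-participant edge filter), then computes everything the analysis
produces per task: group graph, node metrics, expected force, Louvain and
divisive edge-betweenness communities, global metrics vs a seeded G(n, m)
reference, hub/influencer sets, cross-task comparison and statistics.
All outputs land in results/synthetic/.
"""

from pathlib import Path

from efconn.io import TASKS
from efconn.pipeline import export_tables, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

bundle = run_pipeline({"simulate": {}, "seed": 0, "replicates": 100})
export_tables(bundle, OUT)

for task in TASKS:
    res = bundle.tasks[task]
    g = res.graph
    gm = res.global_metrics
    print(f"{task:11s} n={g.number_of_nodes():3d} m={g.number_of_edges():3d} "
          f"density={gm.edge_density:.3f} Q={gm.modularity:.3f} "
          f"L={gm.char_path_length:.2f} E={gm.global_efficiency:.3f} "
          f"sigma={gm.small_world_sigma:.2f} "
          f"communities={res.louvain.n_communities} "
          f"hubs={sorted(res.hubs.members)}")

kw = bundle.kruskal
print(f"\nshared nodes across tasks: {len(bundle.cross.shared_nodes)}; "
      f"shared hubs: {sorted(bundle.cross.shared_hubs)}")
print(f"KW on shared-node strengths: chi2={kw.statistic:.3f} "
      f"df={kw.df} p={kw.p_value:.3g}")
print(f"wrote per-task tables, graphs and stats to {OUT}")
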