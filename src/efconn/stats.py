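"""Cross-task nonparametric statistics.

Three comparisons are used on the group graphs:

* Kruskal–Wallis on the strengths of the ROIs present in all four task
  graphs (tie-corrected H, chi-squared approximation, df = groups − 1);
* pairwise two-sided Wilcoxon rank-sum tests (normal approximation with
  tie and continuity correction) with familywise-error adjustment —
  Bonferroni by default, which reproduces the published pairwise table;
  Holm and unadjusted are available;
* two-sample Kolmogorov–Smirnov between a graph's degree sequence and the
  pooled degree sequence of seeded null-model replicates with matched
  n and m.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = ("holm", "bonferroni", "none")
DEFAULT_ADJUST = "bonferroni"


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: "int | None" = None


@dataclass
class PairwiseResult:
    """Lower-triangular matrix of adjusted p-values, plus the raw ones."""

    adjusted: pd.DataFrame
    raw: pd.DataFrame
    adjust_method: str

    def p(self, a: str, b: str) -> float:
        m = self.adjusted
        if a in m.index and b in m.columns and not np.isnan(m.loc[a, b]):
            return float(m.loc[a, b])
        return float(m.loc[b, a])


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H across ≥2 named groups."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays.append(vals)
    h, p = ss.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), len(arrays) - 1)


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approx., ties + continuity)."""
    return float(ss.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue)


def pairwise_wilcoxon(groups: Mapping[str, Sequence[float]],
                      adjust: str = DEFAULT_ADJUST) -> PairwiseResult:
    """All pairwise rank-sum tests with familywise adjustment."""
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"unknown adjust method {adjust!r}; "
                         f"expected one of {ADJUST_METHODS}")
    if len(groups) < 2:
        raise ValueError("pairwise comparison needs at least 2 groups")
    names = list(groups)
    pairs = list(combinations(names, 2))
    raw = [rank_sum_p(groups[a], groups[b]) for a, b in pairs]
    if adjust == "none":
        adj = list(raw)
    else:
        adj = list(multipletests(raw, method=adjust)[1])
    raw_m = pd.DataFrame(np.nan, index=names, columns=names)
    adj_m = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), pr, pa in zip(pairs, raw, adj):
        raw_m.loc[b, a] = pr
        adj_m.loc[b, a] = pa
    return PairwiseResult(adj_m, raw_m, adjust)


NULL_MODELS = ("er_gnm", "configuration")


def ks_degree_vs_random(graph: nx.Graph, null: str = "er_gnm",
                        replicates: int = 20, seed: int = 0) -> TestResult:
    """KS test of the degree sequence against pooled null-model degrees."""
    if null not in NULL_MODELS:
        raise ValueError(f"unknown null model {null!r}; "
                         f"expected one of {NULL_MODELS}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    observed = np.array([d for _, d in graph.degree], dtype=float)
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(replicates):
        rseed = int(rng.integers(2**31))
        if null == "er_gnm":
            g = nx.gnm_random_graph(n, m, seed=rseed)
        else:
            g = nx.Graph(nx.configuration_model(
                [int(d) for d in observed], seed=rseed))
            g.remove_edges_from(nx.selfloop_edges(g))
        pooled.extend(d for _, d in g.degree)
    d, p = ss.ks_2samp(observed, np.asarray(pooled, dtype=float))
    return TestResult(f"ks_degree_vs_{null}", float(d), float(p))


def kw_type1_error(n_groups: int = 4, n_per_group: int = 48,
                   n_sims: int = 1000, alpha: float = 0.05,
                   seed: int = 0) -> float:
    """Empirical type-I error of the KW test under i.i.d. null groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        samples = rng.standard_normal((n_groups, n_per_group))
        _, p = ss.kruskal(*samples)
        if p < alpha:
            rejections += 1
    return rejections / n_sims
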