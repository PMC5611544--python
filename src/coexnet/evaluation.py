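"""Data-driven evaluation of a density-threshold sweep.

Four criteria are computed per density threshold so a T_d can be chosen
from the data rather than ad hoc: (1) the number of clusters of size >= 3,
(2) the fraction of network genes inside clusters, (3) the distribution of
per-cluster average segregation, and (4) the extent of gene-set enrichment
among clusters (at q < 0.1).

Average segregation of a cluster c is the ratio of the mean weight of
edges internal to c to the mean weight of all distinct edges incident on
members of c (internal edges included in the incident set):

    seg(c) = mean(w : (u,v), u,v in c) / mean(w : (u,v), u in c or v in c)

An isolated clique — all incident edges internal — scores exactly 1;
values above 1 indicate internal edges outweigh the surroundings. The
incident-edge sum could alternatively be read as summing over members (so
internal edges count twice); the distinct-edge convention used here is the
one under which the isolated-clique case equals exactly 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .enrichment import GeneSetCollection, annotate_clusters

__all__ = [
    "average_segregation",
    "notch_bounds",
    "SweepMetrics",
    "evaluate_sweep",
    "plot_sweep",
]


def average_segregation(network: nx.Graph, cluster: Iterable[str]) -> float:
    """Modularity ratio of a cluster; NaN when it has no internal edges."""
    members = set(cluster)
    internal = [w for _, _, w in network.subgraph(members).edges(data="weight")]
    if not internal:
        warnings.warn("cluster has no internal edges; segregation undefined")
        return float("nan")
    incident: dict[frozenset, float] = {}
    for u in members:
        for v, data in network.adj[u].items():
            incident[frozenset((u, v))] = data["weight"]
    return (sum(internal) / len(internal)) / (sum(incident.values()) / len(incident))


def notch_bounds(values: np.ndarray) -> tuple[float, float]:
    """Median +/- 1.58*IQR/sqrt(n) — the box-plot notch interval, a rough
    95% CI for the median."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (float("nan"), float("nan"))
    med = float(np.median(values))
    q1, q3 = np.percentile(values, [25, 75])
    half = 1.58 * (q3 - q1) / math.sqrt(values.size)
    return (med - half, med + half)


@dataclass
class SweepMetrics:
    """Per-threshold sweep statistics plus the underlying distributions."""

    table: pd.DataFrame
    segregation: dict[float, np.ndarray]
    es: dict[float, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _summary(values: np.ndarray, prefix: str) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        nan = float("nan")
        return {f"{prefix}_median": nan, f"{prefix}_q1": nan, f"{prefix}_q3": nan,
                f"{prefix}_notch_lo": nan, f"{prefix}_notch_hi": nan}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    lo, hi = notch_bounds(values)
    return {f"{prefix}_median": med, f"{prefix}_q1": q1, f"{prefix}_q3": q3,
            f"{prefix}_notch_lo": lo, f"{prefix}_notch_hi": hi}


def evaluate_sweep(sweep: Mapping[float, ClusterSet],
                   network: nx.Graph,
                   genesets: GeneSetCollection,
                   *, q_threshold: float = 0.1) -> SweepMetrics:
    """Score every ClusterSet of a T_d sweep by the four criteria.

    ``genesets`` should already be restricted to specific sets (the sweep
    preset keeps sets annotating < 500 genes). Enrichment counts clusters
    and distinct sets with at least one pair at q < ``q_threshold``; the ES
    distribution records each enriched cluster's best score. Pure: the same
    sweep always yields the same table.
    """
    n_nodes = network.number_of_nodes()
    universe = frozenset(network.nodes)
    rows = []
    seg_dist: dict[float, np.ndarray] = {}
    es_dist: dict[float, np.ndarray] = {}
    for t_d, clusters in sweep.items():
        seg = np.array([average_segregation(network, c)
                        for c in clusters.clusters], dtype=float)
        seg_dist[t_d] = seg
        if len(clusters):
            enr = annotate_clusters(clusters, genesets, universe=universe)
            sig = enr[enr["q"] < q_threshold]
            n_enriched_clusters = sig["cluster_id"].nunique()
            n_distinct_sets = sig["set_name"].nunique()
            es = sig.groupby("cluster_id")["es"].max().to_numpy(dtype=float)
        else:
            n_enriched_clusters = n_distinct_sets = 0
            es = np.array([], dtype=float)
        es_dist[t_d] = es
        row = {
            "t_d": t_d,
            "n_clusters": len(clusters),
            "gene_fraction": clusters.n_clustered / n_nodes if n_nodes else 0.0,
            "n_enriched_clusters": n_enriched_clusters,
            "n_distinct_enriched_sets": n_distinct_sets,
        }
        row.update(_summary(seg, "seg"))
        row.update(_summary(es, "es"))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("t_d").reset_index(drop=True)
    return SweepMetrics(table, seg_dist, es_dist)


def plot_sweep(metrics: SweepMetrics, path) -> None:
    """Four-panel summary of the sweep (counts/fraction, segregation
    box plots, enrichment counts, ES box plots)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = metrics.table
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    ax = axes[0, 0]
    ax.plot(table["t_d"], table["n_clusters"], "o-", color="tab:blue")
    ax.set_xlabel("T_d"); ax.set_ylabel("clusters (size >= 3)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(table["t_d"], table["gene_fraction"], "s--", color="tab:red")
    ax2.set_ylabel("fraction of genes clustered", color="tab:red")

    ax = axes[0, 1]
    tds = sorted(metrics.segregation)
    data = [metrics.segregation[t][~np.isnan(metrics.segregation[t])] for t in tds]
    ax.boxplot(data, tick_labels=[f"{t:g}" for t in tds], notch=True,
               showfliers=False)
    ax.set_xlabel("T_d"); ax.set_ylabel("average segregation")

    ax = axes[1, 0]
    ax.plot(table["t_d"], table["n_enriched_clusters"], "o-", color="tab:blue")
    ax.set_xlabel("T_d"); ax.set_ylabel("enriched clusters", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(table["t_d"], table["n_distinct_enriched_sets"], "s--",
             color="tab:red")
    ax2.set_ylabel("distinct enriched sets", color="tab:red")

    ax = axes[1, 1]
    data = [metrics.es[t] for t in tds]
    if any(len(d) for d in data):
        ax.boxplot(data, tick_labels=[f"{t:g}" for t in tds], showfliers=False)
    ax.set_xlabel("T_d"); ax.set_ylabel("enrichment score")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
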