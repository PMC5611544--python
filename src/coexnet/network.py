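"""All-pairs coexpression scoring and network construction.

The coexpression score of a gene pair is its Pearson correlation ``r``
across conditions, variance-stabilized by Fisher's z-transform
(``z = arctanh(r)``) and then standardized over the population of all
unordered gene pairs:

    z_cs = (arctanh(r) - mean) / sd

so that ``z_cs`` counts standard deviations from the pair-population mean
and a cutoff of 1.96 retains the upper 2.5% tail when the scores are
normally distributed. The network connects pairs whose ``z_cs`` strictly
exceeds the cutoff; the edge weight used by all downstream computations
(cluster density, segregation) is ``r`` itself, with ``z_cs`` carried as
edge metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CoexpressionScores",
    "pairwise_scores",
    "threshold_network",
    "first_neighbors",
    "write_edge_tsv",
    "read_edge_tsv",
    "write_sif",
    "write_graphml",
    "write_nodes",
    "read_nodes",
]

#: clamp |r| to 1 - CLAMP_EPS before arctanh so perfect correlations stay finite
CLAMP_EPS = 1e-15


@dataclass
class CoexpressionScores:
    """Per-pair coexpression scores over all unordered, non-self gene pairs.

    ``row``/``col`` index into ``gene_ids`` with ``row < col`` (upper
    triangle), so each pair is stored exactly once.
    """

    gene_ids: np.ndarray
    row: np.ndarray
    col: np.ndarray
    r: np.ndarray
    z_fisher: np.ndarray = field(repr=False, default=None)
    z_cs: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.z_fisher is None:
            self.z_fisher = fisher_z(self.r)
        if self.z_cs is None:
            mean = self.z_fisher.mean()
            sd = self.z_fisher.std(ddof=1)
            if sd == 0:
                raise ValueError("degenerate score population: zero spread")
            self.z_cs = (self.z_fisher - mean) / sd

    def __len__(self) -> int:
        return len(self.r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_u": self.gene_ids[self.row],
            "gene_v": self.gene_ids[self.col],
            "r": self.r,
            "z_cs": self.z_cs,
        })


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform with |r| clamped away from 1 for finiteness."""
    return np.arctanh(np.clip(r, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS))


def pairwise_scores(matrix: pd.DataFrame, *,
                    chunk_size: int = 512,
                    min_overlap: int | None = None) -> CoexpressionScores:
    """Compute r, Fisher z and standardized z_cs for every unordered gene pair.

    Works in row chunks so memory stays bounded for large gene counts. With
    complete data the correlations come from a chunked product of
    standardized rows; when missing values are present, pairwise-complete
    correlations are used and pairs observed in fewer than ``min_overlap``
    samples (default: all samples) are an error.

    Raises
    ------
    ValueError
        If fewer than 3 samples are available or any gene has zero variance.
    """
    if matrix.shape[1] < 3:
        raise ValueError("pairwise correlation requires at least 3 samples")
    gene_ids = np.asarray(matrix.index, dtype=object)
    values = matrix.to_numpy(dtype=float, na_value=np.nan)
    n_genes = len(gene_ids)
    if n_genes < 2:
        raise ValueError("need at least 2 genes")

    has_missing = np.isnan(values).any()
    if has_missing:
        if min_overlap is None:
            min_overlap = matrix.shape[1]
        corr = matrix.T.corr(min_periods=min_overlap).to_numpy()
        iu, ju = np.triu_indices(n_genes, k=1)
        r = corr[iu, ju]
        if np.isnan(r).any():
            raise ValueError(
                "gene pair(s) with zero variance or fewer than "
                f"{min_overlap} shared observations"
            )
        return CoexpressionScores(gene_ids, iu.astype(np.int32),
                                  ju.astype(np.int32), r)

    sd = values.std(axis=1)
    if (sd == 0).any():
        offenders = gene_ids[sd == 0].tolist()
        raise ValueError(f"zero-variance genes must be removed first: {offenders[:10]}")
    centered = values - values.mean(axis=1, keepdims=True)
    normed = centered / np.linalg.norm(centered, axis=1, keepdims=True)

    rows, cols, rs = [], [], []
    for start in range(0, n_genes, chunk_size):
        stop = min(start + chunk_size, n_genes)
        block = normed[start:stop] @ normed.T  # (chunk, n_genes)
        for local, i in enumerate(range(start, stop)):
            j = np.arange(i + 1, n_genes)
            if len(j) == 0:
                continue
            rows.append(np.full(len(j), i, dtype=np.int32))
            cols.append(j.astype(np.int32))
            rs.append(block[local, i + 1:])
    r = np.clip(np.concatenate(rs), -1.0, 1.0)
    return CoexpressionScores(gene_ids, np.concatenate(rows),
                              np.concatenate(cols), r)


def threshold_network(scores: CoexpressionScores,
                      z_cutoff: float = 1.96) -> nx.Graph:
    """Build the coexpression network keeping pairs with z_cs > z_cutoff.

    The inequality is strict. All scored genes become nodes (isolated nodes
    are retained so downstream clustered-gene fractions are computed against
    the full network). The realized kept-edge fraction and the minimum r
    among kept edges are recorded as graph attributes ``edge_fraction`` and
    ``min_r_kept`` — the empirical analogue of the Pearson value the
    standardized cutoff corresponds to on a given dataset.
    """
    keep = scores.z_cs > z_cutoff
    graph = nx.Graph()
    graph.add_nodes_from(scores.gene_ids.tolist())
    edges = zip(scores.gene_ids[scores.row[keep]].tolist(),
                scores.gene_ids[scores.col[keep]].tolist(),
                scores.r[keep].tolist(),
                scores.z_cs[keep].tolist())
    graph.add_edges_from((u, v, {"weight": r, "z_cs": z}) for u, v, r, z in edges)
    n_kept = int(keep.sum())
    if n_kept == 0:
        warnings.warn(f"no pair exceeds z_cs cutoff {z_cutoff}; network has no edges")
    graph.graph["z_cutoff"] = float(z_cutoff)
    graph.graph["edge_fraction"] = n_kept / len(scores)
    graph.graph["min_r_kept"] = float(scores.r[keep].min()) if n_kept else float("nan")
    return graph


def first_neighbors(network: nx.Graph, gene: str,
                    min_weight: float = 0.80) -> nx.Graph:
    """Induced subgraph on a query gene and its neighbors above ``min_weight``.

    Neighbors are kept when the connecting edge weight strictly exceeds
    ``min_weight`` (correlation scale); the query gene itself is always
    included, even if isolated at that cutoff.
    """
    if gene not in network:
        raise KeyError(f"unknown gene identifier: {gene!r}")
    keep = {gene}
    keep.update(v for _, v, w in network.edges(gene, data="weight")
                if w > min_weight)
    return network.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# exports

def write_edge_tsv(network: nx.Graph, path) -> None:
    """Edge list TSV (gene_u, gene_v, r, z_cs), sorted by z_cs descending."""
    rows = [(u, v, d["weight"], d.get("z_cs", float("nan")))
            for u, v, d in network.edges(data=True)]
    frame = pd.DataFrame(rows, columns=["gene_u", "gene_v", "r", "z_cs"])
    frame = frame.sort_values(["z_cs", "gene_u", "gene_v"],
                              ascending=[False, True, True])
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_tsv(path, nodes=None) -> nx.Graph:
    """Rebuild a network from an edge-list TSV (optionally adding isolated nodes)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_u": str, "gene_v": str})
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for rec in frame.itertuples(index=False):
        graph.add_edge(rec.gene_u, rec.gene_v, weight=float(rec.r),
                       z_cs=float(rec.z_cs))
    return graph


def write_sif(network: nx.Graph, path, relation: str = "coexp") -> None:
    with open(path, "w") as handle:
        for u, v in sorted(network.edges()):
            handle.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def write_nodes(network: nx.Graph, path) -> None:
    with open(path, "w") as handle:
        for node in sorted(network.nodes()):
            handle.write(f"{node}\n")


def read_nodes(path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]
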