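"""Hypergeometric gene-set enrichment with BH correction.

Overlap significance between a cluster and a gene set is the upper
cumulative hypergeometric tail: with a universe of N genes, sets of sizes
n_i and n_j, and an observed overlap m, the p-value is P(X >= m) for
X ~ Hypergeometric(N, n_i, n_j). P-values from one call form one
multiple-testing family and are BH-adjusted together; the enrichment score
is ES = -log10(q), so the annotation rule ES > 1.3 corresponds to
q < 10^-1.3 ≈ 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterSet

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_overlap",
    "bh_adjust",
    "enrichment_score",
    "filter_genesets",
    "annotate_clusters",
    "best_terms",
    "identify_responsive_clusters",
    "motif_presence_filter",
    "read_motif_hits",
    "write_enrichment_tsv",
]

#: smallest q-value used when taking -log10, to keep ES finite
_Q_FLOOR = 1e-300


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional background universe."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self):
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def effective_sets(self, universe: frozenset[str] | None = None
                       ) -> dict[str, frozenset[str]]:
        """Sets intersected with the (given or declared) universe."""
        uni = universe if universe is not None else self.universe
        if uni is None:
            return dict(self.sets)
        return {name: members & uni for name, members in self.sets.items()}


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-delimited)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions,
                             frozenset(universe) if universe is not None else None)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{desc}\t{members}\n")


def hypergeom_overlap(N: int, n_i: int, n_j: int, m: int) -> float:
    """Upper cumulative hypergeometric tail P(overlap >= m).

    ``N``: universe size; ``n_i``, ``n_j``: set sizes; ``m``: observed
    overlap. Computed via the survival function of
    ``scipy.stats.hypergeom`` (log-space combinatorics internally).
    """
    if not (0 <= m <= min(n_i, n_j) <= max(n_i, n_j) <= N):
        raise ValueError(
            f"inconsistent counts: N={N}, n_i={n_i}, n_j={n_j}, m={m}")
    return float(stats.hypergeom.sf(m - 1, N, n_i, n_j))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def enrichment_score(q: np.ndarray | float) -> np.ndarray | float:
    """ES = -log10(q), floored so perfect overlaps stay finite."""
    return -np.log10(np.maximum(q, _Q_FLOOR))


def filter_genesets(collection: GeneSetCollection,
                    min_size: int = 10,
                    max_size: int = 1500,
                    *, strict_max: bool = False) -> GeneSetCollection:
    """Keep sets whose size (within the declared universe) is in bounds.

    The default bounds drop sets annotating fewer than 10 or more than 1500
    genes (both bounds inclusive for kept sets). ``strict_max=True`` keeps
    only sets strictly below ``max_size`` — used with ``max_size=500`` and
    ``min_size=0`` as the sweep-evaluation preset (sets annotating < 500
    genes).
    """
    effective = collection.effective_sets()
    kept = {}
    for name, members in effective.items():
        size = len(members)
        ok_max = size < max_size if strict_max else size <= max_size
        if size >= min_size and ok_max:
            kept[name] = collection.sets[name]
    return GeneSetCollection(
        kept,
        {n: collection.descriptions.get(n, "") for n in kept},
        collection.universe,
    )


def _resolve_universe(clusters: ClusterSet,
                      genesets: GeneSetCollection,
                      universe) -> frozenset[str]:
    if universe is not None:
        return frozenset(universe)
    if genesets.universe is not None:
        return genesets.universe
    # default: all network genes — everything the clustering partitioned
    return frozenset(clusters.all_genes())


def annotate_clusters(clusters: ClusterSet,
                      genesets: GeneSetCollection,
                      *, universe: Iterable[str] | None = None,
                      es_cutoff: float = 1.3) -> pd.DataFrame:
    """Test every (cluster, gene set) overlap; BH-adjust across the family.

    Returns one row per pair with columns ``cluster_id, set_name, overlap,
    n_cluster, n_set, p, q, es, annotated`` where ``annotated`` flags
    ES > ``es_cutoff`` (default 1.3, i.e. q < 0.05). The universe defaults
    to all genes the clustering was run on; cluster genes outside the
    universe are an error.
    """
    uni = _resolve_universe(clusters, genesets, universe)
    N = len(uni)
    sets = genesets.effective_sets(uni)
    rows = []
    for cid, members in clusters.as_dict().items():
        cluster_genes = frozenset(members)
        offenders = cluster_genes - uni
        if offenders:
            raise ValueError(
                f"cluster {cid} contains genes absent from the universe: "
                f"{sorted(offenders)[:10]}")
        for name, set_genes in sets.items():
            m = len(cluster_genes & set_genes)
            p = hypergeom_overlap(N, len(cluster_genes), len(set_genes), m)
            rows.append((cid, name, m, len(cluster_genes), len(set_genes), p))
    result = pd.DataFrame(
        rows, columns=["cluster_id", "set_name", "overlap",
                       "n_cluster", "n_set", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    result["es"] = enrichment_score(result["q"].to_numpy()) if len(result) else []
    result["annotated"] = result["es"] > es_cutoff
    return result


def best_terms(results: pd.DataFrame) -> dict[str, str]:
    """The single best term per cluster: lowest q, ties by p then name."""
    best: dict[str, str] = {}
    ordered = results.sort_values(["q", "p", "set_name"])
    for cid, group in ordered.groupby("cluster_id", sort=False):
        best[cid] = group.iloc[0]["set_name"]
    return best


def identify_responsive_clusters(clusters: ClusterSet,
                                 de_lists: Mapping[str, Collection[str]],
                                 directions: Mapping[str, str],
                                 universe: Iterable[str],
                                 q_cutoff: float = 0.001) -> pd.DataFrame:
    """Score clusters for enrichment of differentially expressed gene lists.

    Each (cluster, list) pair gets a hypergeometric p, a family-wide BH q,
    and a signed score: +/-(-log10 q) with the sign taken from the list's
    direction (``"up"`` / ``"down"``), set to 0 when q >= ``q_cutoff``. A
    cluster is *responsive* when it is significant for at least one list.
    """
    uni = frozenset(universe)
    N = len(uni)
    for name, direction in directions.items():
        if direction not in ("up", "down"):
            raise ValueError(
                f"unknown direction label {direction!r} for list {name!r}; "
                "expected 'up' or 'down'")
    rows = []
    for cid, members in clusters.as_dict().items():
        cluster_genes = frozenset(members) & uni
        for name, genes in de_lists.items():
            if name not in directions:
                raise ValueError(f"no direction declared for list {name!r}")
            de_genes = frozenset(genes)
            if not de_genes <= uni:
                raise ValueError(
                    f"DE list {name!r} contains genes outside the universe")
            m = len(cluster_genes & de_genes)
            p = hypergeom_overlap(N, len(cluster_genes), len(de_genes), m)
            rows.append((cid, name, directions[name], m, p))
    result = pd.DataFrame(
        rows, columns=["cluster_id", "list_name", "direction", "overlap", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    sign = np.where(result["direction"].to_numpy() == "up", 1.0, -1.0)
    significant = result["q"].to_numpy() < q_cutoff
    score = np.where(significant,
                     sign * enrichment_score(result["q"].to_numpy()), 0.0)
    result["score"] = score
    responsive = result.groupby("cluster_id")["score"].transform(
        lambda s: (s != 0).any())
    result["responsive"] = responsive
    return result


def motif_presence_filter(clusters: ClusterSet,
                          hits: Mapping[str, Collection[str]],
                          min_fraction: float = 0.5) -> dict[str, list[str]]:
    """Motifs present in more than ``min_fraction`` of a cluster's genes.

    The inequality is strict: a motif hitting exactly half the genes is
    dropped at the default 0.5.
    """
    annotations: dict[str, list[str]] = {}
    for cid, members in clusters.as_dict().items():
        counts: dict[str, int] = {}
        for gene in members:
            for motif in hits.get(gene, ()):
                counts[motif] = counts.get(motif, 0) + 1
        kept = sorted(m for m, c in counts.items()
                      if c / len(members) > min_fraction)
        annotations[cid] = kept
    return annotations


def read_motif_hits(path) -> dict[str, set[str]]:
    """Two-column (gene_id, motif_id) TSV, multiple rows per gene."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] != 2:
        raise ValueError(f"motif hit file {path} must have two columns")
    hits: dict[str, set[str]] = {}
    for rec in table.itertuples(index=False):
        hits.setdefault(rec[0], set()).add(rec[1])
    return hits


def write_enrichment_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
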