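"""Parametric gene-set (PAGE-style) scoring of cluster perturbation.

Given a genome-wide log2 fold-change profile and predefined coexpression
clusters, each cluster of m profiled genes with set mean S_m is scored
against the profile's population moments (mean mu, standard deviation
delta) as

    Z = (S_m - mu) * sqrt(m) / delta

which is approximately standard normal for random sets under the central
limit theorem, giving a two-sided normal p per cluster and BH q-values
across all scored clusters. Cluster genes absent from the profile are
ignored (m counts profiled members only), and clusters with fewer than
``min_set_size`` profiled genes are skipped to keep the normal
approximation honest.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSet
from .enrichment import bh_adjust

__all__ = ["page_zscores", "select_perturbed", "write_perturbation_tsv"]


def _cluster_map(clusters) -> dict[str, tuple[str, ...]]:
    if isinstance(clusters, ClusterSet):
        return clusters.as_dict()
    return {cid: tuple(genes) for cid, genes in clusters.items()}


def page_zscores(profile: Mapping[str, float] | pd.Series,
                 clusters: ClusterSet | Mapping[str, tuple],
                 min_set_size: int = 10) -> pd.DataFrame:
    """Score every cluster's coordinated fold-change shift.

    Returns a DataFrame with columns ``cluster_id, m, set_mean, z, p, q,
    direction`` (one row per scored cluster). ``profile`` maps gene IDs to
    log2 fold changes; population moments use the sample standard
    deviation over all profiled genes.
    """
    if not isinstance(profile, pd.Series):
        profile = pd.Series(dict(profile), dtype=float)
    values = profile.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("fold-change profile contains missing values")
    if len(values) < 1000:
        warnings.warn(
            f"profile covers only {len(values)} genes; population moments "
            "may be unstable below ~1000")
    mu = values.mean()
    delta = values.std(ddof=1)
    if delta == 0:
        raise ValueError("constant fold-change profile: zero standard deviation")

    index = pd.Index(profile.index)
    rows = []
    skipped = []
    for cid, members in _cluster_map(clusters).items():
        pos = index.get_indexer(list(members))
        pos = pos[pos >= 0]
        m = len(pos)
        if m < min_set_size:
            skipped.append(cid)
            continue
        set_mean = values[pos].mean()
        z = (set_mean - mu) * np.sqrt(m) / delta
        rows.append((cid, m, set_mean, z))
    if skipped:
        warnings.warn(
            f"{len(skipped)} cluster(s) skipped with fewer than "
            f"{min_set_size} profiled genes: {skipped[:5]}...")
    result = pd.DataFrame(rows, columns=["cluster_id", "m", "set_mean", "z"])
    if len(result):
        result["p"] = 2.0 * stats.norm.sf(np.abs(result["z"].to_numpy()))
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["direction"] = np.where(result["z"] >= 0, "+", "-")
    else:
        result["p"] = []
        result["q"] = []
        result["direction"] = []
    return result


def select_perturbed(results: pd.DataFrame,
                     q_cutoff: float = 0.01) -> pd.DataFrame:
    """Clusters with q < ``q_cutoff`` (strict), ranked by |Z| descending."""
    kept = results[results["q"] < q_cutoff].copy()
    kept["abs_z"] = kept["z"].abs()
    kept = kept.sort_values(["abs_z", "cluster_id"], ascending=[False, True])
    return kept.drop(columns="abs_z").reset_index(drop=True)


def write_perturbation_tsv(results: pd.DataFrame, path,
                           best_term: Mapping[str, str] | None = None) -> None:
    """TSV export; optionally attaches each cluster's representative term."""
    out = results.copy()
    if best_term is not None:
        out["best_term"] = out["cluster_id"].map(dict(best_term))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
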