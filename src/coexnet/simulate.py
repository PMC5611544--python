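"""Seeded synthetic data with planted structure for end-to-end testing.

Expression matrices are built by latent-factor mixing: a gene in block b
with within-block correlation target rho_in is

    x_g = sqrt(rho_out) * g_global + sqrt(rho_in - rho_out) * f_b
          + sqrt(1 - rho_in) * eps_g        (+ baseline)

where g_global, f_b and eps_g are independent standard-normal condition
profiles, so the expected Pearson correlation is rho_in within a block and
rho_out across blocks (and among background genes). A per-gene baseline
shifts values onto a realistic log2-expression scale without altering any
correlation. Defaults mirror the compendium scale this emulates: 45
conditions, 5 planted 30-gene modules with rho_in = 0.9 over a background
of independent genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterSet

__all__ = ["PlantedDesign", "simulate_expression", "simulate_profile",
           "write_truth_tsv"]


@dataclass(frozen=True)
class PlantedDesign:
    """Design of a planted-module expression matrix."""

    n_genes: int = 400
    n_conditions: int = 45
    block_sizes: tuple[int, ...] = (30, 30, 30, 30, 30)
    rho_in: float = 0.9
    rho_out: float = 0.0
    noise_sd: float = 0.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_conditions < 1:
            raise ValueError("degenerate design: need >= 1 gene and condition")
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes exceed the number of genes")
        if not (0 <= self.rho_out < self.rho_in <= 1) and self.block_sizes:
            raise ValueError("require 0 <= rho_out < rho_in <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_expression(design: PlantedDesign
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes x conditions matrix with planted coexpressed blocks.

    Returns the matrix and the truth assignment: a Series mapping each gene
    to its block label (``M1``, ``M2``, ...) or ``background``. Identical
    design (including seed) always yields an identical matrix.
    """
    rng = np.random.default_rng(design.seed)
    n, k = design.n_genes, design.n_conditions
    gene_ids = [f"G{i:05d}" for i in range(1, n + 1)]
    cond_ids = [f"C{j:02d}" for j in range(1, k + 1)]

    global_factor = rng.standard_normal(k)
    a = np.sqrt(design.rho_out)
    values = np.empty((n, k))
    labels = np.array(["background"] * n, dtype=object)

    pos = 0
    for b, size in enumerate(design.block_sizes, start=1):
        factor = rng.standard_normal(k)
        coef_block = np.sqrt(design.rho_in - design.rho_out)
        coef_noise = np.sqrt(1.0 - design.rho_in)
        eps = rng.standard_normal((size, k))
        values[pos:pos + size] = (a * global_factor + coef_block * factor
                                  + coef_noise * eps)
        labels[pos:pos + size] = f"M{b}"
        pos += size
    n_bg = n - pos
    if n_bg:
        eps = rng.standard_normal((n_bg, k))
        values[pos:] = a * global_factor + np.sqrt(1.0 - design.rho_out) * eps

    if design.noise_sd > 0:
        values = values + design.noise_sd * rng.standard_normal((n, k))
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
    values = values + baseline[:, None]

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=cond_ids)
    truth = pd.Series(labels, index=matrix.index, name="block")
    return matrix, truth


def simulate_profile(clusters: ClusterSet,
                     perturbed: Iterable[str],
                     effect: float,
                     seed: int) -> tuple[pd.Series, dict[str, float]]:
    """Generate a fold-change profile with planted perturbed clusters.

    Background fold changes are i.i.d. standard normal over every gene the
    clustering covers; genes in ``perturbed`` clusters (given by cluster
    id) are shifted by ``effect``. Returns the profile and the signed truth
    (cluster id -> planted shift).
    """
    cluster_map = clusters.as_dict()
    perturbed = list(perturbed)
    unknown = [cid for cid in perturbed if cid not in cluster_map]
    if unknown:
        raise ValueError(f"unknown cluster ids: {unknown}")
    genes = sorted(clusters.all_genes())
    rng = np.random.default_rng(seed)
    profile = pd.Series(rng.standard_normal(len(genes)), index=genes,
                        name="log2fc")
    truth: dict[str, float] = {}
    for cid in perturbed:
        profile.loc[list(cluster_map[cid])] += effect
        truth[cid] = float(effect)
    return profile, truth


def write_truth_tsv(truth: pd.Series, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index_label="gene_id")
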