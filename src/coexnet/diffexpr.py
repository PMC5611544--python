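"""Two-group differential expression on replicate samples.

Per gene, the log2 fold change is the difference of group means (the data
are log2 scale) and significance comes from the two-group linear-model t
with empirical-Bayes variance moderation: per-gene pooled variances are
shrunk toward a common prior fitted by moments from all genes (a scaled-F
fit of the variance distribution), the standard remedy for the very low
residual degrees of freedom of small replicate designs. The unmoderated
pooled-variance t is available via ``moderated=False``. P-values are
BH-adjusted across all tested genes. Differential expression must be
computed on replicates, never on replicate-averaged matrices.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_adjust
from .expression import _as_series

__all__ = [
    "de_test",
    "select_de",
    "write_de_profile",
    "read_de_profile",
    "write_fold_change_upload",
    "read_fold_changes",
]


def _trigamma_inverse(x: float) -> float:
    # Newton solve of polygamma(1, y) = x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray
                        ) -> tuple[float, float] | None:
    """Moment fit of a scaled-F prior to per-gene sample variances.

    Returns (prior df d0, prior variance s0^2), with d0 = inf when the
    observed variances show no more spread than chi-square sampling alone;
    None when too few usable variances exist to fit.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return None
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2))
    if evar <= 0:
        return float("inf"), float(np.exp(e.mean()))
    half_d0 = _trigamma_inverse(evar)
    s0_2 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    return 2 * half_d0, float(s0_2)


def de_test(matrix: pd.DataFrame,
            grouping: Mapping[str, str] | pd.Series,
            contrast: tuple[str, str],
            *, moderated: bool = True) -> pd.DataFrame:
    """Per-gene treatment-vs-control linear-model t-test.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean
    treatment minus mean control), ``t``, ``p`` (two-sided) and ``q`` (BH).
    With ``moderated=True`` (default) per-gene variances are squeezed
    toward the fitted prior and the t-test gains the prior degrees of
    freedom; with ``moderated=False`` the ordinary pooled-variance t is
    used and genes with zero residual variance get missing ``t``/``p``/
    ``q``. Each side of the contrast needs at least 2 replicate samples.
    """
    grouping = _as_series(grouping)
    treatment, control = contrast
    t_cols = grouping.index[grouping == treatment].tolist()
    c_cols = grouping.index[grouping == control].tolist()
    for label, cols in ((treatment, t_cols), (control, c_cols)):
        if len(cols) < 2:
            raise ValueError(
                f"contrast group {label!r} has {len(cols)} sample(s); "
                "at least 2 replicates are required")
        missing = [c for c in cols if c not in matrix.columns]
        if missing:
            raise ValueError(f"samples absent from matrix: {missing}")

    tv = matrix[t_cols].to_numpy(dtype=float, na_value=np.nan)
    cv = matrix[c_cols].to_numpy(dtype=float, na_value=np.nan)
    n1 = (~np.isnan(tv)).sum(axis=1)
    n2 = (~np.isnan(cv)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        m1 = np.nanmean(tv, axis=1)
        m2 = np.nanmean(cv, axis=1)
        v1 = np.nanvar(tv, axis=1, ddof=1)
        v2 = np.nanvar(cv, axis=1, ddof=1)
        df = (n1 + n2 - 2).astype(float)
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        log2fc = m1 - m2

    usable = (n1 >= 2) & (n2 >= 2)
    prior = _fit_variance_prior(pooled[usable], df[usable]) if moderated else None
    if prior is not None:
        d0, s0_2 = prior
        if np.isinf(d0):
            post = np.full_like(pooled, s0_2)
            total_df = np.full_like(df, np.inf)
        else:
            post = (d0 * s0_2 + df * pooled) / (d0 + df)
            total_df = df + d0
    else:
        post = pooled
        total_df = df

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
        t = log2fc / se
        finite_df = np.isfinite(total_df)
        p = np.where(finite_df,
                     2.0 * stats.t.sf(np.abs(t), np.where(finite_df, total_df, 1)),
                     2.0 * stats.norm.sf(np.abs(t)))

    degenerate = usable & (post == 0)
    t = np.where(degenerate | ~usable, np.nan, t)
    p = np.where(degenerate | ~usable, np.nan, p)

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    result = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": q}, index=matrix.index)
    result.index.name = "gene_id"
    return result


def select_de(profile: pd.DataFrame,
              q_cutoff: float = 0.01) -> tuple[list[str], list[str]]:
    """Split significant genes into up- and down-regulated lists.

    A gene is selected when ``q < q_cutoff`` (strict) and assigned to the
    up (log2fc > 0) or down (log2fc < 0) list; the lists are disjoint.
    """
    sig = profile[(profile["q"] < q_cutoff) & profile["q"].notna()]
    up = sig.index[sig["log2fc"] > 0].tolist()
    down = sig.index[sig["log2fc"] < 0].tolist()
    return up, down


def write_de_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index_label="gene_id",
                   float_format="%.10g", na_rep="NA")


def read_de_profile(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_fold_change_upload(profile: pd.DataFrame, path) -> None:
    """Two-column (gene_id, log2fc) projection: the upload format consumed
    by the cluster-perturbation scorer."""
    profile[["log2fc"]].to_csv(path, sep="\t", index_label="gene_id",
                               float_format="%.10g")


def read_fold_changes(path) -> pd.Series:
    """Read a two-column (gene ID, log2 fold change) TSV with a header.

    Any other column count is rejected: the contract is exactly two columns
    — gene identifiers first, fold-change values second.
    """
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] != 2:
        raise ValueError(
            f"fold-change file {path} must contain exactly two columns "
            "(gene ID, log2 fold change) with a header row; "
            f"found {table.shape[1]} column(s)")
    gene_col, fc_col = table.columns
    genes = table[gene_col].astype(str)
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in upload: {dups[:10]}")
    values = pd.to_numeric(table[fc_col], errors="raise")
    return pd.Series(values.to_numpy(dtype=float), index=genes.to_numpy(),
                     name="log2fc")
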