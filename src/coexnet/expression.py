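"""Expression-matrix ingestion, replicate averaging, and variance filtering.

Matrices are genes x samples :class:`pandas.DataFrame` objects holding
log2-scale expression values; the index carries gene identifiers and the
columns carry sample (or, after averaging, condition-group) identifiers.
Missing measurements are ``NaN``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_grouping",
    "read_contrasts",
    "validate_matrix",
    "average_replicates",
    "iqr_filter",
]


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the matrix.

    Raises
    ------
    ValueError
        On duplicate gene or sample identifiers, or non-numeric values.
    """
    dup_genes = matrix.index[matrix.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene identifiers: {dup_genes}")
    dup_samples = matrix.columns[matrix.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample identifiers: {dup_samples}")
    bad = [c for c in matrix.columns if not pd.api.types.is_numeric_dtype(matrix[c])]
    if bad:
        raise ValueError(f"non-numeric expression columns: {bad}")
    if np.isinf(matrix.to_numpy(dtype=float, na_value=np.nan)).any():
        raise ValueError("expression values must be finite or missing")
    return matrix


def read_expression_matrix(path, *, missing_token: str = "NA") -> pd.DataFrame:
    """Read a tab-delimited expression matrix.

    The file must have a header row of sample identifiers and gene
    identifiers in the first column. Cells equal to ``missing_token`` are
    read as missing; any other non-numeric cell is an error.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=[missing_token], keep_default_na=False,
    )
    try:
        matrix = raw.apply(pd.to_numeric).astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene_id"
    return validate_matrix(matrix)


def write_expression_matrix(matrix: pd.DataFrame, path, *,
                            missing_token: str = "NA",
                            float_format: str = "%.10g") -> None:
    """Write a matrix as TSV (header = sample IDs, column 1 = gene IDs)."""
    matrix.to_csv(path, sep="\t", na_rep=missing_token,
                  float_format=float_format, index_label="gene_id")


def read_grouping(path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a sample->group Series."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] != 2:
        raise ValueError(
            f"grouping file {path} must have exactly two columns "
            f"(sample_id, group); found {table.shape[1]}"
        )
    sample, group = table.columns
    return pd.Series(table[group].values, index=table[sample].values, name="group")


def read_contrasts(path) -> list[tuple[str, str]]:
    """Read a two-column (treatment_group, control_group) TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] != 2:
        raise ValueError(
            f"contrast file {path} must have exactly two columns; "
            f"found {table.shape[1]}"
        )
    return [tuple(row) for row in table.itertuples(index=False)]


def _as_series(grouping: Mapping[str, str] | pd.Series) -> pd.Series:
    if isinstance(grouping, pd.Series):
        return grouping.astype(str)
    return pd.Series(dict(grouping), dtype=str)


def average_replicates(matrix: pd.DataFrame,
                       grouping: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Average replicate samples into one column per condition group.

    Each output cell is the arithmetic mean over the group's replicates,
    with missing values excluded; a cell with no usable replicate is
    flagged missing. Only samples named in ``grouping`` are retained, and
    groups appear in order of first appearance.
    """
    grouping = _as_series(grouping)
    unknown = [s for s in grouping.index if s not in matrix.columns]
    if unknown:
        raise ValueError(f"grouped samples absent from matrix: {unknown}")
    groups: dict[str, list[str]] = {}
    for sample, group in grouping.items():
        groups.setdefault(group, []).append(sample)
    out = {g: matrix[cols].mean(axis=1, skipna=True) for g, cols in groups.items()}
    averaged = pd.DataFrame(out, index=matrix.index)
    averaged.columns.name = matrix.columns.name
    return averaged


def _gene_iqrs(values: np.ndarray) -> np.ndarray:
    # linear interpolation between order statistics, missing values excluded
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        q1, q3 = np.nanpercentile(values, [25, 75], axis=1, method="linear")
    return q3 - q1


def iqr_filter(matrix: pd.DataFrame, *,
               rule: str = "median_of_iqrs",
               max_missing_fraction: float = 0.5,
               ) -> tuple[pd.DataFrame, list[str]]:
    """Remove lowly varying genes by interquartile range.

    The published rule ("IQR less than the median") is ambiguous; under the
    default ``rule="median_of_iqrs"`` a gene is removed when its IQR across
    samples is strictly below the median of all genes' IQRs (the standard
    variance-filter convention). ``rule="gene_median"`` instead compares each
    gene's IQR to that gene's own median expression. Genes missing in more
    than ``max_missing_fraction`` of samples are removed with a warning.

    Returns the filtered matrix and the list of removed genes; together they
    partition the input genes exactly.
    """
    if matrix.shape[1] < 2:
        raise ValueError("iqr_filter requires at least 2 samples")
    if matrix.shape[1] < 4:
        warnings.warn("IQR computed on fewer than 4 samples is unstable")
    if rule not in ("median_of_iqrs", "gene_median"):
        raise ValueError(f"unknown rule {rule!r}")

    values = matrix.to_numpy(dtype=float, na_value=np.nan)
    missing_frac = np.isnan(values).mean(axis=1)
    too_missing = missing_frac > max_missing_fraction
    if too_missing.any():
        warnings.warn(
            f"{int(too_missing.sum())} gene(s) missing in more than "
            f"{max_missing_fraction:.0%} of samples were removed"
        )

    iqrs = _gene_iqrs(values)
    if rule == "median_of_iqrs":
        threshold = np.nanmedian(iqrs[~too_missing])
        low = iqrs < threshold
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gene_medians = np.nanmedian(values, axis=1)
        low = iqrs < gene_medians
    removed_mask = low | too_missing
    removed = matrix.index[removed_mask].tolist()
    return matrix.loc[~removed_mask], removed
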