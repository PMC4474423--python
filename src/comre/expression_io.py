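"""Reading, collapsing, filtering and writing log2 expression matrices.

The central container is :class:`ExpressionMatrix`, a genes x samples table of
log2-scale expression values with unique row (gene or probe) and column
(sample) identifiers. Matrices arrive as plain delimited text: a header row of
sample ids and a first column of gene/probe ids.

Microarray platforms often carry several probe sets per gene; following common
practice the probe with the largest coefficient of variation (CV) across
samples is kept as the gene's representative, and rows that are computationally
non-informative (CV below 5% or mean log2 expression below 6) are removed
before any pairwise analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ExpressionParseError,
    MissingGeneError,
    ProbeMapError,
    ZeroVarianceError,
)

__all__ = [
    "ExpressionMatrix",
    "FilterSummary",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_map",
    "collapse_probes_by_cv",
    "filter_noninformative",
    "coefficient_of_variation",
]

#: Default ddof used for every standard deviation in this module (sample sd).
DEFAULT_DDOF = 1


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Parameters
    ----------
    gene_ids
        Ordered unique row identifiers (probe ids before collapsing, gene
        symbols after).
    sample_ids
        Ordered unique column identifiers.
    values
        Float array of shape ``(len(gene_ids), len(sample_ids))``; must be
        finite everywhere.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ExpressionParseError(f"duplicate gene/probe ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ExpressionParseError(f"duplicate sample ids: {dupes}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionParseError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise MissingGeneError(f"gene id not in matrix: {gene_id!r}") from None

    def row_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except KeyError:
            raise MissingGeneError(f"gene id not in matrix: {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.row_index(g) for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class FilterSummary:
    """Row counts for one pass of :func:`filter_noninformative`.

    A row failing both criteria is counted under both ``removed_low_cv`` and
    ``removed_low_mean``; ``n_input - n_kept`` is the number of distinct rows
    removed.
    """

    n_input: int
    n_kept: int
    removed_low_cv: int
    removed_low_mean: int


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The first row holds sample ids, the first column gene/probe ids and the
    body is numeric. Any non-numeric or empty cell raises
    :class:`ExpressionParseError` naming the row and column; missing values
    are deliberately rejected rather than imputed because the downstream
    covariability and least-squares computations assume complete data.
    """
    path = Path(path)
    # pandas mangles duplicate header names, so check the raw header first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        raise ExpressionParseError(
            f"{path.name}: duplicate sample ids: {_duplicates(header)}"
        )
    # keep_default_na=False so tokens like "NA" surface as parse errors with
    # a location instead of silently becoming NaN.
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ExpressionParseError(
            f"{path.name}: duplicate sample ids: {_duplicates(sample_ids)}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ExpressionParseError(
            f"{path.name}: duplicate gene/probe ids: {_duplicates(gene_ids)}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ExpressionParseError(
                f"{path.name}: non-numeric cell {df.iloc[i, j]!r} at "
                f"gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix as delimited text that round-trips through
    :func:`read_expression_matrix` at full float precision."""
    expr.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_probe_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (probe_id, gene_id) table with a header row.

    Returns a probe -> gene mapping; duplicate probe ids or empty gene ids are
    errors.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     na_values=[])
    if df.shape[1] < 2:
        raise ProbeMapError(f"{Path(path).name}: expected 2 columns, got {df.shape[1]}")
    probes = df.iloc[:, 0].astype(str).tolist()
    genes = df.iloc[:, 1].astype(str).tolist()
    if len(set(probes)) != len(probes):
        raise ProbeMapError(f"duplicate probe ids: {_duplicates(probes)}")
    if any(g == "" for g in genes):
        empties = [p for p, g in zip(probes, genes) if g == ""]
        raise ProbeMapError(f"empty gene id for probes: {empties}")
    return dict(zip(probes, genes))


def coefficient_of_variation(
    values: np.ndarray, ddof: int = DEFAULT_DDOF
) -> np.ndarray:
    """Row-wise CV (standard deviation over arithmetic mean) on log2 values.

    Rows with zero mean get NaN: their CV is undefined. The ``ddof``
    convention (sample sd by default) is exposed because published filter
    thresholds rarely state it.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, sd / mean, np.nan)
    return cv


def collapse_probes_by_cv(
    expr: ExpressionMatrix,
    probe_map: Mapping[str, str],
    ddof: int = DEFAULT_DDOF,
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with the largest CV across samples is kept; ties
    are broken toward the lexicographically smallest probe id so the result is
    deterministic. Output rows are labelled with gene ids, ordered by the
    first appearance of each gene among the input probes.

    Raises
    ------
    ProbeMapError
        If any probe row is absent from ``probe_map``.
    ZeroVarianceError
        If every probe of some gene has zero mean (CV undefined).
    """
    missing = [p for p in expr.gene_ids if p not in probe_map]
    if missing:
        raise ProbeMapError(f"probes missing from map: {missing}")
    cv = coefficient_of_variation(expr.values, ddof=ddof)

    gene_order: list[str] = []
    probes_of: dict[str, list[int]] = {}
    for i, probe in enumerate(expr.gene_ids):
        gene = probe_map[probe]
        if gene not in probes_of:
            probes_of[gene] = []
            gene_order.append(gene)
        probes_of[gene].append(i)

    chosen_rows: list[int] = []
    for gene in gene_order:
        candidates = [i for i in probes_of[gene] if np.isfinite(cv[i])]
        if not candidates:
            probes = [expr.gene_ids[i] for i in probes_of[gene]]
            raise ZeroVarianceError(
                f"gene {gene!r}: CV undefined for every probe "
                f"(zero mean): {probes}"
            )
        best = min(candidates, key=lambda i: (-cv[i], expr.gene_ids[i]))
        chosen_rows.append(best)

    return ExpressionMatrix(gene_order, list(expr.sample_ids), expr.values[chosen_rows])


def filter_noninformative(
    expr: ExpressionMatrix,
    cv_min: float = 0.05,
    mean_min: float = 6.0,
    ddof: int = DEFAULT_DDOF,
) -> tuple[ExpressionMatrix, FilterSummary]:
    """Drop rows with CV below ``cv_min`` or mean log2 expression below
    ``mean_min``.

    Retention uses ``>=`` on both criteria (strictly-below rows are removed),
    the surviving rows keep their input order, and the returned
    :class:`FilterSummary` reports how many rows each criterion removed. An
    empty result is a warning, not an error.
    """
    cv = coefficient_of_variation(expr.values, ddof=ddof)
    mean = expr.values.mean(axis=1)
    # undefined CV (zero mean) never satisfies cv >= cv_min
    cv_ok = np.nan_to_num(cv, nan=-np.inf) >= cv_min
    mean_ok = mean >= mean_min
    keep = cv_ok & mean_ok
    summary = FilterSummary(
        n_input=expr.n_genes,
        n_kept=int(keep.sum()),
        removed_low_cv=int((~cv_ok).sum()),
        removed_low_mean=int((~mean_ok).sum()),
    )
    if summary.n_kept == 0:
        warnings.warn("all rows removed by the CV/mean filters", stacklevel=2)
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return (
        ExpressionMatrix(kept_ids, list(expr.sample_ids), expr.values[keep]),
        summary,
    )
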