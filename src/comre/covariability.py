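"""Per-sample covariability of gene pairs.

Covariability is the per-sample product of two genes' expression z-scores:
for genes i and j and sample k,

    C_ijk = ((e_ik - mean(e_i)) / sd(e_i)) * ((e_jk - mean(e_j)) / sd(e_j)),

i.e. sample k's product-moment contribution to the Pearson correlation of the
two genes. A large positive (negative) value flags a sample in which the two
genes deviate strongly in the same (opposite) direction, so the vector of
C_ijk over samples is a per-sample readout of regulation strength that can be
regressed on candidate modulator expression.

Standard deviations are sample sds (K-1 denominator; see ``PEARSON_DDOF``),
so the per-pair sum satisfies sum_k C_ijk = (K-1) * r_ij with r the Pearson
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ZeroVarianceError
from .expression_io import ExpressionMatrix

__all__ = [
    "PEARSON_DDOF",
    "CovariabilityVector",
    "zscore",
    "covariability",
    "covariability_profile",
    "pearson_from_covariability",
    "all_pairs",
]

#: ddof of the standard deviation used in every z-transform. With the sample
#: sd (ddof=1) the covariability of a pair sums to (K-1) times its Pearson
#: correlation; with ddof=0 it would sum to K times. Kept as a module-level
#: documented constant because the two conventions differ only by this factor.
PEARSON_DDOF = 1


@dataclass(frozen=True)
class CovariabilityVector:
    """Per-sample covariability of one gene pair (length K, dimensionless)."""

    gene_i: str
    gene_j: str
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)

    def pearson(self) -> float:
        """Pearson correlation of the pair, via sum(C) / (K-1)."""
        return pearson_from_covariability(self.values)


def zscore(v: Sequence[float] | np.ndarray, name: str | None = None) -> np.ndarray:
    """Center to mean 0 and scale to sample standard deviation 1.

    Raises :class:`ZeroVarianceError` (naming ``name`` if given) on constant
    input, and ``ValueError`` for vectors shorter than 3 samples, where a
    per-sample correlation decomposition is not meaningful.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("zscore expects a 1-D vector")
    if v.size < 3:
        raise ValueError(f"need at least 3 samples, got {v.size}")
    sd = v.std(ddof=PEARSON_DDOF)
    if sd == 0.0 or not np.isfinite(sd):
        label = f" for {name!r}" if name else ""
        raise ZeroVarianceError(f"zero variance{label}: cannot z-transform")
    return (v - v.mean()) / sd


def covariability(
    e_i: Sequence[float] | np.ndarray,
    e_j: Sequence[float] | np.ndarray,
    gene_i: str = "gene_i",
    gene_j: str = "gene_j",
) -> CovariabilityVector:
    """Per-sample covariability of two expression vectors.

    Element k is ``zscore(e_i)[k] * zscore(e_j)[k]``. Inputs must have equal
    length K >= 3 and be nonconstant.
    """
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    if e_i.shape != e_j.shape:
        raise ValueError(
            f"length mismatch: {gene_i} has {e_i.shape}, {gene_j} has {e_j.shape}"
        )
    return CovariabilityVector(
        gene_i, gene_j, zscore(e_i, gene_i) * zscore(e_j, gene_j)
    )


def pearson_from_covariability(values: np.ndarray) -> float:
    """Recover the Pearson correlation from a covariability vector."""
    values = np.asarray(values, dtype=float)
    return float(values.sum() / (values.size - PEARSON_DDOF))


def zscore_rows(expr: ExpressionMatrix, gene_ids: Sequence[str]) -> np.ndarray:
    """Z-score the given genes' rows; returns a (len(gene_ids), K) array."""
    out = np.empty((len(gene_ids), expr.n_samples))
    for r, g in enumerate(gene_ids):
        out[r] = zscore(expr.row(g), g)
    return out


def all_pairs(gene_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs (i before j in the given order)."""
    return list(combinations(gene_ids, 2))


def covariability_profile(
    expr: ExpressionMatrix,
    pairs: Iterable[tuple[str, str]],
    chunk_size: int = 10_000,
) -> np.ndarray:
    """Covariability matrix for many gene pairs: one row per pair, one column
    per sample.

    Gene rows are z-scored once and pairs are processed in chunks of
    ``chunk_size`` so memory stays proportional to the chunk, not the full
    pair list. Self-pairs are allowed when explicitly listed (their row is
    the squared z-score). Unknown gene ids raise :class:`MissingGeneError`.
    """
    pairs = list(pairs)
    if not pairs:
        return np.empty((0, expr.n_samples))
    genes_used: list[str] = []
    seen: set[str] = set()
    for gi, gj in pairs:
        for g in (gi, gj):
            if g not in seen:
                seen.add(g)
                genes_used.append(g)
    z = zscore_rows(expr, genes_used)
    zidx = {g: r for r, g in enumerate(genes_used)}

    out = np.empty((len(pairs), expr.n_samples))
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start:start + chunk_size]
        ii = [zidx[gi] for gi, _ in chunk]
        jj = [zidx[gj] for _, gj in chunk]
        out[start:start + len(chunk)] = z[ii] * z[jj]
    return out
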