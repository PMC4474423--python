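"""Multiple regression of covariability on modulator expression.

For every gene pair (i, j) the model is

    C_ij = b0 + sum_m beta_m * z(e_m) + eps,

where C_ij is the pair's per-sample covariability vector and z(e_m) the
z-transformed expression of candidate modulator m. Because the regressors are
the same for every pair, the ordinary-least-squares projector
(X'X)^{-1} X' is computed once and applied to chunked blocks of covariability
rows, which makes the all-pairs sweep a sequence of matrix products rather
than millions of independent model fits. Each coefficient gets a two-sided
t-test p-value with K - M - 1 degrees of freedom (K - M without intercept).

The model formula has no explicit intercept, but a covariability vector has
mean (K-1) r / K, generally nonzero, so the intercept is included by default
and is excluded from the significance tests; ``intercept=False`` reproduces
the bare formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariability import CovariabilityVector, all_pairs, zscore, zscore_rows
from .exceptions import MissingGeneError, RankDeficientError
from .expression_io import ExpressionMatrix

__all__ = [
    "DesignMatrix",
    "CoModulationPattern",
    "build_design_matrix",
    "random_design",
    "fit_pair",
    "fit_batch",
    "fit_all_pairs",
    "count_pairs",
    "write_patterns",
    "read_patterns",
]

#: Condition-number ceiling for X'X; beyond this the design is treated as
#: rank deficient (hard error, no silent regularisation).
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class DesignMatrix:
    """Shared regression design: z-scored modulator columns (+ intercept).

    ``columns`` is K x (M+1) with the intercept last when present, K x M
    otherwise. Every modulator column has mean 0 and sample sd 1 by
    construction.
    """

    sample_ids: tuple[str, ...]
    modulator_ids: tuple[str, ...]
    columns: np.ndarray
    intercept_included: bool

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_modulators(self) -> int:
        return len(self.modulator_ids)

    @property
    def df_resid(self) -> int:
        return self.n_samples - self.columns.shape[1]

    @property
    def modulator_columns(self) -> np.ndarray:
        return self.columns[:, : self.n_modulators]


@dataclass(frozen=True)
class CoModulationPattern:
    """Fitted co-modulation pattern of one gene pair.

    ``betas`` and ``pvalues`` are aligned with ``modulator_ids`` (length M);
    ``intercept`` is 0.0 when the model was fitted without one.
    """

    gene_i: str
    gene_j: str
    modulator_ids: tuple[str, ...]
    betas: np.ndarray
    pvalues: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.betas) != len(self.modulator_ids) or len(self.pvalues) != len(
            self.modulator_ids
        ):
            raise ValueError("betas/pvalues length must equal number of modulators")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)

    def significant_set(self, alpha: float = 0.05) -> frozenset[str]:
        """Modulators with p strictly below ``alpha``."""
        return frozenset(
            m for m, p in zip(self.modulator_ids, self.pvalues) if p < alpha
        )


def build_design_matrix(
    expr: ExpressionMatrix,
    modulator_ids: Sequence[str],
    intercept: bool = True,
) -> DesignMatrix:
    """Extract and z-transform the modulator rows of ``expr`` into a design.

    Modulators must be distinct, present in the matrix and nonconstant, and
    there must be more samples than fitted coefficients.
    """
    modulator_ids = [str(m) for m in modulator_ids]
    if len(set(modulator_ids)) != len(modulator_ids):
        dupes = sorted({m for m in modulator_ids if modulator_ids.count(m) > 1})
        raise ValueError(f"duplicate modulator ids: {dupes}")
    missing = [m for m in modulator_ids if m not in expr]
    if missing:
        raise MissingGeneError(f"modulators missing from matrix: {missing}")
    z = zscore_rows(expr, modulator_ids).T  # K x M
    return _assemble_design(tuple(expr.sample_ids), tuple(modulator_ids), z, intercept)


def random_design(
    n_samples: int,
    n_modulators: int,
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Design matrix of standard-normal draws in place of real modulators.

    This is the random-baseline control: rerunning the all-pairs regression
    against simulated regressors calibrates the empirical significance rate
    at the chosen alpha. Columns are z-scored like real modulators.
    """
    if sample_ids is None:
        sample_ids = [f"S{k + 1:04d}" for k in range(n_samples)]
    raw = rng.standard_normal((n_samples, n_modulators))
    z = np.column_stack([zscore(raw[:, m]) for m in range(n_modulators)])
    ids = tuple(f"RAND{m + 1:02d}" for m in range(n_modulators))
    return _assemble_design(tuple(str(s) for s in sample_ids), ids, z, intercept)


def _assemble_design(
    sample_ids: tuple[str, ...],
    modulator_ids: tuple[str, ...],
    z: np.ndarray,
    intercept: bool,
) -> DesignMatrix:
    K, M = z.shape
    n_coef = M + (1 if intercept else 0)
    if K <= n_coef:
        raise ValueError(
            f"need more samples than coefficients: K={K}, coefficients={n_coef}"
        )
    cols = np.column_stack([z, np.ones(K)]) if intercept else z
    design = DesignMatrix(sample_ids, modulator_ids, cols, intercept)
    _check_rank(design)
    return design


def _check_rank(design: DesignMatrix) -> None:
    xtx = design.columns.T @ design.columns
    if np.linalg.cond(xtx) > CONDITION_LIMIT:
        # name the near-dependent columns via the diagonal of R in a QR
        names = list(design.modulator_ids) + (
            ["<intercept>"] if design.intercept_included else []
        )
        r = np.linalg.qr(design.columns, mode="r")
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-7 * diag.max())]
        raise RankDeficientError(
            "design matrix is rank deficient (condition number of X'X above "
            f"{CONDITION_LIMIT:g}); collinear columns: {bad or names}"
        )


class _SharedFit:
    """The pair-independent part of the OLS fit, computed once per design."""

    def __init__(self, design: DesignMatrix):
        self.design = design
        X = design.columns
        xtx = X.T @ X
        if np.linalg.cond(xtx) > CONDITION_LIMIT:
            _check_rank(design)  # raises with column names
        self.projector = np.linalg.solve(xtx, X.T)  # (M+1) x K
        self.xtx_inv_diag = np.diag(np.linalg.inv(xtx))
        self.df = design.df_resid

    def fit(self, C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fit a block of responses (n_pairs x K).

        Returns (betas n x M, pvalues n x M, intercepts n).
        """
        design = self.design
        C = np.atleast_2d(np.asarray(C, dtype=float))
        coef = C @ self.projector.T  # n x n_coef
        resid = C - coef @ design.columns.T
        rss = np.einsum("ij,ij->i", resid, resid)
        sigma2 = rss / self.df
        M = design.n_modulators
        betas = coef[:, :M]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2[:, None] * self.xtx_inv_diag[None, :M])
            t = betas / se
        pvalues = 2.0 * stats.t.sf(np.abs(t), self.df)
        # a perfect fit (rss == 0) gives se == 0: p is 0 for a nonzero
        # coefficient, 1 for a (numerically) zero one
        degenerate = se == 0.0
        if degenerate.any():
            scale = 1e-10 * np.maximum(1.0, np.abs(C).max(axis=1))
            pvalues[degenerate] = np.where(
                np.abs(betas[degenerate]) > np.broadcast_to(scale[:, None], betas.shape)[degenerate],
                0.0, 1.0,
            )
        if design.intercept_included:
            intercepts = coef[:, M]
        else:
            intercepts = np.zeros(C.shape[0])
        return betas, pvalues, intercepts


def fit_pair(C: CovariabilityVector, design: DesignMatrix) -> CoModulationPattern:
    """OLS fit of one pair's covariability vector on the shared design."""
    if len(C) != design.n_samples:
        raise ValueError(
            f"covariability length {len(C)} != design samples {design.n_samples}"
        )
    betas, pvalues, intercepts = _SharedFit(design).fit(C.values[None, :])
    return CoModulationPattern(
        C.gene_i, C.gene_j, design.modulator_ids,
        betas[0], pvalues[0], float(intercepts[0]),
    )


def fit_batch(
    C: np.ndarray, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit many covariability rows at once against one design.

    Returns ``(betas, pvalues, intercepts)`` with one row per response;
    numerically identical (to ~1e-10) to per-row :func:`fit_pair` calls.
    """
    return _SharedFit(design).fit(C)


def count_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n(n-1)/2."""
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    return n_genes * (n_genes - 1) // 2


def fit_all_pairs(
    expr: ExpressionMatrix,
    modulator_ids: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    chunk_size: int = 10_000,
    intercept: bool = True,
    design: DesignMatrix | None = None,
) -> Iterator[CoModulationPattern]:
    """Fit the co-modulation regression for every requested gene pair.

    ``pairs`` defaults to all unordered combinations of the genes in ``expr``
    that are not themselves modulators. A prebuilt ``design`` (e.g. from
    :func:`random_design` for the random-baseline control) overrides
    ``modulator_ids``. Yields one :class:`CoModulationPattern` per pair;
    covariability rows are formed and fitted in chunks of ``chunk_size`` so
    memory stays bounded while the projector is shared across all pairs.
    """
    if design is None:
        if modulator_ids is None:
            raise ValueError("either modulator_ids or design must be given")
        design = build_design_matrix(expr, modulator_ids, intercept=intercept)
    if tuple(expr.sample_ids) != design.sample_ids:
        raise ValueError("expression matrix and design have different samples")
    if pairs is None:
        mods = set(design.modulator_ids)
        pairs = all_pairs([g for g in expr.gene_ids if g not in mods])
    pairs = list(pairs)
    if not pairs:
        return
    shared = _SharedFit(design)

    genes_used: list[str] = []
    seen: set[str] = set()
    for gi, gj in pairs:
        for g in (gi, gj):
            if g not in seen:
                seen.add(g)
                genes_used.append(g)
    z = zscore_rows(expr, genes_used)
    zidx = {g: r for r, g in enumerate(genes_used)}

    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start:start + chunk_size]
        ii = [zidx[gi] for gi, _ in chunk]
        jj = [zidx[gj] for _, gj in chunk]
        C = z[ii] * z[jj]
        betas, pvalues, intercepts = shared.fit(C)
        for r, (gi, gj) in enumerate(chunk):
            yield CoModulationPattern(
                gi, gj, design.modulator_ids,
                betas[r].copy(), pvalues[r].copy(), float(intercepts[r]),
            )


def write_patterns(
    patterns: Iterable[CoModulationPattern], path: str | Path, delimiter: str = "\t"
) -> int:
    """Write patterns as a flat table: gene_i, gene_j, intercept, then one
    beta_<mod> and p_<mod> column per modulator. Returns the row count."""
    path = Path(path)
    n = 0
    with open(path, "w") as fh:
        header: list[str] | None = None
        for pat in patterns:
            if header is None:
                header = ["gene_i", "gene_j", "intercept"]
                for m in pat.modulator_ids:
                    header += [f"beta_{m}", f"p_{m}"]
                fh.write(delimiter.join(header) + "\n")
            row = [pat.gene_i, pat.gene_j, repr(pat.intercept)]
            for b, p in zip(pat.betas, pat.pvalues):
                row += [repr(float(b)), repr(float(p))]
            fh.write(delimiter.join(row) + "\n")
            n += 1
        if header is None:
            fh.write(delimiter.join(["gene_i", "gene_j", "intercept"]) + "\n")
    return n


def read_patterns(path: str | Path, delimiter: str = "\t") -> list[CoModulationPattern]:
    """Read a pattern table written by :func:`write_patterns`."""
    df = pd.read_csv(path, sep=delimiter, dtype={"gene_i": str, "gene_j": str})
    beta_cols = [c for c in df.columns if c.startswith("beta_")]
    modulator_ids = tuple(c[len("beta_"):] for c in beta_cols)
    p_cols = [f"p_{m}" for m in modulator_ids]
    missing = [c for c in p_cols if c not in df.columns]
    if missing:
        raise ValueError(f"pattern table missing p-value columns: {missing}")
    out = []
    betas = df[beta_cols].to_numpy(dtype=float)
    pvals = df[p_cols].to_numpy(dtype=float)
    inter = df["intercept"].to_numpy(dtype=float) if "intercept" in df else np.zeros(len(df))
    for r in range(len(df)):
        out.append(
            CoModulationPattern(
                str(df.iloc[r, 0]), str(df.iloc[r, 1]), modulator_ids,
                betas[r], pvals[r], float(inter[r]),
            )
        )
    return out
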