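"""Downstream analysis of co-modulation patterns.

Takes the per-pair regression output and produces the network-level results:
which modulators are significant for which pairs, per-modulator tallies,
grouping of pairs by their exact significant-modulator signature, "core"
subsets under Bonferroni adjustment, node degrees and hub genes within each
group, pairwise modulator co-occurrence (Fisher's exact test), and Wald
confidence intervals for proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regression import CoModulationPattern

__all__ = [
    "SignificanceCalls",
    "ModulationGroup",
    "CoOccurrenceResult",
    "call_significance",
    "modulator_tally",
    "group_by_signature",
    "core_pairs",
    "node_degrees",
    "cooccurrence_test",
    "fisher_2x2",
    "set_overlap_test",
    "proportion_ci",
    "percent",
    "write_group_table",
    "write_cooccurrence_matrix",
    "write_edge_list",
]


def percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage of ``count`` out of ``total``, rounded for reporting."""
    if total < 1:
        raise ValueError("total must be >= 1")
    return round(100.0 * count / total, decimals)


@dataclass
class SignificanceCalls:
    """Boolean significance matrix: one row per gene pair, one column per
    modulator; entry is True iff the modulator's regression p-value is
    strictly below ``alpha``."""

    pairs: list[tuple[str, str]]
    modulator_ids: tuple[str, ...]
    calls: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape != (len(self.pairs), len(self.modulator_ids)):
            raise ValueError("calls must be pairs x modulators")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def per_pair_counts(self) -> np.ndarray:
        """Number of significant modulators of each pair."""
        return self.calls.sum(axis=1)

    def per_modulator_totals(self) -> dict[str, int]:
        """Number of pairs for which each modulator is significant."""
        totals = self.calls.sum(axis=0)
        return {m: int(t) for m, t in zip(self.modulator_ids, totals)}

    def column(self, modulator: str) -> np.ndarray:
        try:
            j = self.modulator_ids.index(modulator)
        except ValueError:
            raise KeyError(f"unknown modulator: {modulator!r}") from None
        return self.calls[:, j]


@dataclass
class ModulationGroup:
    """Gene pairs whose significant-modulator set equals ``signature``.

    The empty signature is the 'modulated by none' group. ``percentage`` is a
    fraction of all pairs analyzed; ``degrees`` maps each member gene to its
    number of partners within the group, so degrees sum to twice the number
    of pairs.
    """

    signature: frozenset[str]
    pairs: list[tuple[str, str]]
    percentage: float
    member_genes: set[str] = field(init=False)
    degrees: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        degrees: dict[str, int] = {}
        for gi, gj in self.pairs:
            degrees[gi] = degrees.get(gi, 0) + 1
            degrees[gj] = degrees.get(gj, 0) + 1
        self.degrees = degrees
        self.member_genes = set(degrees)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def signature_label(self, sep: str = "-") -> str:
        return sep.join(sorted(self.signature)) if self.signature else "none"


@dataclass(frozen=True)
class CoOccurrenceResult:
    """Fisher's exact test of two modulators co-occurring as significant.

    ``table`` counts pairs [[both, a_only], [b_only, neither]];
    ``odds_direction`` compares the both-count with its expectation under
    independent margins.
    """

    modulator_a: str
    modulator_b: str
    table: np.ndarray
    odds_direction: Literal["positive", "negative", "none"]
    pvalue: float


def call_significance(
    patterns: Iterable[CoModulationPattern], alpha: float = 0.05
) -> SignificanceCalls:
    """Threshold each pattern's p-values at ``alpha`` (strict)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    pairs: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    modulator_ids: tuple[str, ...] | None = None
    for pat in patterns:
        if modulator_ids is None:
            modulator_ids = pat.modulator_ids
        elif pat.modulator_ids != modulator_ids:
            raise ValueError("patterns have inconsistent modulator ids")
        pairs.append(pat.pair)
        rows.append(pat.pvalues < alpha)
    if modulator_ids is None:
        modulator_ids = ()
    calls = np.array(rows, dtype=bool) if rows else np.empty((0, len(modulator_ids)), bool)
    return SignificanceCalls(pairs, modulator_ids, calls, alpha)


def modulator_tally(calls: SignificanceCalls, total_pairs: int | None = None) -> pd.DataFrame:
    """Per-modulator counts and percentages of modulated pairs.

    ``total_pairs`` defaults to the number of pairs in ``calls``; percentages
    are rounded to two decimals.
    """
    if total_pairs is None:
        total_pairs = calls.n_pairs
    if total_pairs < 1:
        raise ValueError("total_pairs must be >= 1")
    totals = calls.per_modulator_totals()
    df = pd.DataFrame(
        {
            "modulator": list(calls.modulator_ids),
            "n_pairs": [totals[m] for m in calls.modulator_ids],
        }
    )
    df["fraction"] = df["n_pairs"] / total_pairs
    df["percentage"] = [percent(c, total_pairs) for c in df["n_pairs"]]
    return df.sort_values("n_pairs", ascending=False, kind="stable").reset_index(drop=True)


def group_by_signature(calls: SignificanceCalls) -> list[ModulationGroup]:
    """Partition all pairs by their exact significant-modulator set.

    The partition is exhaustive and disjoint and includes the empty
    signature; groups are sorted by size descending, ties by sorted
    signature.
    """
    buckets: dict[frozenset[str], list[tuple[str, str]]] = {}
    mods = np.array(calls.modulator_ids, dtype=object)
    for pair, row in zip(calls.pairs, calls.calls):
        sig = frozenset(mods[row])
        buckets.setdefault(sig, []).append(pair)
    total = max(calls.n_pairs, 1)
    groups = [
        ModulationGroup(sig, pair_list, percentage=len(pair_list) / total)
        for sig, pair_list in buckets.items()
    ]
    groups.sort(key=lambda g: (-g.n_pairs, sorted(g.signature)))
    return groups


def core_pairs(
    patterns: Iterable[CoModulationPattern],
    signature: Iterable[str],
    family_size: int,
    alpha: float = 0.05,
    rule: Literal["all", "any"] = "all",
) -> list[tuple[str, str]]:
    """Bonferroni-surviving ('core') pairs of one co-modulation group.

    A pattern belongs to the group when its significant set (at ``alpha``)
    equals ``signature`` exactly; it is core when every signature modulator
    (rule='all', default) or at least one (rule='any') satisfies
    ``p * family_size < alpha``. ``family_size`` is the number of tests in
    the Bonferroni family, typically the total number of pairs tested.
    """
    signature = frozenset(signature)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if not signature:
        raise ValueError("core_pairs needs a non-empty signature")
    out: list[tuple[str, str]] = []
    for pat in patterns:
        if pat.significant_set(alpha) != signature:
            continue
        adjusted_ok = [
            p * family_size < alpha
            for m, p in zip(pat.modulator_ids, pat.pvalues)
            if m in signature
        ]
        passed = all(adjusted_ok) if rule == "all" else any(adjusted_ok)
        if passed:
            out.append(pat.pair)
    return out


def node_degrees(
    group: ModulationGroup, top_k: int = 3
) -> tuple[dict[str, int], list[tuple[str, int]]]:
    """Gene degrees within a group's pair graph plus the top-k hubs.

    Hubs are ordered by degree descending, ties broken by gene id.
    """
    degrees = dict(group.degrees)
    hubs = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return degrees, hubs


def fisher_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value of a 2x2 contingency table.

    Two-sided by the point-probability rule: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def cooccurrence_test(
    calls: SignificanceCalls, modulator_a: str, modulator_b: str
) -> CoOccurrenceResult:
    """Do pairs modulated by one modulator tend to be modulated by another?

    Builds the 2x2 table (both / a only / b only / neither) over all pairs
    and applies the two-sided Fisher's exact test. Direction is positive
    (negative) when the observed both-count exceeds (falls short of) its
    expectation under independent margins; a degenerate margin — a modulator
    significant for none or all pairs — yields p = 1 with a warning.
    """
    if modulator_a == modulator_b:
        raise ValueError("co-occurrence requires two distinct modulators")
    a = calls.column(modulator_a)
    b = calls.column(modulator_b)
    n = calls.n_pairs
    both = int(np.sum(a & b))
    a_only = int(np.sum(a & ~b))
    b_only = int(np.sum(~a & b))
    neither = n - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]], dtype=np.int64)

    expected_both = (both + a_only) * (both + b_only) / n if n else 0.0
    if both > expected_both:
        direction: Literal["positive", "negative", "none"] = "positive"
    elif both < expected_both:
        direction = "negative"
    else:
        direction = "none"

    degenerate = (a.sum() in (0, n)) or (b.sum() in (0, n))
    if degenerate:
        warnings.warn(
            f"degenerate margin for {modulator_a!r}/{modulator_b!r}: "
            "co-occurrence test uninformative (p = 1)",
            stacklevel=2,
        )
        return CoOccurrenceResult(modulator_a, modulator_b, table, "none", 1.0)
    return CoOccurrenceResult(modulator_a, modulator_b, table, direction, fisher_2x2(table))


def set_overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> CoOccurrenceResult:
    """Fisher's exact test of the overlap between two gene sets drawn from a
    universe of ``universe_size`` genes (Venn-style comparison)."""
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = universe_size - both - a_only - b_only
    if neither < 0:
        raise ValueError("universe_size smaller than the union of the sets")
    table = np.array([[both, a_only], [b_only, neither]], dtype=np.int64)
    expected = len(set_a) * len(set_b) / universe_size if universe_size else 0.0
    direction: Literal["positive", "negative", "none"]
    direction = "positive" if both > expected else "negative" if both < expected else "none"
    return CoOccurrenceResult("set_a", "set_b", table, direction, fisher_2x2(table))


def proportion_ci(
    p_hat: float, n: int, clip: bool = False
) -> tuple[float, float]:
    """95% Wald confidence interval for a proportion:
    p +/- 1.96 sqrt(p (1-p) / n). Not clipped to [0, 1] unless asked."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = 1.96 * float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    low, high = p_hat - half, p_hat + half
    if clip:
        low, high = max(low, 0.0), min(high, 1.0)
    return (low, high)


# ---------------------------------------------------------------------------
# tabular exports

def write_group_table(
    groups: Sequence[ModulationGroup],
    path: str | Path,
    core: dict[frozenset[str], list[tuple[str, str]]] | None = None,
    top_k: int = 3,
) -> pd.DataFrame:
    """Write a group summary table (one row per signature): size, percentage,
    top hubs with degrees, and — when ``core`` provides Bonferroni-surviving
    pairs per signature — core pair/gene counts."""
    rows = []
    for g in groups:
        _, hubs = node_degrees(g, top_k=top_k)
        row: dict[str, object] = {
            "signature": g.signature_label(),
            "n_pairs": g.n_pairs,
            "percentage": round(100.0 * g.percentage, 2),
            "top_hubs": "; ".join(f"{gene} ({deg})" for gene, deg in hubs),
        }
        if core is not None:
            cp = core.get(g.signature, [])
            row["n_core_pairs"] = len(cp)
            row["n_core_genes"] = len({x for pair in cp for x in pair})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_cooccurrence_matrix(
    results: Sequence[CoOccurrenceResult], path: str | Path
) -> pd.DataFrame:
    """Write a symmetric matrix of signed log10 co-occurrence p-values:
    -log10(p) for positive association, +log10(p) (negative values) for
    negative association, 0 on the diagonal."""
    mods = sorted({r.modulator_a for r in results} | {r.modulator_b for r in results})
    mat = pd.DataFrame(0.0, index=mods, columns=mods)
    for r in results:
        logp = -np.log10(max(r.pvalue, np.finfo(float).tiny))
        signed = logp if r.odds_direction == "positive" else -logp
        if r.odds_direction == "none":
            signed = 0.0
        mat.loc[r.modulator_a, r.modulator_b] = signed
        mat.loc[r.modulator_b, r.modulator_a] = signed
    mat.to_csv(path, sep="\t", index_label="modulator")
    return mat


def write_edge_list(group: ModulationGroup, path: str | Path) -> None:
    """Write a group's pairs as a 2-column TSV edge list for network tools."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\n")
        for gi, gj in group.pairs:
            fh.write(f"{gi}\t{gj}\n")
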