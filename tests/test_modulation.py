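from fractions import Fraction
from math import comb

import numpy as np
import pytest

from comre import (
    call_significance,
    cooccurrence_test,
    core_pairs,
    group_by_signature,
    modulator_tally,
    node_degrees,
    proportion_ci,
)
from comre.modulation import (
    SignificanceCalls,
    fisher_2x2,
    percent,
    set_overlap_test,
)
from comre.regression import CoModulationPattern


def make_pattern(gene_i, gene_j, pvalues, mods=None, betas=None):
    pvalues = np.asarray(pvalues, dtype=float)
    if mods is None:
        mods = tuple(f"M{i}" for i in range(len(pvalues)))
    if betas is None:
        betas = np.zeros(len(pvalues))
    return CoModulationPattern(gene_i, gene_j, tuple(mods), np.asarray(betas, float),
                               pvalues)


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: exact rational hypergeometric enumeration with the
    point-probability rule."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = [Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
             for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return float(sum(p for p in probs if p <= p_obs))


class TestCallSignificance:
    def test_strict_threshold_boundary(self):
        pat = make_pattern("A", "B", [0.04, 0.06, 0.05])
        calls = call_significance([pat], alpha=0.05)
        assert calls.calls[0].tolist() == [True, False, False]

    def test_all_insignificant(self):
        calls = call_significance([make_pattern("A", "B", [1.0, 1.0])])
        assert calls.per_pair_counts().tolist() == [0]

    def test_totals_match_recount(self, rng):
        p = rng.uniform(size=(200, 5))
        pats = [make_pattern(f"A{i}", f"B{i}", p[i]) for i in range(200)]
        calls = call_significance(pats, alpha=0.05)
        totals = calls.per_modulator_totals()
        for j, m in enumerate(calls.modulator_ids):
            assert totals[m] == int((p[:, j] < 0.05).sum())
        np.testing.assert_array_equal(calls.per_pair_counts(),
                                      (p < 0.05).sum(axis=1))

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            call_significance([], alpha=1.5)


class TestTallyAndPercent:
    def test_printed_style_rounding(self):
        assert percent(2_449_249, 14_084_778) == 17.39
        assert percent(0, 14_084_778) == 0.0

    def test_tally_counts_and_order(self):
        pats = [
            make_pattern("A", "B", [0.01, 0.5]),
            make_pattern("A", "C", [0.01, 0.01]),
            make_pattern("B", "C", [0.5, 0.5]),
        ]
        df = modulator_tally(call_significance(pats))
        assert df.iloc[0]["modulator"] == "M0" and df.iloc[0]["n_pairs"] == 2
        assert df.iloc[0]["percentage"] == 66.67


class TestGrouping:
    def test_small_partition(self):
        pats = [
            make_pattern("A", "B", [0.01, 0.5]),
            make_pattern("A", "C", [0.02, 0.9]),
            make_pattern("B", "C", [0.01, 0.01]),
        ]
        groups = group_by_signature(call_significance(pats))
        assert [sorted(g.signature) for g in groups] == [["M0"], ["M0", "M1"]]
        assert groups[0].n_pairs == 2 and groups[1].n_pairs == 1

    def test_all_false_single_empty_group(self):
        pats = [make_pattern(f"A{i}", f"B{i}", [0.9, 0.9]) for i in range(4)]
        groups = group_by_signature(call_significance(pats))
        assert len(groups) == 1
        assert groups[0].signature == frozenset()
        assert groups[0].signature_label() == "none"
        assert groups[0].n_pairs == 4

    def test_random_partition_matches_dict_recount(self, rng):
        calls_matrix = rng.uniform(size=(100, 4)) < 0.3
        pairs = [(f"A{i}", f"B{i}") for i in range(100)]
        mods = ("M0", "M1", "M2", "M3")
        calls = SignificanceCalls(pairs, mods, calls_matrix, 0.05)
        groups = group_by_signature(calls)
        # independent recount
        expected: dict[frozenset, int] = {}
        for row in calls_matrix:
            sig = frozenset(m for m, v in zip(mods, row) if v)
            expected[sig] = expected.get(sig, 0) + 1
        assert {g.signature: g.n_pairs for g in groups} == expected
        assert sum(g.n_pairs for g in groups) == 100
        assert sorted(g.n_pairs for g in groups) == sorted(expected.values())
        for g in groups:
            assert sum(g.degrees.values()) == 2 * g.n_pairs


class TestCorePairs:
    def test_adjusted_arithmetic(self):
        family = 14_084_778
        keep = make_pattern("A", "B", [1e-9, 0.5])
        drop = make_pattern("A", "C", [1e-6, 0.5])
        assert core_pairs([keep, drop], {"M0"}, family) == [("A", "B")]

    def test_random_set_matches_direct_recomputation(self, rng):
        family = 500
        pats = [make_pattern(f"A{i}", f"B{i}", rng.uniform(0, 0.1, 2))
                for i in range(100)]
        got = core_pairs(pats, {"M0"}, family)
        expected = [
            p.pair for p in pats
            if p.significant_set(0.05) == {"M0"} and p.pvalues[0] * family < 0.05
        ]
        assert got == expected

    def test_all_vs_any_rule(self):
        pat = make_pattern("A", "B", [1e-9, 0.01])
        sig = {"M0", "M1"}
        assert core_pairs([pat], sig, 1000, rule="all") == []
        assert core_pairs([pat], sig, 1000, rule="any") == [("A", "B")]


class TestNodeDegrees:
    def test_star_counts(self):
        calls = SignificanceCalls(
            [("A", "B"), ("A", "C")], ("M0",), np.ones((2, 1), bool), 0.05
        )
        group = group_by_signature(calls)[0]
        degrees, hubs = node_degrees(group)
        assert degrees == {"A": 2, "B": 1, "C": 1}
        assert hubs == [("A", 2), ("B", 1), ("C", 1)]  # ties lexicographic

    def test_random_incidence_recount(self, rng):
        genes = [f"G{i}" for i in range(20)]
        pairs = []
        seen = set()
        while len(pairs) < 50:
            i, j = rng.choice(20, 2, replace=False)
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                pairs.append((genes[key[0]], genes[key[1]]))
        calls = SignificanceCalls(pairs, ("M0",), np.ones((50, 1), bool), 0.05)
        group = group_by_signature(calls)[0]
        degrees, _ = node_degrees(group, top_k=5)
        for g in degrees:
            assert degrees[g] == sum(g in p for p in pairs)
        assert sum(degrees.values()) == 100


class TestCooccurrence:
    def make_calls(self, a_col, b_col):
        n = len(a_col)
        calls = np.column_stack([a_col, b_col]).astype(bool)
        pairs = [(f"A{i}", f"B{i}") for i in range(n)]
        return SignificanceCalls(pairs, ("Ma", "Mb"), calls, 0.05)

    def test_perfect_cooccurrence_table(self):
        a = [True] * 10 + [False] * 10
        calls = self.make_calls(a, a)
        res = cooccurrence_test(calls, "Ma", "Mb")
        np.testing.assert_array_equal(res.table, [[10, 0], [0, 10]])
        assert res.odds_direction == "positive"
        # the point-probability rule sums both equally improbable extremes
        # (a=10 and a=0), each with probability 1/C(20,10)
        assert res.pvalue == pytest.approx(2 / comb(20, 10), abs=1e-12)
        assert res.pvalue == pytest.approx(
            exact_fisher_two_sided(10, 0, 0, 10), abs=1e-12
        )

    def test_independent_margins_at_expectation(self):
        # both = 5 equals expectation 10*10/20; direction undefined
        a = [True] * 10 + [False] * 10
        b = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        res = cooccurrence_test(self.make_calls(a, b), "Ma", "Mb")
        assert res.odds_direction == "none"
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_margin_warns(self):
        a = [True] * 10
        b = [True] * 5 + [False] * 5
        with pytest.warns(UserWarning, match="degenerate"):
            res = cooccurrence_test(self.make_calls(a, b), "Ma", "Mb")
        assert res.pvalue == 1.0
        assert res.odds_direction == "none"

    def test_same_modulator_rejected(self):
        calls = self.make_calls([True, False, True], [False, True, True])
        with pytest.raises(ValueError):
            cooccurrence_test(calls, "Ma", "Ma")

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = fisher_2x2([[a, b], [c, d]])
            assert p == pytest.approx(exact_fisher_two_sided(a, b, c, d), abs=1e-12)

    def test_gene_set_overlap(self):
        res = set_overlap_test({"A", "B", "C"}, {"B", "C", "D"}, universe_size=10)
        assert res.table[0, 0] == 2
        assert res.table.sum() == 10
        assert 0.0 <= res.pvalue <= 1.0


class TestProportionCI:
    def test_half_width_examples(self):
        low, high = proportion_ci(0.5, 100)
        assert (low, high) == (pytest.approx(0.402), pytest.approx(0.598))
        assert proportion_ci(0.0, 50) == (0.0, 0.0)
        low, high = proportion_ci(0.25, 64)
        half = 1.96 * np.sqrt(0.25 * 0.75 / 64)
        assert high - low == pytest.approx(2 * half, abs=1e-12)

    def test_clipping(self):
        low, high = proportion_ci(0.99, 10, clip=True)
        assert high == 1.0
        assert proportion_ci(0.99, 10)[1] > 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1.5, 10)
        with pytest.raises(ValueError):
            proportion_ci(0.5, 0)
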