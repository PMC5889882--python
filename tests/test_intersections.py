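"""Exclusive-intersection semantics, sharing fractions, category matrices."""

from __future__ import annotations

import numpy as np
import pytest

from lncpair import (
    PairRecord,
    RegulatedPair,
    category_counts,
    exclusive_intersections,
    membership_sets,
    read_category_map,
    shared_fraction,
    top_intersections,
)

from .oracles import oracle_exclusive_intersections


def _table_to_dict(table):
    return dict(zip(table["subset"], table["count"]))


def test_single_comparison_exclusive_cell():
    table = exclusive_intersections({"U15/L15": {"a", "b"}})
    assert _table_to_dict(table) == {frozenset({"U15/L15"}): 2}


def test_pair_in_two_of_three_comparisons_counts_only_in_the_two_set_cell():
    """An item called in U15/L15 and U6/L6 but not Aer/Rt belongs to the
    two-set exclusive cell only, never to the singletons."""
    calls = {"U15/L15": {"p1"}, "U6/L6": {"p1"}, "Aer/Rt": set()}
    d = _table_to_dict(exclusive_intersections(calls))
    assert d == {frozenset({"U15/L15", "U6/L6"}): 1}


def test_unknown_comparison_name_rejected():
    with pytest.raises(ValueError, match="unknown"):
        exclusive_intersections({"bogus": {"a"}}, known_comparisons=["U15/L15"])


def test_matches_brute_force_on_random_memberships(rng):
    names = ["U15/L15", "U6/L6", "Aer/Rt"]
    for trial in range(20):
        items = [f"p{i}" for i in range(30)]
        calls = {n: {i for i in items if rng.random() < 0.5} for n in names}
        got = _table_to_dict(exclusive_intersections(calls))
        assert got == oracle_exclusive_intersections(calls)


def test_conservation_sum_equals_distinct_items(rng):
    """Exclusive cells partition the once-called universe: their counts sum
    to the number of distinct items (100 random instances)."""
    for trial in range(100):
        k = int(rng.integers(1, 5))
        names = [f"c{j}" for j in range(k)]
        items = [f"p{i}" for i in range(int(rng.integers(0, 40)))]
        calls = {n: {i for i in items if rng.random() < 0.4} for n in names}
        table = exclusive_intersections(calls)
        distinct = len(set().union(*calls.values()))
        assert table["count"].sum() == distinct


def test_coarsening_two_comparisons_merges_cells(rng):
    """Collapsing comparisons A and B into one pooled comparison preserves
    item membership semantics: the merged table equals the table computed on
    the pooled sets directly."""
    items = [f"p{i}" for i in range(40)]
    calls = {n: {i for i in items if rng.random() < 0.4}
             for n in ("A", "B", "C")}
    pooled = {"AB": calls["A"] | calls["B"], "C": calls["C"]}
    direct = _table_to_dict(exclusive_intersections(pooled))
    # coarsen the fine table by renaming A and B to AB in each subset
    coarse: dict[frozenset, int] = {}
    fine = exclusive_intersections(calls)
    for subset, count in zip(fine["subset"], fine["count"]):
        renamed = frozenset("AB" if s in ("A", "B") else s for s in subset)
        coarse[renamed] = coarse.get(renamed, 0) + count
    assert coarse == direct


def test_top_intersections_is_a_display_filter_only():
    calls = {"A": {"1", "2", "3"}, "B": {"3", "4"}, "C": {"5"}}
    table = exclusive_intersections(calls)
    top = top_intersections(table, 2)
    assert len(top) <= len(table)
    assert top["count"].tolist() == sorted(table["count"], reverse=True)[:len(top)]


class TestSharedFraction:
    def test_identical_sets(self):
        sf = shared_fraction({"a": {1, 2}, "b": {1, 2}}, "a", "b")
        assert sf.jaccard == 1.0 and sf.fraction_of_a == 1.0

    def test_disjoint_sets(self):
        sf = shared_fraction({"a": {1}, "b": {2}}, "a", "b")
        assert sf.jaccard == 0.0 and sf.fraction_of_a == 0.0

    def test_planted_jaccard_recovered_exactly(self):
        """A cohort built with 14 shared of 100 total items yields 0.14."""
        shared = {f"s{i}" for i in range(14)}
        only_a = {f"a{i}" for i in range(43)}
        only_b = {f"b{i}" for i in range(43)}
        sf = shared_fraction({"a": shared | only_a, "b": shared | only_b},
                             "a", "b")
        assert sf.jaccard == pytest.approx(0.14)
        assert sf.fraction_of_a == pytest.approx(14 / 57)

    def test_empty_union_flagged(self):
        sf = shared_fraction({"a": set(), "b": set()}, "a", "b")
        assert not sf.defined and sf.jaccard is None

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError):
            shared_fraction({"a": {1}}, "a", "b")


def _reg(gene, call, comparison, lnc="l1"):
    return RegulatedPair(PairRecord(lnc, gene, "asOver", 0), comparison,
                         1.0, 1.0, 0.01, 0.01, call)


class TestCategoryMatrix:
    def test_simple_tally(self):
        regs = [_reg("g1", "antiregulated", "U6/L6"),
                _reg("g2", "coregulated", "U6/L6")]
        m = category_counts(regs, {"g1": ("translation",),
                                   "g2": ("translation",)})
        assert m.loc["translation", ("U6/L6", "antiregulated")] == 1
        assert m.loc["translation", ("U6/L6", "coregulated")] == 1

    def test_gene_in_two_categories_contributes_to_both_rows(self):
        regs = [_reg("g1", "antiregulated", "U6/L6")]
        m = category_counts(regs, {"g1": ("translation", "cell cycle")})
        assert m.loc["translation", ("U6/L6", "antiregulated")] == 1
        assert m.loc["cell cycle", ("U6/L6", "antiregulated")] == 1

    def test_unmapped_gene_falls_into_unassigned(self):
        regs = [_reg("gX", "coregulated", "Aer/Rt")]
        m = category_counts(regs, {})
        assert m.loc["unassigned", ("Aer/Rt", "coregulated")] == 1

    def test_distinct_genes_counted_once_per_cell(self):
        regs = [_reg("g1", "antiregulated", "U6/L6", lnc="l1"),
                _reg("g1", "antiregulated", "U6/L6", lnc="l2")]
        m = category_counts(regs, {"g1": ("meiosis",)})
        assert m.loc["meiosis", ("U6/L6", "antiregulated")] == 1

    def test_matches_direct_tally_on_random_cohort(self, rng):
        cats = ["translation", "cell cycle", "meiosis", "cell wall"]
        cmap = {f"g{i}": tuple(
            c for c in cats if rng.random() < 0.4) or ("translation",)
            for i in range(30)}
        regs = []
        for i in range(30):
            for comparison in ("U6/L6", "Aer/Rt"):
                call = ["antiregulated", "coregulated", "not_called"][
                    int(rng.integers(0, 3))]
                regs.append(_reg(f"g{i}", call, comparison, lnc=f"l{i}"))
        m = category_counts(regs, cmap)
        # brute-force tally
        for cat in m.index:
            for (comparison, call) in m.columns:
                genes = {r.pair.gene_id for r in regs
                         if r.call == call and r.comparison == comparison
                         and cat in cmap.get(r.pair.gene_id, ("unassigned",))}
                assert m.loc[cat, (comparison, call)] == len(genes)

    def test_deterministic_ordering(self):
        regs = [_reg("g1", "antiregulated", "U6/L6"),
                _reg("g2", "coregulated", "Aer/Rt")]
        cmap = {"g1": ("b-cat",), "g2": ("a-cat",)}
        m = category_counts(regs, cmap)
        assert list(m.index) == sorted(m.index)
        assert list(m.columns) == sorted(m.columns)


def test_read_category_map(tmp_path):
    path = tmp_path / "cats.tsv"
    path.write_text("g1\ttranslation\ng1\tcell cycle\ng2\tmeiosis\n")
    cmap = read_category_map(path)
    assert cmap == {"g1": ("translation", "cell cycle"), "g2": ("meiosis",)}


def test_membership_sets_inversion():
    calls = {"A": {"x", "y"}, "B": {"y"}}
    assert membership_sets(calls) == {"x": frozenset({"A"}),
                                      "y": frozenset({"A", "B"})}
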