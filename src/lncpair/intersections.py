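"""Exclusive (UpSet-style "distinct" mode) intersections of regulated-pair
sets across comparisons, pairwise sharing statistics, and functional-category
count matrices.

An *exclusive intersection* counts the items whose comparison-membership set
equals exactly a given subset: an item called in U15/L15 and U6/L6 but not in
Aer/Rt contributes only to the {U15/L15, U6/L6} cell, never to the singleton
cells. Exclusive cells therefore partition the universe of items called at
least once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .regulation import RegulatedPair


@dataclass(frozen=True)
class SharedFraction:
    """Pairwise sharing between two comparisons' sets, under two labels:
    Jaccard (|A∩B| / |A∪B|) and the asymmetric fraction |A∩B| / |A|."""

    jaccard: Optional[float]
    fraction_of_a: Optional[float]
    intersection: int
    union: int
    size_a: int
    defined: bool = True


def membership_sets(
    calls: Mapping[str, Iterable[Hashable]],
) -> dict[Hashable, frozenset[str]]:
    """Invert per-comparison item sets into item -> set of comparisons."""
    out: dict[Hashable, set[str]] = {}
    for comparison, items in calls.items():
        for item in items:
            out.setdefault(item, set()).add(comparison)
    return {item: frozenset(s) for item, s in out.items()}


def exclusive_intersections(
    calls: Mapping[str, Iterable[Hashable]],
    known_comparisons: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Exclusive-intersection table over per-comparison item sets.

    Parameters
    ----------
    calls:
        Mapping of comparison name to the set of item ids (pair keys or
        gene ids) called in that comparison.
    known_comparisons:
        If given, any comparison name outside this set is an error.

    Returns
    -------
    DataFrame with one row per *nonempty* observed subset, columns
    ``subset`` (frozenset), ``degree`` and ``count``, sorted by descending
    count then subset name. Counts over all rows sum to the number of
    distinct items called at least once.
    """
    if not calls:
        raise ValueError("at least one comparison required")
    if known_comparisons is not None:
        unknown = set(calls) - set(known_comparisons)
        if unknown:
            raise ValueError(f"unknown comparison name(s): {sorted(unknown)}")
    members = membership_sets(calls)
    tally: dict[frozenset[str], int] = {}
    for subset in members.values():
        tally[subset] = tally.get(subset, 0) + 1
    rows = [
        {"subset": s, "degree": len(s), "count": n}
        for s, n in tally.items()
    ]
    df = pd.DataFrame(rows, columns=["subset", "degree", "count"])
    if len(df):
        df["_key"] = df["subset"].map(lambda s: "&".join(sorted(s)))
        df = (df.sort_values(["count", "_key"], ascending=[False, True])
                .drop(columns="_key").reset_index(drop=True))
    return df


def top_intersections(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Display filter: the k largest exclusive cells (the full table is
    always computed; only the view is truncated)."""
    return table.nlargest(k, "count", keep="all").reset_index(drop=True)


def shared_fraction(
    calls: Mapping[str, Iterable[Hashable]],
    a: str,
    b: str,
) -> SharedFraction:
    """Sharing statistics between two comparisons' call sets."""
    for name in (a, b):
        if name not in calls:
            raise ValueError(f"comparison {name!r} not present")
    set_a, set_b = set(calls[a]), set(calls[b])
    inter, union = len(set_a & set_b), len(set_a | set_b)
    if union == 0:
        return SharedFraction(None, None, 0, 0, 0, defined=False)
    frac_a = len(set_a & set_b) / len(set_a) if set_a else None
    return SharedFraction(inter / union, frac_a, inter, union, len(set_a))


def pair_key(r: RegulatedPair, mode: str = "gene") -> Hashable:
    """Identity of a pair for cross-comparison matching.

    ``mode="gene"`` matches by gene id only (the default: DE gene sets are
    what gets compared across comparisons); ``mode="pair"`` matches by
    (lnc_id, gene_id). Orientation is never part of the identity.
    """
    if mode == "gene":
        return r.pair.gene_id
    if mode == "pair":
        return (r.pair.lnc_id, r.pair.gene_id)
    raise ValueError(f"unknown pair identity mode {mode!r}")


def call_sets(
    regulated: Iterable[RegulatedPair],
    call: str,
    mode: str = "gene",
) -> dict[str, set[Hashable]]:
    """Per-comparison sets of item ids with the given call."""
    out: dict[str, set[Hashable]] = {}
    for r in regulated:
        out.setdefault(r.comparison, set())
        if r.call == call:
            out[r.comparison].add(pair_key(r, mode))
    return out


def category_counts(
    regulated: Iterable[RegulatedPair],
    category_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Functional-category count matrix.

    Rows are categories (plus ``unassigned`` for unmapped genes), columns a
    (comparison, call) MultiIndex; each cell counts the distinct genes in
    that category with that call in that comparison. A gene in k categories
    contributes to k rows, so column totals can exceed the number of
    distinct genes. Rows sort by category name, columns by comparison then
    call — the matrix is deterministic.
    """
    cells: dict[tuple[str, str, str], set[str]] = {}
    for r in regulated:
        if r.call not in ("antiregulated", "coregulated"):
            continue
        cats = category_map.get(r.pair.gene_id) or ("unassigned",)
        for cat in cats:
            cells.setdefault((cat, r.comparison, r.call), set()).add(r.pair.gene_id)
    if not cells:
        return pd.DataFrame()
    rows = [
        {"category": cat, "comparison": comp, "call": call, "count": len(genes)}
        for (cat, comp, call), genes in cells.items()
    ]
    df = pd.DataFrame(rows)
    matrix = df.pivot_table(index="category", columns=["comparison", "call"],
                            values="count", fill_value=0, aggfunc="sum")
    return matrix.sort_index(axis=0).sort_index(axis=1)


def read_category_map(path) -> dict[str, tuple[str, ...]]:
    """Read a gene -> categories TSV (gene_id<TAB>category, one row per
    membership; a gene may appear on several rows)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"],
                     dtype=str, comment="#")
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.gene_id, []).append(r.category)
    return {g: tuple(c) for g, c in out.items()}


def intersections_to_tsv(table: pd.DataFrame, path) -> None:
    """Write an intersection table with the subset rendered as 'A&B' labels."""
    out = table.copy()
    out["subset"] = out["subset"].map(lambda s: "&".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)
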