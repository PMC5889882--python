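"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive every quantity from first principles with the
simplest possible logic (all-vs-all loops, "pointing" rules, full subset
enumeration) and never call the code paths they verify.
"""

from __future__ import annotations

from itertools import chain, combinations
from typing import Hashable, Iterable, Mapping

from lncpair import GenomicFeature


def _points_toward(a: GenomicFeature, b: GenomicFeature) -> bool:
    """True if reading a in its transcription direction heads toward b
    (for non-overlapping intervals)."""
    if a.strand == "+":
        return b.start >= a.end
    return b.end <= a.start


def oracle_orientation(lnc: GenomicFeature, gene: GenomicFeature) -> str:
    """Case-table orientation classification via the 'pointing' rule."""
    assert lnc.chrom == gene.chrom
    ov = min(lnc.end, gene.end) - max(lnc.start, gene.start)
    if lnc.strand != gene.strand:
        if ov >= 1:
            return "asOver"
        if _points_toward(lnc, gene) and _points_toward(gene, lnc):
            return "asConv"
        return "asDiv"
    if ov >= 1:
        # sense overlap: upstream-like when the lncRNA 5' end is not past
        # the gene 5' end in the gene's reading direction
        if gene.strand == "+":
            return "tandem5" if lnc.five_prime <= gene.five_prime else "tandem3"
        return "tandem5" if lnc.five_prime >= gene.five_prime else "tandem3"
    # non-overlapping same strand: upstream iff the gene "reads away" from
    # the lncRNA, i.e. the lncRNA precedes the gene 5' end
    if gene.strand == "+":
        return "tandem5" if lnc.end <= gene.start else "tandem3"
    return "tandem5" if lnc.start >= gene.end else "tandem3"


def oracle_pairs(features: Iterable[GenomicFeature], window: int = 1500,
                 min_overlap: int = 1) -> set[tuple[str, str]]:
    """All-vs-all O(n^2) enumeration of qualifying (lnc_id, gene_id) pairs."""
    feats = list(features)
    out = set()
    for lnc in feats:
        if lnc.role != "lncRNA":
            continue
        for gene in feats:
            if gene.role != "gene" or gene.chrom != lnc.chrom:
                continue
            ov = min(lnc.end, gene.end) - max(lnc.start, gene.start)
            gap = max(0, max(lnc.start, gene.start) - min(lnc.end, gene.end))
            if ov >= min_overlap or gap <= window:
                out.add((lnc.feature_id, gene.feature_id))
    return out


def oracle_exclusive_intersections(
    calls: Mapping[str, Iterable[Hashable]],
) -> dict[frozenset[str], int]:
    """Count items per exact membership subset by enumerating all subsets."""
    names = sorted(calls)
    sets = {n: set(calls[n]) for n in names}
    universe = set().union(*sets.values()) if sets else set()
    out: dict[frozenset[str], int] = {}
    subsets = chain.from_iterable(
        combinations(names, r) for r in range(1, len(names) + 1))
    for subset in subsets:
        inside, outside = set(subset), set(names) - set(subset)
        n = sum(
            1 for item in universe
            if all(item in sets[s] for s in inside)
            and not any(item in sets[s] for s in outside)
        )
        if n:
            out[frozenset(subset)] = n
    return out
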