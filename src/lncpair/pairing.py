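"""Enumerate lncRNA/gene neighbor pairs and classify their mutual orientation.

A lncRNA and a gene form a pair when they lie on the same chromosome and
either overlap on opposite strands (antisense overlap) or are separated by at
most a configurable gap (1.5 kb by default, the window used in yeast colony
subpopulation studies). Each pair falls into exactly one of five orientation
categories:

========  ==================================================================
asOver    antisense-overlapping: opposite strands, intervals share >= 1 bp
asConv    antisense-convergent: opposite strands, no overlap, 3' ends face
          each other across the gap (the '+' member lies left of the '-')
asDiv     antisense-divergent: opposite strands, no overlap, 5' ends face
          each other (the '-' member lies left of the '+'); typical of
          bidirectional promoters
tandem5   same strand, lncRNA upstream (5'-ward) of the gene in the gene's
          reading direction
tandem3   same strand, lncRNA downstream (3'-ward) of the gene
========  ==================================================================

Same-strand *overlapping* pairs are not one of the five headline categories;
they are classified tandem5/tandem3 by the relative position of the lncRNA's
5' end and flagged ``sense_overlap`` so they can be filtered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .features import GenomicFeature

ORIENTATIONS = ("asOver", "asConv", "asDiv", "tandem5", "tandem3")


@dataclass(frozen=True)
class PairingConfig:
    """Window and overlap settings for pair enumeration.

    ``window_bp`` bounds the edge-to-edge gap between the two intervals
    ("within 1.5 kb" = gap <= 1500, a closed bound). ``min_overlap_bp`` is
    the minimal shared length for a pair to count as overlapping; abutting
    intervals have gap 0 and are non-overlapping.
    """

    window_bp: int = 1500
    min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")


@dataclass(frozen=True)
class PairRecord:
    """One lncRNA/gene pair with its orientation category and gap.

    ``gap_bp`` is the edge-to-edge distance (0 iff the intervals overlap or
    abut). ``sense_overlap`` marks same-strand overlapping pairs, which the
    five-category scheme does not cover natively.
    """

    lnc_id: str
    gene_id: str
    orientation: str
    gap_bp: int
    sense_overlap: bool = False


def overlap_bp(a: GenomicFeature, b: GenomicFeature) -> int:
    """Shared length of two intervals on the same chromosome (<= 0 if none)."""
    return min(a.end, b.end) - max(a.start, b.start)


def gap_bp(a: GenomicFeature, b: GenomicFeature) -> int:
    """Edge-to-edge gap; 0 for overlapping or abutting intervals."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_orientation(
    lnc: GenomicFeature,
    gene: GenomicFeature,
    config: PairingConfig = PairingConfig(),
) -> tuple[str, bool]:
    """Classify a same-chromosome lncRNA/gene pair into one orientation.

    Returns ``(orientation, sense_overlap)``. The classification is a total
    function of coordinates and strands: every stranded pair receives
    exactly one category.

    Raises
    ------
    ValueError
        If the features sit on different chromosomes (callers must
        pre-filter; there is no inter-chromosomal pairing).
    """
    if lnc.chrom != gene.chrom:
        raise ValueError(
            f"cannot classify {lnc.feature_id!r}/{gene.feature_id!r}: "
            f"different chromosomes ({lnc.chrom} vs {gene.chrom})"
        )
    ov = overlap_bp(lnc, gene)
    overlapping = ov >= config.min_overlap_bp

    if lnc.strand != gene.strand:
        if overlapping:
            return "asOver", False
        # Non-overlapping antisense pair: the category is decided solely by
        # which strand lies left. '+' left of '-' means both read toward the
        # gap (3' ends flank it) -> convergent; the mirror case means both
        # read away from the gap (5' ends flank it) -> divergent.
        plus, minus = (lnc, gene) if lnc.strand == "+" else (gene, lnc)
        return ("asConv" if plus.start < minus.start else "asDiv"), False

    # same strand
    if overlapping:
        # Sense overlap: fall back to the relative 5' positions; a 5'-ward
        # lncRNA is "upstream-like". Ties resolve to tandem5.
        if gene.strand == "+":
            upstream = lnc.five_prime <= gene.five_prime
        else:
            upstream = lnc.five_prime >= gene.five_prime
        return ("tandem5" if upstream else "tandem3"), True
    if gene.strand == "+":
        upstream = lnc.end <= gene.start
    else:
        upstream = lnc.start >= gene.end
    return ("tandem5" if upstream else "tandem3"), False


def find_pairs(
    features: Iterable[GenomicFeature],
    config: PairingConfig = PairingConfig(),
) -> list[PairRecord]:
    """Enumerate every qualifying (lncRNA, gene) pair.

    A pair qualifies when both features share a chromosome and either
    overlap by at least ``config.min_overlap_bp`` or have an edge-to-edge
    gap of at most ``config.window_bp``. All qualifying genes are kept for
    each lncRNA (no nearest-only reduction); each pair appears once.
    Uses an interval tree per chromosome, so runtime is near-linear in the
    number of features for sparse annotations.
    """
    feats = list(features)
    lncs = [f for f in feats if f.role == "lncRNA"]
    genes = [f for f in feats if f.role == "gene"]

    trees: dict[str, IntervalTree] = {}
    gene_by_id: dict[str, GenomicFeature] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.feature_id)
        gene_by_id[g.feature_id] = g

    pairs: list[PairRecord] = []
    for lnc in lncs:
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        # Window query: any gene whose interval intersects the lncRNA
        # extended by window_bp on both sides is a candidate.
        hits = tree.overlap(lnc.start - config.window_bp - 1,
                            lnc.end + config.window_bp + 1)
        for hit in sorted(hits, key=lambda h: (h.begin, h.data)):
            gene = gene_by_id[hit.data]
            ov = overlap_bp(lnc, gene)
            gp = gap_bp(lnc, gene)
            if ov >= config.min_overlap_bp or (ov < config.min_overlap_bp
                                               and gp <= config.window_bp):
                orientation, sense_ov = classify_orientation(lnc, gene, config)
                pairs.append(PairRecord(lnc.feature_id, gene.feature_id,
                                        orientation, gp, sense_ov))
    return pairs


def pairs_to_frame(pairs: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "gene_id": p.gene_id,
                "orientation": p.orientation,
                "gap_bp": p.gap_bp,
                "sense_overlap": p.sense_overlap,
            }
            for p in pairs
        ],
        columns=["lnc_id", "gene_id", "orientation", "gap_bp", "sense_overlap"],
    )


def write_pairs(pairs: Sequence[PairRecord], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[PairRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "gene_id": str})
    return [
        PairRecord(r.lnc_id, r.gene_id, r.orientation, int(r.gap_bp),
                   bool(r.sense_overlap))
        for r in df.itertuples(index=False)
    ]
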