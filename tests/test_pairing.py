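"""Orientation classification and pair enumeration against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncpair import (
    GenomicFeature,
    PairingConfig,
    classify_orientation,
    find_pairs,
)
from lncpair.pairing import ORIENTATIONS, gap_bp, overlap_bp

from .oracles import oracle_orientation, oracle_pairs
from .conftest import random_feature


@pytest.mark.parametrize(
    "lnc_coords, gene_coords, expected",
    [
        # opposite strands sharing 200 bases
        ((100, 500, "+"), (300, 800, "-"), "asOver"),
        # '+' on the left and '-' on the right necessarily point toward each other
        ((100, 500, "+"), (700, 1200, "-"), "asConv"),
        # 5' ends flank the gap
        ((700, 1200, "+"), (100, 500, "-"), "asDiv"),
        # gene reads rightward; lncRNA upstream / downstream
        ((100, 500, "+"), (700, 1200, "+"), "tandem5"),
        ((700, 1200, "+"), (100, 500, "+"), "tandem3"),
        # mirror of tandem5 under strand flip: lncRNA left of a leftward-
        # reading gene is downstream
        ((100, 500, "-"), (700, 1200, "-"), "tandem3"),
        ((700, 1200, "-"), (100, 500, "-"), "tandem5"),
    ],
)
def test_orientation_case_table(feat, lnc_coords, gene_coords, expected):
    lnc = feat("l", *lnc_coords, role="lncRNA")
    gene = feat("g", *gene_coords)
    orientation, sense_ov = classify_orientation(lnc, gene)
    assert orientation == expected
    assert not sense_ov
    assert oracle_orientation(lnc, gene) == expected


def test_sense_overlap_flagged_and_classified_by_five_prime(feat):
    lnc = feat("l", 100, 600, "+", role="lncRNA")
    gene = feat("g", 300, 900, "+")
    orientation, sense_ov = classify_orientation(lnc, gene)
    assert sense_ov
    assert orientation == "tandem5"  # lnc 5' (100) precedes gene 5' (300)
    orientation, sense_ov = classify_orientation(lnc, feat("g2", 50, 400, "+"))
    assert sense_ov and orientation == "tandem3"


def test_different_chromosomes_rejected(feat):
    lnc = feat("l", 0, 100, "+", role="lncRNA", chrom="chrI")
    gene = feat("g", 0, 100, "-", chrom="chrII")
    with pytest.raises(ValueError, match="chromosome"):
        classify_orientation(lnc, gene)


def test_classifier_matches_oracle_on_random_pairs(rng):
    """Exhaustive randomized cross-check: the classifier agrees with the
    independent case-table oracle and returns exactly one category."""
    for i in range(5_000):
        lnc = random_feature(rng, "l", "lncRNA", span=5_000, max_len=1_500)
        gene = random_feature(rng, "g", "gene", span=5_000, max_len=1_500)
        orientation, _ = classify_orientation(lnc, gene)
        assert orientation in ORIENTATIONS
        assert orientation == oracle_orientation(lnc, gene), (lnc, gene)


coord = st.integers(min_value=0, max_value=8_000)
length = st.integers(min_value=1, max_value=2_500)
strand = st.sampled_from("+-")


@settings(max_examples=300, derandomize=True)
@given(ls=coord, ll=length, lst=strand, gs=coord, gl=length, gst=strand)
def test_orientation_total_and_exclusive(ls, ll, lst, gs, gl, gst):
    """Every stranded same-chromosome pair gets exactly one of the five
    categories (the classifier is a total function)."""
    lnc = GenomicFeature("l", "chrI", ls, ls + ll, lst, "lncRNA", "SUT")
    gene = GenomicFeature("g", "chrI", gs, gs + gl, gst, "gene")
    orientation, _ = classify_orientation(lnc, gene)
    assert orientation in ORIENTATIONS


@settings(max_examples=300, derandomize=True)
@given(ls=coord, ll=length, lst=strand, gs=coord, gl=length, gst=strand,
       pivot=st.integers(min_value=20_000, max_value=40_000))
def test_strand_flip_reflection_invariance(ls, ll, lst, gs, gl, gst, pivot):
    """Flipping both strands while reflecting coordinates about any pivot
    preserves the category: upstream stays upstream, convergent stays
    convergent."""
    flip = {"+": "-", "-": "+"}
    lnc = GenomicFeature("l", "chrI", ls, ls + ll, lst, "lncRNA", "SUT")
    gene = GenomicFeature("g", "chrI", gs, gs + gl, gst, "gene")
    lnc_m = GenomicFeature("l", "chrI", pivot - lnc.end, pivot - lnc.start,
                           flip[lst], "lncRNA", "SUT")
    gene_m = GenomicFeature("g", "chrI", pivot - gene.end, pivot - gene.start,
                            flip[gst], "gene")
    assert classify_orientation(lnc, gene) == classify_orientation(lnc_m, gene_m)


def test_asconv_asdiv_decided_by_left_strand(feat):
    """On opposite strands without overlap the category depends only on
    which strand lies left, whatever the gap."""
    for gap in (0, 1, 400, 1500):
        lnc = feat("l", 100, 500, "+", role="lncRNA")
        gene = feat("g", 500 + gap, 900 + gap, "-")
        assert classify_orientation(lnc, gene)[0] == "asConv"
        lnc2 = feat("l", 500 + gap, 900 + gap, "+", role="lncRNA")
        gene2 = feat("g", 100, 500, "-")
        assert classify_orientation(lnc2, gene2)[0] == "asDiv"


class TestFindPairs:
    def test_two_genes_within_window(self, feat):
        feats = [
            feat("l", 1000, 1400, "+", role="lncRNA"),
            feat("g1", 1600, 2000, "+"),   # gap 200
            feat("g2", 3400 - 600, 3400, "-", chrom="chrI"),  # overlapping? no:
        ]
        feats[2] = feat("g2", 2800, 3400, "-")  # gap 1400
        pairs = find_pairs(feats)
        assert {(p.lnc_id, p.gene_id) for p in pairs} == {("l", "g1"), ("l", "g2")}

    def test_window_boundary_inclusive_at_1500(self, feat):
        lnc = feat("l", 0, 400, "+", role="lncRNA")
        at_edge = feat("g_in", 1900, 2400, "+")    # gap exactly 1500
        beyond = feat("g_out", 1901, 2401, "+")    # gap 1501
        assert {p.gene_id for p in find_pairs([lnc, at_edge])} == {"g_in"}
        assert find_pairs([lnc, beyond]) == []

    def test_abutting_counts_as_gap_zero_not_overlap(self, feat):
        lnc = feat("l", 0, 400, "+", role="lncRNA")
        gene = feat("g", 400, 800, "-")
        (pair,) = find_pairs([lnc, gene])
        assert pair.gap_bp == 0
        assert pair.orientation == "asConv"  # non-overlapping antisense

    def test_matches_brute_force_on_random_features(self, rng):
        for trial in range(10):
            feats = []
            for i in range(25):
                chrom = f"chr{rng.integers(1, 4)}"
                role = "lncRNA" if rng.random() < 0.4 else "gene"
                feats.append(random_feature(rng, f"f{trial}_{i}", role,
                                            chrom=chrom, span=15_000))
            got = {(p.lnc_id, p.gene_id) for p in find_pairs(feats)}
            assert got == oracle_pairs(feats)

    def test_each_pair_appears_once(self, rng):
        feats = [random_feature(rng, f"f{i}", "lncRNA" if i % 2 else "gene",
                                span=6_000) for i in range(40)]
        pairs = find_pairs(feats)
        keys = [(p.lnc_id, p.gene_id) for p in pairs]
        assert len(keys) == len(set(keys))

    def test_gap_never_exceeds_window_unless_overlapping(self, rng):
        feats = [random_feature(rng, f"f{i}", "lncRNA" if i % 3 == 0 else "gene",
                                span=30_000) for i in range(60)]
        for p in find_pairs(feats, PairingConfig(window_bp=800)):
            assert p.gap_bp <= 800


def test_pairing_config_validation():
    with pytest.raises(ValueError):
        PairingConfig(window_bp=-1)
    with pytest.raises(ValueError):
        PairingConfig(min_overlap_bp=0)


def test_gap_and_overlap_helpers(feat):
    a = feat("a", 100, 500, "+")
    b = feat("b", 450, 900, "-")
    assert overlap_bp(a, b) == 50
    assert gap_bp(a, b) == 0
    c = feat("c", 700, 900, "-")
    assert overlap_bp(a, c) == -200
    assert gap_bp(a, c) == 200
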