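"""Classify lncRNA/gene pair orientations from raw stranded intervals.

Builds five tiny hand-placed pairs — one per orientation category — and
prints the category and gap the classifier derives from coordinates and
strands alone.
"""

from lncpair import GenomicFeature, classify_orientation
from lncpair.pairing import gap_bp

cases = [
    ("antisense pair sharing 200 bp",
     GenomicFeature("lnc-a", "chrI", 100, 500, "+", "lncRNA", "SUT"),
     GenomicFeature("gene-a", "chrI", 300, 800, "-", "gene")),
    ("antisense pair reading toward each other",
     GenomicFeature("lnc-b", "chrI", 100, 500, "+", "lncRNA", "CUT"),
     GenomicFeature("gene-b", "chrI", 700, 1200, "-", "gene")),
    ("antisense pair reading apart (shared promoter region)",
     GenomicFeature("lnc-c", "chrI", 700, 1200, "+", "lncRNA", "SUT"),
     GenomicFeature("gene-c", "chrI", 100, 500, "-", "gene")),
    ("same strand, lncRNA upstream of the gene",
     GenomicFeature("lnc-d", "chrI", 100, 500, "+", "lncRNA", "MUT"),
     GenomicFeature("gene-d", "chrI", 700, 1200, "+", "gene")),
    ("same strand, lncRNA downstream of the gene",
     GenomicFeature("lnc-e", "chrI", 700, 1200, "+", "lncRNA", "XUT"),
     GenomicFeature("gene-e", "chrI", 100, 500, "+", "gene")),
]

for description, lnc, gene in cases:
    orientation, sense_overlap = classify_orientation(lnc, gene)
    print(f"{orientation:8s} gap={gap_bp(lnc, gene):4d} bp  <- {description}")

print()
print("asOver/asConv/asDiv are the antisense categories; tandem5/tandem3")
print("place a same-strand lncRNA up- or downstream in the gene's reading")
print("direction. Exactly one category applies to every stranded pair.")
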