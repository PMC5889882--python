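# Methods

## Coordinate and orientation model

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the I/O boundary (GFF3 start *s*, end *e* →
(*s* − 1, *e*)), BED passes through unchanged. A single internal convention
removes off-by-one risk from gap arithmetic. Unstranded features are
rejected outright because every downstream classification depends on
strand; empty intervals are likewise rejected.

Two intervals' **gap** is the edge-to-edge distance, 0 when they overlap or
abut; abutting intervals (gap 0, overlap 0) count as *non-overlapping*.
"Within 1.5 kb" is implemented as the closed bound gap ≤ 1500; a gene at
gap 1500 pairs, at 1501 it does not. The window is measured edge-to-edge.
A TSS-to-TSS variant was considered and deliberately not implemented as a
validated mode: promoter-anchored distances need a TSS model that plain
interval annotations do not carry.

The orientation classifier is a total function of coordinates and strands:

- opposite strands, overlap ≥ `min_overlap_bp` (default 1) → `asOver`;
- opposite strands, no overlap: the category depends only on which strand
  lies left. '+' left of '−' means both read toward the gap → `asConv`;
  the mirror arrangement reads apart → `asDiv`. No mixed case exists.
- same strand, no overlap: `tandem5` when the lncRNA is upstream of the
  gene in the gene's reading direction, else `tandem3`.
- same strand **with** overlap is not one of the five field categories. To
  keep the classifier total without inventing a sixth headline category,
  such pairs are classified by the lncRNA's 5′ end relative to the gene's
  5′ end (5′-ward → `tandem5`, else `tandem3`; an exact 5′ tie resolves to
  `tandem5`) and flagged `sense_overlap` so they can be filtered.

Pair enumeration keeps **all** qualifying genes per lncRNA — a lncRNA may
pair with many genes and vice versa — and never crosses chromosomes.
Interval-tree queries (one tree per chromosome) give near-linear scaling;
the test suite checks the output against all-vs-all enumeration.

## Regulation calls

For one comparison `A/B`, `log2fc > 0` means *up in A*. A feature passes
the DE gates when `padj < max_padj` (strict, default 0.05), `|log2fc| ≥
min_abs_log2fc` (default 1.0), and its sign is defined (`log2fc ≠ 0` — a
zero fold-change is never significant regardless of p-value). A pair is
**antiregulated** when both members pass with opposite signs,
**coregulated** when both pass with equal signs, otherwise **not_called**;
both members must pass individually, with no rescue of a near-threshold
partner. Features absent from a DE table are retained with `padj = 1` so
the pair universe stays constant across comparisons; for the same reason a
missing `padj` cell is read as 1 rather than dropped. The upstream DE
studies do not publish their cut-offs, so the gates are configuration, not
constants, and every output stamps the thresholds used. Tightening either
gate can only shrink the anti and co sets (monotonicity; property-tested).

## Compositions and ratios

Class compositions count **lncRNAs** (a lncRNA in several pairs counts
once; direction comes from its own fold-change sign), orientation
compositions count **pairs** — the two summaries deliberately use
different units because one describes the DE lncRNA complement and the
other the pair population. Percentages are reported to one decimal; modal
categories report ties explicitly instead of breaking them. Ratios between
compositions are count ratios (both counts are carried in the result, so a
percentage ratio is recoverable); a zero denominator returns a flagged
undefined value, never a number or an exception.

## Exclusive intersections

Cross-comparison matching uses UpSet "distinct" semantics: each item is
counted once, in the cell of its exact membership set, so cells partition
the once-called universe (conservation is property-tested, as is
consistency under pooling two comparisons into one). Item identity defaults
to the gene id — DE *gene* sets are what gets compared across comparisons —
with `(lnc_id, gene_id)` available as `mode="pair"`; orientation is never
part of the identity. The full table is always computed; top-k truncation
is a display filter only. Category matrices count distinct genes per
(category, comparison, call) cell; a gene mapped to k categories appears in
k rows, unmapped genes fall into `unassigned`, and row/column order is
lexicographic so the matrix is deterministic.

## Synthetic cohorts

The generator emulates the study design the package targets: ten named
subpopulation comparisons (`U6/L6` … `Aer/Rt`), lncRNA classes drawn iid
with proportions SUT 0.50 / CUT 0.15 / MUT 0.20 / XUT 0.15 (SUTs the
majority class, CUTs ~15%, MUTs between the ~6.5% and ~20% extremes
observed in smooth vs biofilm colonies), and a per-comparison anti:co:null
mixture of 0.2:0.4:0.4 (co:anti = 2, within the >1.7–1.8× range reported
for these designs).

Each planted pair occupies its own cassette; cassette spacing always
exceeds the pairing window, so the only in-window gene for a lncRNA is its
planted partner and cross-cassette pairs cannot arise. Orientations are
realized by construction (interval placement forces the category — the
truth table is re-derivable from the emitted coordinates, and a test does
exactly that). Gaps are uniform on [0, 1500]; a configurable decoy fraction
(default 0.1) adds beyond-window cassettes (gap 1501–3000) that must never
pair; a decoy requested in the antisense-overlap slot is emitted as a
separated antisense pair, since an overlapping decoy is geometrically
impossible. Gene lengths are uniform on [300, 1500] bp and lncRNA lengths
on [200, 800] bp, the scale of yeast coding loci and unannotated
transcripts; fifty cassettes share one chromosome so multi-chromosome
indexing is exercised.

The regulation mixture is realized as **exact counts** via a seeded
shuffled partition, not iid draws, so planted call counts are recovered
exactly; class labels are iid, so class compositions are recovered
statistically. In the default exact mode, significant effects satisfy
`|log2fc| ≥ threshold + 0.25` (magnitudes `max(1.25, |N(2.0, 0.75)|)`) with
`padj ~ U(0, 0.01)`, and null features draw `log2fc ~ U(−0.75, 0.75)`,
`padj ~ U(0.1, 1)` — every planted call is unambiguous at the generator's
own thresholds (padj 0.05, |log2fc| 1.0). The noisy mode instead draws
magnitudes `|N(1.0, 0.5)|` and `padj ~ U(0, 0.1)`, straddling both gates,
for monotonicity testing. Generation is deterministic given the seed:
identical seeds produce byte-identical files (floats are written with
round-trip precision).

What the generator does **not** emulate: read counts or any RNA-seq error
model (the pipeline starts at DE tables), correlated DE across
comparisons, overlapping gene dense regions where one lncRNA has several
in-window partners, or class-dependent regulation structure. Passing
recovery tests therefore demonstrates correctness of the interval
arithmetic, classification, joining and counting — not robustness to
annotation noise or DE miscalibration in real data.

## Validation set-up

Tests cross-check every core operation against an independent oracle
written from first principles: a case-table orientation classifier using a
"points-toward" rule, O(n²) all-vs-all pair enumeration, and full subset
enumeration for exclusive intersections. Property tests (hypothesis,
derandomized) cover totality/exclusivity of the classifier and invariance
under the strand-flip + coordinate-reflection symmetry, which preserves
every category. The end-to-end recovery check runs at 500 planted pairs
(100 per orientation) — large enough that the composition check is
informative while the whole suite stays fast. Recovered class compositions
are judged against simultaneous 95% binomial bounds (Bonferroni-corrected
per-class quantile, the standard construction for a multinomial
composition).

The pipeline also ships an arithmetic-consistency suite over the published
summary counts of the colony-subpopulation survey this design mirrors
(transcribed constants, marked as such in the source): each printed group
total must equal the sum of its printed co- and antiregulated components
(e.g. 308 + 157 = 465), and the printed "89%" share is accepted within one
percentage point of the computed 222/251 = 88.4%, treating the printed
value as rounded up.

## Known limitations

- Orientation uses interval 5′ ends as TSS proxies; no promoter or
  nucleosome-depleted-region modelling.
- Regulation calls are descriptive labels, not causal or mechanistic
  claims, and no statistical test is attached to composition differences
  (the summaries are descriptive, matching how such surveys report them).
- Sense-overlapping same-strand pairs are outside the five-category scheme
  and only handled via the flagged fallback.
- The DE sign convention (positive = up in the first-named subpopulation)
  must hold in user-supplied tables; the package cannot verify it.
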