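"""Composition summaries: lncRNA class make-up of up-/down-regulated sets and
orientation make-up of anti-/coregulated pair sets, plus ratio statistics.

Two different counting units are deliberate: class compositions count
*lncRNAs* (a lncRNA paired with several genes contributes once), while
orientation compositions count *pairs* (once per pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .features import DERecord, GenomicFeature
from .pairing import ORIENTATIONS
from .regulation import DEThresholds, RegulatedPair

LNC_CLASS_ORDER = ("SUT", "CUT", "MUT", "XUT", "other")


@dataclass(frozen=True)
class Composition:
    """Counts and percentages over a fixed set of categories.

    Percentages are reported to one decimal and sum to ~100 (up to
    rounding); an empty composition has all-zero counts and no percentages.
    ``modal`` lists every category tied for the maximum count — ties are
    reported, never broken silently.
    """

    counts: dict[str, int]
    label: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {}
        return {k: round(100.0 * v / t, 1) for k, v in self.counts.items()}

    @property
    def modal(self) -> tuple[str, ...]:
        if self.total == 0:
            return ()
        top = max(self.counts.values())
        return tuple(k for k, v in self.counts.items() if v == top)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "count": pd.Series(self.counts),
                "percent": pd.Series({k: pct.get(k, 0.0) for k in self.counts}),
            }
        ).rename_axis("category")


@dataclass(frozen=True)
class Ratio:
    """A count ratio with an explicit undefined flag for a zero denominator."""

    value: Optional[float]
    defined: bool
    numerator: int = 0
    denominator: int = 0

    def __float__(self) -> float:
        if not self.defined:
            raise ValueError("undefined ratio (zero denominator)")
        return float(self.value)


def class_composition(
    lnc_de: Iterable[DERecord],
    lnc_classes: Mapping[str, str],
    direction: str,
    thresholds: DEThresholds = DEThresholds(),
) -> Composition:
    """Class composition of significantly up- or down-regulated lncRNAs.

    ``lnc_de`` holds DE records of lncRNAs only; ``lnc_classes`` maps each
    lncRNA id to its stability class. The direction is judged on the
    lncRNA's own fold-change sign (``up`` = positive = higher in the
    first-named subpopulation), independent of any gene partner. Each lncRNA
    contributes once even if it occurs in several pairs.

    Raises
    ------
    ValueError
        If a significant lncRNA has no class label (all offending ids are
        listed).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    want_positive = direction == "up"
    selected: dict[str, DERecord] = {}
    for rec in lnc_de:
        if thresholds.passes(rec.log2fc, rec.padj) and (rec.log2fc > 0) == want_positive:
            selected[rec.feature_id] = rec

    unlabeled = sorted(fid for fid in selected if fid not in lnc_classes)
    if unlabeled:
        raise ValueError(f"lncRNAs without class label: {unlabeled}")

    counts = {cls: 0 for cls in LNC_CLASS_ORDER}
    for fid in selected:
        counts[lnc_classes[fid]] += 1
    return Composition(counts=counts, label=f"{direction}regulated lncRNAs")


def composition_ratio(comp_a: Composition, comp_b: Composition, cls: str) -> Ratio:
    """Count ratio of one category between two compositions (a / b).

    A zero denominator yields a flagged undefined :class:`Ratio`, not a
    number; this is how "x-fold as many CUTs up in roots as in aerial cells"
    style statistics are computed.
    """
    a = comp_a.counts.get(cls, 0)
    b = comp_b.counts.get(cls, 0)
    if b == 0:
        return Ratio(value=None, defined=False, numerator=a, denominator=0)
    return Ratio(value=a / b, defined=True, numerator=a, denominator=b)


def orientation_composition(
    regulated: Iterable[RegulatedPair],
    call: str,
) -> Composition:
    """Orientation composition of anti- or coregulated pairs (counted per pair)."""
    if call not in ("antiregulated", "coregulated"):
        raise ValueError(f"call must be 'antiregulated' or 'coregulated', got {call!r}")
    counts = {o: 0 for o in ORIENTATIONS}
    for r in regulated:
        if r.call == call:
            counts[r.pair.orientation] += 1
    return Composition(counts=counts, label=f"{call} pairs")


def merge_compositions(a: Composition, b: Composition) -> Composition:
    """Count-weighted merge of two disjoint cohorts' compositions."""
    keys = set(a.counts) | set(b.counts)
    return Composition(
        counts={k: a.counts.get(k, 0) + b.counts.get(k, 0) for k in sorted(keys)},
        label=f"{a.label}+{b.label}" if a.label and b.label else a.label or b.label,
    )


def lnc_class_map(features: Iterable[GenomicFeature]) -> dict[str, str]:
    """Convenience: feature_id -> lnc_class for the lncRNAs of an annotation."""
    return {f.feature_id: f.lnc_class for f in features if f.role == "lncRNA"}
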