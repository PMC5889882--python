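"""Core domain types: stranded genomic features and differential-expression records.

All coordinates are 0-based half-open throughout the package; format-specific
conventions (GFF3 1-based inclusive) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

#: Stability-defined lncRNA classes used in yeast transcriptomics:
#: SUT = stable unannotated transcript, CUT = cryptic unstable transcript
#: (nuclear-exosome degraded), MUT = meiotic unstable transcript
#: (Rrp6-sensitive), XUT = Xrn1-sensitive unstable transcript.
LNC_CLASSES = ("SUT", "CUT", "MUT", "XUT", "other")

ROLES = ("gene", "lncRNA")

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicFeature:
    """A stranded genomic interval with a role and, for lncRNAs, a class label.

    Parameters
    ----------
    feature_id:
        Unique identifier within one annotation set.
    chrom:
        Chromosome / sequence name.
    start, end:
        0-based half-open interval; ``0 <= start < end`` (empty intervals
        are rejected).
    strand:
        ``"+"`` or ``"-"``; unstranded features are rejected because every
        orientation call depends on strand.
    role:
        ``"gene"`` or ``"lncRNA"``.
    lnc_class:
        One of :data:`LNC_CLASSES`; required for lncRNAs, forbidden for genes.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    role: str
    lnc_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end}) — need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r} (unstranded features are not allowed)"
            )
        if self.role not in ROLES:
            raise AnnotationError(
                f"feature {self.feature_id!r}: role must be one of {ROLES}, "
                f"got {self.role!r}"
            )
        if self.role == "gene" and self.lnc_class is not None:
            raise AnnotationError(
                f"feature {self.feature_id!r}: a gene must not carry a "
                f"lnc_class (got {self.lnc_class!r})"
            )
        if self.role == "lncRNA":
            if self.lnc_class is None:
                raise AnnotationError(
                    f"feature {self.feature_id!r}: lncRNA without lnc_class"
                )
            if self.lnc_class not in LNC_CLASSES:
                raise AnnotationError(
                    f"feature {self.feature_id!r}: unknown lnc_class "
                    f"{self.lnc_class!r}; expected one of {LNC_CLASSES}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end (the transcription start side)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Coordinate of the 3' end."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression result for one named comparison.

    ``log2fc`` follows the convention *positive = upregulated in the
    comparison's first-named subpopulation* (e.g. U15 in "U15/L15").
    ``padj`` is the adjusted p-value in [0, 1]; a missing value upstream is
    encoded as 1 (never significant) rather than dropped, so the feature
    universe stays comparable across comparisons.
    """

    feature_id: str
    comparison: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(
                f"{self.feature_id!r} ({self.comparison}): padj {self.padj} "
                f"outside [0, 1]"
            )


def check_unique_ids(features: Iterable[GenomicFeature]) -> None:
    """Raise :class:`AnnotationError` if any feature_id occurs twice."""
    seen: set[str] = set()
    for f in features:
        if f.feature_id in seen:
            raise AnnotationError(f"duplicate feature_id {f.feature_id!r}")
        seen.add(f.feature_id)
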