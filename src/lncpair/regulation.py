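"""Join lncRNA/gene pairs to DE results and call anti-/coregulation.

A pair is *antiregulated* in a comparison when lncRNA and gene are both
significantly differentially expressed with opposite fold-change signs
(antagonistic), and *coregulated* when both are significant with the same
sign (agonistic). Everything else — either member non-significant, below
the fold-change gate, or with an undefined sign (log2fc == 0) — is
*not_called*. Both members must pass individually; a near-threshold partner
is never rescued.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .features import DERecord
from .pairing import PairRecord

CALLS = ("antiregulated", "coregulated", "not_called")


@dataclass(frozen=True)
class DEThresholds:
    """Significance gates for a DE call.

    A feature passes when ``padj < max_padj`` and ``|log2fc| >= min_abs_log2fc``
    and its fold-change sign is defined (log2fc != 0). The source DE studies
    do not publish their cut-offs, so these are configuration with
    conventional defaults, and they are stamped into output metadata.
    """

    max_padj: float = 0.05
    min_abs_log2fc: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.max_padj <= 1.0):
            raise ValueError("max_padj must be in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")

    def passes(self, log2fc: float, padj: float) -> bool:
        return (
            padj < self.max_padj
            and abs(log2fc) >= self.min_abs_log2fc
            and log2fc != 0.0
        )


@dataclass(frozen=True)
class RegulatedPair:
    """A pair joined to the DE results of both members for one comparison."""

    pair: PairRecord
    comparison: str
    gene_log2fc: float
    lnc_log2fc: float
    gene_padj: float
    lnc_padj: float
    call: str


def call_regulation(
    pairs: Iterable[PairRecord],
    de: Iterable[DERecord],
    comparison: str,
    thresholds: DEThresholds = DEThresholds(),
) -> list[RegulatedPair]:
    """Label every pair antiregulated / coregulated / not_called.

    Every input pair is emitted exactly once. A feature absent from the DE
    table is treated as not significant (``padj = 1``, ``log2fc = 0``).

    Raises
    ------
    ValueError
        If no DE record carries the requested comparison name.
    """
    table = {r.feature_id: r for r in de if r.comparison == comparison}
    if not table:
        raise ValueError(f"no DE records for comparison {comparison!r}")

    out: list[RegulatedPair] = []
    for pair in pairs:
        g = table.get(pair.gene_id)
        l = table.get(pair.lnc_id)
        g_lfc, g_p = (g.log2fc, g.padj) if g is not None else (0.0, 1.0)
        l_lfc, l_p = (l.log2fc, l.padj) if l is not None else (0.0, 1.0)
        if thresholds.passes(g_lfc, g_p) and thresholds.passes(l_lfc, l_p):
            call = "antiregulated" if (g_lfc > 0) != (l_lfc > 0) else "coregulated"
        else:
            call = "not_called"
        out.append(RegulatedPair(pair, comparison, g_lfc, l_lfc, g_p, l_p, call))
    return out


def count_calls(regulated: Iterable[RegulatedPair]) -> pd.DataFrame:
    """Tabulate calls per comparison.

    Returns a DataFrame indexed by comparison with columns
    ``antiregulated, coregulated, not_called, total``; the three calls
    partition each comparison's pairs, so they sum to ``total``.
    """
    rows = [{"comparison": r.comparison, "call": r.call} for r in regulated]
    if not rows:
        return pd.DataFrame(columns=list(CALLS) + ["total"]).rename_axis("comparison")
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["comparison", "call"]).size().unstack(fill_value=0)
        .reindex(columns=list(CALLS), fill_value=0)
    )
    counts.columns.name = None
    counts["total"] = counts.sum(axis=1)
    return counts


def co_anti_ratio(counts: pd.DataFrame) -> float:
    """Overall coregulated : antiregulated ratio across all comparisons.

    Returns ``inf`` when no pair is antiregulated and ``nan`` when neither
    call occurs.
    """
    co = int(counts["coregulated"].sum())
    anti = int(counts["antiregulated"].sum())
    if anti == 0:
        return float("nan") if co == 0 else float("inf")
    return co / anti


def regulated_to_frame(regulated: Sequence[RegulatedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": r.pair.lnc_id,
                "gene_id": r.pair.gene_id,
                "comparison": r.comparison,
                "orientation": r.pair.orientation,
                "call": r.call,
                "gene_log2fc": r.gene_log2fc,
                "lnc_log2fc": r.lnc_log2fc,
                "gene_padj": r.gene_padj,
                "lnc_padj": r.lnc_padj,
            }
            for r in regulated
        ],
        columns=["lnc_id", "gene_id", "comparison", "orientation", "call",
                 "gene_log2fc", "lnc_log2fc", "gene_padj", "lnc_padj"],
    )


def write_calls(regulated: Sequence[RegulatedPair], path: str | Path) -> None:
    regulated_to_frame(regulated).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[RegulatedPair]:
    df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "gene_id": str})
    out = []
    for r in df.itertuples(index=False):
        pair = PairRecord(r.lnc_id, r.gene_id, r.orientation, 0)
        out.append(RegulatedPair(pair, r.comparison, r.gene_log2fc, r.lnc_log2fc,
                                 r.gene_padj, r.lnc_padj, r.call))
    return out
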