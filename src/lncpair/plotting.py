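"""Optional matplotlib views: stacked composition bars and an
exclusive-intersection bar chart (UpSet-like, without the matrix styling)."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .summarize import Composition


def stacked_composition_bars(compositions: Mapping[str, Composition],
                             ax=None, title: str = ""):
    """One stacked percentage bar per labelled composition (e.g. one per
    comparison), categories stacked in a fixed order."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 1.2 * len(compositions)), 4))
    labels = list(compositions)
    categories: list[str] = []
    for comp in compositions.values():
        for c in comp.counts:
            if c not in categories:
                categories.append(c)
    bottom = [0.0] * len(labels)
    for cat in categories:
        heights = [compositions[l].percentages.get(cat, 0.0) for l in labels]
        ax.bar(labels, heights, bottom=bottom, label=cat)
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax.set_ylabel("percent")
    ax.set_ylim(0, 105)
    ax.legend(fontsize="small")
    if title:
        ax.set_title(title)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    return ax


def intersection_bars(table: pd.DataFrame, top_k: int = 15, ax=None,
                      title: str = ""):
    """Bar chart of the largest exclusive-intersection cells."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    shown = table.nlargest(top_k, "count", keep="all")
    labels = shown["subset"].map(lambda s: "\n&".join(sorted(s)))
    ax.bar(range(len(shown)), shown["count"])
    ax.set_xticks(range(len(shown)))
    ax.set_xticklabels(labels, fontsize="x-small")
    ax.set_ylabel("pairs in exactly this set of comparisons")
    if title:
        ax.set_title(title)
    return ax
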