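"""Synthetic annotation + DE fixture generator with exact ground truth.

The generator emulates the structure of a yeast-colony subpopulation
transcriptome study: a compact multi-chromosome annotation in which lncRNA
loci sit next to genes in controlled orientations and gaps, lncRNA stability
classes drawn from realistic proportions, and one DE table per named
pairwise subpopulation comparison containing a planted mixture of
antiregulated, coregulated and null lncRNA/gene pairs.

Orientations are realized *by construction* (intervals are placed to force
the category), and in the default exact mode planted DE calls are realized
exactly at the generator's own thresholds: effect sizes are drawn at least
0.25 log2 units above the fold-change gate and significant adjusted
p-values at least an order of magnitude below the significance gate, so a
pipeline run with matching thresholds recovers the planted counts exactly.
A separate noisy mode draws effects and p-values straddling the gates, for
threshold-monotonicity testing. Generation is deterministic given the seed;
re-running with the same seed emits byte-identical files.

Each planted pair lives in its own well-separated cassette (inter-cassette
spacing exceeds the pairing window), so the only in-window gene for each
lncRNA is its planted partner. A configurable fraction of extra cassettes
are beyond-window decoys that must never pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import write_de_table, write_gff3
from .features import DERecord, GenomicFeature
from .pairing import ORIENTATIONS, classify_orientation

#: The pairwise cell-subpopulation comparisons of the smooth-colony
#: (U/M/L = upper/margin/lower at 6 or 15 days) and colony-biofilm
#: (Aer/Rt = aerial/root) designs.
DEFAULT_COMPARISONS = (
    "U6/L6", "U6/M6", "M6/L6",
    "U15/L15", "U15/M15", "M15/L15",
    "U15/U6", "M15/M6", "L15/L6",
    "Aer/Rt",
)

#: Observed orders of magnitude for class shares of DE lncRNAs: SUTs are the
#: majority class (>50%), CUTs ~15%, MUTs between ~6.5% and ~20%, XUTs the
#: remainder.
DEFAULT_CLASS_PROPORTIONS = {"SUT": 0.50, "CUT": 0.15, "MUT": 0.20, "XUT": 0.15}


class GeneratorConfigError(ValueError):
    """Invalid or geometrically impossible generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level knobs of the synthetic cohort.

    ``mixture`` gives the (anti, co, null) fractions of planted pairs per
    comparison; they are realized as exact deterministic counts (rounded),
    not iid draws, so call recovery is exact. ``class_proportions`` by
    contrast are iid per lncRNA, so composition recovery is binomial.
    """

    n_pairs_per_orientation: dict[str, int] = field(
        default_factory=lambda: {o: 10 for o in ORIENTATIONS})
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    window_bp: int = 1500
    gap_range: tuple[int, int] = (0, 1500)          # non-overlap categories
    decoy_gap_range: tuple[int, int] = (1501, 3000)  # beyond-window controls
    decoy_fraction: float = 0.1
    asover_overlap_range: tuple[int, int] = (1, 150)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    mixture: tuple[float, float, float] = (0.2, 0.4, 0.4)  # anti, co, null
    effect_mean: float = 2.0
    effect_sd: float = 0.75
    min_abs_log2fc: float = 1.0
    max_padj: float = 0.05
    effect_margin: float = 0.25
    sig_padj_range: tuple[float, float] = (0.0, 0.01)
    null_padj_range: tuple[float, float] = (0.1, 1.0)
    noisy: bool = False
    pairs_per_chrom: int = 50
    gene_length_range: tuple[int, int] = (300, 1500)
    lnc_length_range: tuple[int, int] = (200, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_pairs_per_orientation) - set(ORIENTATIONS)
        if unknown:
            raise GeneratorConfigError(f"unknown orientation(s): {sorted(unknown)}")
        if any(n < 0 for n in self.n_pairs_per_orientation.values()):
            raise GeneratorConfigError("pair counts must be >= 0")
        if abs(sum(self.mixture) - 1.0) > 1e-9 or any(m < 0 for m in self.mixture):
            raise GeneratorConfigError("mixture fractions must be >= 0 and sum to 1")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("class proportions must sum to 1")
        lo, hi = self.gap_range
        if not (0 <= lo <= hi):
            raise GeneratorConfigError("invalid gap_range")
        if hi > self.window_bp:
            raise GeneratorConfigError(
                "gap_range extends beyond the pairing window; planted in-window "
                "pairs would not be recoverable")
        dlo, dhi = self.decoy_gap_range
        if not (self.window_bp < dlo <= dhi):
            raise GeneratorConfigError(
                "decoy gaps must exceed the window (decoys must never pair)")
        olo, ohi = self.asover_overlap_range
        if not (1 <= olo <= ohi):
            raise GeneratorConfigError(
                "antisense overlap requires >= 1 shared base (an overlapping "
                "pair with a positive gap is geometrically impossible)")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise GeneratorConfigError("decoy_fraction must be in [0, 1]")
        if self.pairs_per_chrom < 1:
            raise GeneratorConfigError("pairs_per_chrom must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated cohort.

    ``pairs`` has one row per cassette (planted orientation, gap, class,
    decoy flag); ``calls`` one row per (in-window pair, comparison) with the
    planted regulation label. Both are mutually consistent with the emitted
    annotation: re-deriving orientations from coordinates reproduces them.
    """

    pairs: pd.DataFrame
    calls: pd.DataFrame
    seed: int
    config: GeneratorConfig

    def planted_orientation_counts(self) -> dict[str, int]:
        inw = self.pairs[~self.pairs["decoy"]]
        return inw["orientation"].value_counts().to_dict()

    def planted_call_counts(self, comparison: str) -> dict[str, int]:
        sub = self.calls[self.calls["comparison"] == comparison]
        return sub["planted_call"].value_counts().to_dict()


@dataclass
class SyntheticDataset:
    features: list[GenomicFeature]
    de_tables: dict[str, list[DERecord]]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit GFF3 + per-comparison DE TSVs + truth TSVs + config YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["annotation"] = outdir / "annotation.gff3"
        write_gff3(self.features, paths["annotation"])
        for comparison, records in self.de_tables.items():
            key = f"de:{comparison}"
            paths[key] = outdir / f"de_{comparison.replace('/', '_')}.tsv"
            write_de_table(records, paths[key])
        paths["truth_pairs"] = outdir / "truth_pairs.tsv"
        self.truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
        paths["truth_calls"] = outdir / "truth_calls.tsv"
        self.truth.calls.to_csv(paths["truth_calls"], sep="\t", index=False)
        paths["config"] = outdir / "config.yaml"
        cfg = dataclasses.asdict(self.truth.config)
        cfg = {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()}
        cfg["seed"] = self.truth.seed
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return paths


def _place_cassette(rng: np.random.Generator, cfg: GeneratorConfig,
                    orientation: str, decoy: bool) -> tuple[tuple[int, int, str],
                                                            tuple[int, int, str], int]:
    """Local (offset-free) coordinates forcing the requested orientation.

    Returns ((lnc_start, lnc_end, lnc_strand), (gene_start, gene_end,
    gene_strand), gap).
    """
    gl = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
    ll = int(rng.integers(cfg.lnc_length_range[0], cfg.lnc_length_range[1] + 1))
    lo, hi = cfg.decoy_gap_range if decoy else cfg.gap_range
    gap = int(rng.integers(lo, hi + 1))

    if orientation == "asOver":
        # decoy asOver is impossible (overlap implies pairing); decoys for
        # this slot are generated as antisense pairs separated by > window.
        sg = "+" if rng.random() < 0.5 else "-"
        sl = "-" if sg == "+" else "+"
        if decoy:
            return (0, ll, sl), (ll + gap, ll + gap + gl, sg), gap
        ov = int(rng.integers(cfg.asover_overlap_range[0],
                              min(cfg.asover_overlap_range[1], gl, ll) + 1))
        return (gl - ov, gl - ov + ll, sl), (0, gl, sg), 0
    if orientation == "asConv":   # '+' member left of '-' member
        if rng.random() < 0.5:
            return (0, ll, "+"), (ll + gap, ll + gap + gl, "-"), gap
        return (gl + gap, gl + gap + ll, "-"), (0, gl, "+"), gap
    if orientation == "asDiv":    # '-' member left of '+' member
        if rng.random() < 0.5:
            return (gl + gap, gl + gap + ll, "+"), (0, gl, "-"), gap
        return (0, ll, "-"), (ll + gap, ll + gap + gl, "+"), gap
    s = "+" if rng.random() < 0.5 else "-"
    lnc_upstream = (orientation == "tandem5")
    lnc_left = lnc_upstream if s == "+" else not lnc_upstream
    if lnc_left:
        return (0, ll, s), (ll + gap, ll + gap + gl, s), gap
    return (gl + gap, gl + gap + ll, s), (0, gl, s), gap


def _effect(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    """Magnitude of a planted significant log2 fold-change."""
    if cfg.noisy:
        return abs(rng.normal(cfg.min_abs_log2fc, 0.5))
    return max(cfg.min_abs_log2fc + cfg.effect_margin,
               abs(rng.normal(cfg.effect_mean, cfg.effect_sd)))


def _sig_padj(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    if cfg.noisy:
        return float(rng.uniform(0.0, 2 * cfg.max_padj))
    return float(rng.uniform(*cfg.sig_padj_range))


def generate(config: GeneratorConfig = GeneratorConfig(),
             seed: Optional[int] = None) -> SyntheticDataset:
    """Generate annotation, DE tables and ground truth for one cohort.

    ``seed`` overrides ``config.seed`` when given. Deterministic: the same
    seed and config always produce identical output.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n_planted = sum(config.n_pairs_per_orientation.get(o, 0) for o in ORIENTATIONS)
    n_decoys = int(round(config.decoy_fraction * n_planted))

    # Cassette plan: planted orientations in a shuffled order, then decoys
    # cycling through the orientations.
    plan: list[tuple[str, bool]] = []
    for o in ORIENTATIONS:
        plan.extend((o, False) for _ in range(config.n_pairs_per_orientation.get(o, 0)))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]
    plan.extend((ORIENTATIONS[i % len(ORIENTATIONS)], True) for i in range(n_decoys))

    spacer = config.window_bp + 1000
    features: list[GenomicFeature] = []
    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])

    pair_rows = []
    for idx, (orientation, decoy) in enumerate(plan):
        chrom = f"chrS{idx // config.pairs_per_chrom + 1:02d}"
        offset = (idx % config.pairs_per_chrom) * (spacer + 6000) + 1
        (ls, le, lstrand), (gs, ge, gstrand), gap = _place_cassette(
            rng, config, orientation, decoy)
        lnc_id = f"lnc{idx + 1:04d}"
        gene_id = f"g{idx + 1:04d}"
        lnc_class = str(rng.choice(classes, p=probs))
        lnc_feat = GenomicFeature(lnc_id, chrom, ls + offset, le + offset,
                                  lstrand, "lncRNA", lnc_class)
        gene_feat = GenomicFeature(gene_id, chrom, gs + offset, ge + offset,
                                   gstrand, "gene")
        features.extend((lnc_feat, gene_feat))
        if decoy:
            # A decoy in the antisense-overlap slot is placed as a separated
            # antisense pair (overlap would force pairing); record the
            # geometry actually realized so truth matches the coordinates.
            orientation = classify_orientation(lnc_feat, gene_feat)[0]
        pair_rows.append({
            "pair_id": f"p{idx + 1:04d}", "lnc_id": lnc_id, "gene_id": gene_id,
            "chrom": chrom, "orientation": orientation, "gap_bp": gap,
            "lnc_class": lnc_class, "decoy": decoy,
        })
    truth_pairs = pd.DataFrame(
        pair_rows, columns=["pair_id", "lnc_id", "gene_id", "chrom",
                            "orientation", "gap_bp", "lnc_class", "decoy"])

    # DE planting: exact anti/co/null partition per comparison over the
    # in-window pairs; decoy features always get null-style rows.
    in_window = truth_pairs[~truth_pairs["decoy"]].reset_index(drop=True)
    n = len(in_window)
    n_anti = int(round(config.mixture[0] * n))
    n_co = int(round(config.mixture[1] * n))

    de_tables: dict[str, list[DERecord]] = {}
    call_rows = []
    decoy_ids = truth_pairs.loc[truth_pairs["decoy"], ["lnc_id", "gene_id"]]
    for comparison in config.comparisons:
        perm = rng.permutation(n)
        labels = np.full(n, "null", dtype=object)
        labels[perm[:n_anti]] = "antiregulated"
        labels[perm[n_anti:n_anti + n_co]] = "coregulated"
        records: list[DERecord] = []
        for i, row in in_window.iterrows():
            label = labels[i]
            if label == "null":
                records.append(DERecord(row.lnc_id, comparison,
                                        float(rng.uniform(-0.75, 0.75)),
                                        float(rng.uniform(*config.null_padj_range))))
                records.append(DERecord(row.gene_id, comparison,
                                        float(rng.uniform(-0.75, 0.75)),
                                        float(rng.uniform(*config.null_padj_range))))
            else:
                s = 1.0 if rng.random() < 0.5 else -1.0
                gsign = -s if label == "antiregulated" else s
                records.append(DERecord(row.lnc_id, comparison,
                                        s * _effect(rng, config),
                                        _sig_padj(rng, config)))
                records.append(DERecord(row.gene_id, comparison,
                                        gsign * _effect(rng, config),
                                        _sig_padj(rng, config)))
            call_rows.append({"pair_id": row.pair_id, "comparison": comparison,
                              "planted_call": label if label != "null"
                              else "not_called"})
        for drow in decoy_ids.itertuples(index=False):
            for fid in (drow.lnc_id, drow.gene_id):
                records.append(DERecord(fid, comparison,
                                        float(rng.uniform(-0.75, 0.75)),
                                        float(rng.uniform(*config.null_padj_range))))
        de_tables[comparison] = records

    truth_calls = pd.DataFrame(
        call_rows, columns=["pair_id", "comparison", "planted_call"])
    truth = SyntheticTruth(pairs=truth_pairs, calls=truth_calls,
                           seed=seed, config=config)
    return SyntheticDataset(features=features, de_tables=de_tables, truth=truth)
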