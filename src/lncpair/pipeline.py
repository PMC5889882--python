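"""End-to-end orchestration: ingest -> pair -> call -> summarize -> intersect,
driven by a YAML config, plus a built-in arithmetic-consistency suite for the
published summary counts of the yeast-colony lncRNA/gene survey this pipeline
mirrors.

The pipeline is deterministic: re-running on the same inputs reproduces
byte-identical outputs (the run log records a config hash, thresholds and
seed, never wall-clock time).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from . import annotation_io, intersections, pairing, regulation, summarize
from .features import DERecord, GenomicFeature


class PipelineConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


@dataclass
class PipelineResult:
    features: list[GenomicFeature]
    pairs: list[pairing.PairRecord]
    regulated: list[regulation.RegulatedPair]
    call_counts: pd.DataFrame
    class_compositions: dict[tuple[str, str], summarize.Composition]
    orientation_compositions: dict[str, summarize.Composition]
    intersection_tables: dict[str, pd.DataFrame]
    category_matrix: Optional[pd.DataFrame]
    output_dir: Optional[Path] = None
    written: dict[str, Path] = field(default_factory=dict)


def _load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("pipeline config must be a mapping")
    return cfg


def run_pipeline(config: str | Path | Mapping[str, Any],
                 output_dir: Optional[str | Path] = None) -> PipelineResult:
    """Run the full analysis described by a config mapping or YAML file.

    Config keys: ``annotation`` (path), ``annotation_format`` (default
    gff3), ``de_tables`` (mapping comparison -> TSV path), ``window_bp``,
    ``max_padj``, ``min_abs_log2fc``, ``pair_id_mode`` (gene|pair),
    ``category_map`` (optional TSV path), ``output_dir`` (optional; may be
    overridden by the argument).

    All inputs are validated for existence before any computation; a
    missing DE table fails naming its comparison.
    """
    cfg = _load_config(config)
    if "annotation" not in cfg:
        raise PipelineConfigError("config missing 'annotation'")
    if "de_tables" not in cfg or not cfg["de_tables"]:
        raise PipelineConfigError("config missing 'de_tables'")

    annotation_path = Path(cfg["annotation"])
    if not annotation_path.exists():
        raise PipelineConfigError(f"annotation file not found: {annotation_path}")
    de_paths: dict[str, Path] = {}
    for comparison, path in cfg["de_tables"].items():
        p = Path(path)
        if not p.exists():
            raise PipelineConfigError(
                f"DE table for comparison {comparison!r} not found: {p}")
        de_paths[comparison] = p
    category_map_path = cfg.get("category_map")
    if category_map_path is not None and not Path(category_map_path).exists():
        raise PipelineConfigError(f"category map not found: {category_map_path}")

    pairing_cfg = pairing.PairingConfig(window_bp=int(cfg.get("window_bp", 1500)))
    thresholds = regulation.DEThresholds(
        max_padj=float(cfg.get("max_padj", 0.05)),
        min_abs_log2fc=float(cfg.get("min_abs_log2fc", 1.0)),
    )
    id_mode = cfg.get("pair_id_mode", "gene")

    features = annotation_io.read_annotation(
        annotation_path, format=cfg.get("annotation_format", "gff3"))
    de_tables: dict[str, list[DERecord]] = {
        comparison: annotation_io.read_de_table(path, comparison)
        for comparison, path in de_paths.items()
    }

    pairs = pairing.find_pairs(features, pairing_cfg)

    regulated: list[regulation.RegulatedPair] = []
    for comparison, records in de_tables.items():
        regulated.extend(
            regulation.call_regulation(pairs, records, comparison, thresholds))

    call_counts = regulation.count_calls(regulated)

    classes = summarize.lnc_class_map(features)
    lnc_ids = set(classes)
    class_compositions: dict[tuple[str, str], summarize.Composition] = {}
    for comparison, records in de_tables.items():
        lnc_de = [r for r in records if r.feature_id in lnc_ids]
        for direction in ("up", "down"):
            class_compositions[(comparison, direction)] = summarize.class_composition(
                lnc_de, classes, direction, thresholds)

    orientation_compositions = {
        call: summarize.orientation_composition(regulated, call)
        for call in ("antiregulated", "coregulated")
    }

    intersection_tables = {}
    for call in ("antiregulated", "coregulated"):
        sets = intersections.call_sets(regulated, call, mode=id_mode)
        intersection_tables[call] = intersections.exclusive_intersections(sets)

    category_matrix = None
    if category_map_path is not None:
        cmap = intersections.read_category_map(category_map_path)
        category_matrix = intersections.category_counts(regulated, cmap)

    result = PipelineResult(
        features=features, pairs=pairs, regulated=regulated,
        call_counts=call_counts, class_compositions=class_compositions,
        orientation_compositions=orientation_compositions,
        intersection_tables=intersection_tables, category_matrix=category_matrix)

    outdir = output_dir or cfg.get("output_dir")
    if outdir is not None:
        result.output_dir = Path(outdir)
        _write_outputs(result, cfg, thresholds)
    return result


def _config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(result: PipelineResult, cfg: Mapping[str, Any],
                   thresholds: regulation.DEThresholds) -> None:
    outdir = result.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    w = result.written

    w["pairs"] = outdir / "pairs.tsv"
    pairing.write_pairs(result.pairs, w["pairs"])
    w["calls"] = outdir / "calls.tsv"
    regulation.write_calls(result.regulated, w["calls"])
    w["call_counts"] = outdir / "call_counts.tsv"
    result.call_counts.to_csv(w["call_counts"], sep="\t")

    comp_rows = []
    for (comparison, direction), comp in sorted(result.class_compositions.items()):
        pct = comp.percentages
        for cls, n in comp.counts.items():
            comp_rows.append({"comparison": comparison, "direction": direction,
                              "lnc_class": cls, "count": n,
                              "percent": pct.get(cls, 0.0)})
    w["class_composition"] = outdir / "class_composition.tsv"
    pd.DataFrame(comp_rows).to_csv(w["class_composition"], sep="\t", index=False)

    ori_rows = []
    for call, comp in sorted(result.orientation_compositions.items()):
        pct = comp.percentages
        for o, n in comp.counts.items():
            ori_rows.append({"call": call, "orientation": o, "count": n,
                             "percent": pct.get(o, 0.0)})
    w["orientation_composition"] = outdir / "orientation_composition.tsv"
    pd.DataFrame(ori_rows).to_csv(w["orientation_composition"], sep="\t", index=False)

    for call, table in result.intersection_tables.items():
        key = f"intersections_{call}"
        w[key] = outdir / f"{key}.tsv"
        intersections.intersections_to_tsv(table, w[key])

    if result.category_matrix is not None:
        w["category_matrix"] = outdir / "category_matrix.tsv"
        result.category_matrix.to_csv(w["category_matrix"], sep="\t")

    consistency = consistency_suite()
    w["consistency"] = outdir / "consistency_checks.tsv"
    consistency.to_csv(w["consistency"], sep="\t", index=False)

    meta = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed"),
        "max_padj": thresholds.max_padj,
        "min_abs_log2fc": thresholds.min_abs_log2fc,
        "window_bp": int(cfg.get("window_bp", 1500)),
        "log2fc_sign_convention": "positive = up in first-named subpopulation",
        "n_features": len(result.features),
        "n_pairs": len(result.pairs),
    }
    w["run_log"] = outdir / "run_log.json"
    with open(w["run_log"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)

    w["report"] = outdir / "report.html"
    _write_html_report(result, consistency, w["report"])


def _write_html_report(result: PipelineResult, consistency: pd.DataFrame,
                       path: Path) -> None:
    parts = ["<html><head><title>lncpair report</title></head><body>",
             "<h1>lncRNA/gene neighborhood analysis</h1>",
             "<h2>Regulation calls per comparison</h2>",
             result.call_counts.to_html(),
             "<h2>Orientation composition of called pairs</h2>"]
    for call, comp in sorted(result.orientation_compositions.items()):
        parts.append(f"<h3>{call}</h3>")
        parts.append(comp.to_frame().to_html())
    for call, table in sorted(result.intersection_tables.items()):
        parts.append(f"<h2>Exclusive intersections ({call})</h2>")
        t = table.copy()
        t["subset"] = t["subset"].map(lambda s: " & ".join(sorted(s)))
        parts.append(t.to_html(index=False))
    parts.append("<h2>Published-count consistency checks</h2>")
    parts.append(consistency.to_html(index=False))
    parts.append("</body></html>")
    path.write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# arithmetic-consistency suite for published summary counts
# ---------------------------------------------------------------------------

#: Exclusive-intersection group totals as printed in the yeast-colony
#: lncRNA/gene survey: each group total should equal the sum of its printed
#: coregulated and antiregulated components. Transcribed constants, marked
#: as such — they are inputs to an arithmetic check, not computed here.
PUBLISHED_GROUPS: tuple[tuple[str, tuple[int, ...], int], ...] = (
    ("exclusive U15/L15 (co 308 + anti 157)", (308, 157), 465),
    ("exclusive U6/L6 (co 184 + anti 126)", (184, 126), 310),
    ("U15/L15 and U6/L6, not Aer/Rt (co 198 + anti 49)", (198, 49), 247),
    ("exclusive Aer/Rt (co 122 + anti 67)", (122, 67), 189),
    ("antiregulated in time-point comparisons (222 + 27 + 2)", (222, 27, 2), 251),
)

#: Printed percentage checks: (label, numerator, denominator, printed %,
#: tolerance in percentage points). 222/251 = 88.45% is printed as 89%; the
#: printed value is treated as rounded up and accepted within one point.
PUBLISHED_PERCENTAGES: tuple[tuple[str, int, int, float, float], ...] = (
    ("U15/U6 share of time-point antiregulated pairs", 222, 251, 89.0, 1.0),
)


def consistency_suite() -> pd.DataFrame:
    """Check that the published group totals and percentages are internally
    consistent: each total equals the sum of its components and each printed
    percentage matches its printed fraction within the stated tolerance.

    Returns a DataFrame with columns ``check, computed, reported, tolerance,
    passed``.
    """
    rows = []
    for label, components, reported_total in PUBLISHED_GROUPS:
        computed = sum(components)
        rows.append({"check": label, "computed": float(computed),
                     "reported": float(reported_total), "tolerance": 0.0,
                     "passed": computed == reported_total})
    for label, num, den, printed_pct, tol in PUBLISHED_PERCENTAGES:
        computed = round(100.0 * num / den, 1)
        rows.append({"check": label, "computed": computed,
                     "reported": printed_pct, "tolerance": tol,
                     "passed": abs(computed - printed_pct) <= tol})
    return pd.DataFrame(rows,
                        columns=["check", "computed", "reported", "tolerance",
                                 "passed"])
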