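"""Read and write genome annotations (GFF3 / BED6 / TSV) and DE tables.

Everything is normalized at this boundary to the package-wide convention of
0-based half-open coordinates. GFF3 is 1-based inclusive on disk, so a GFF3
feature with start *s*, end *e* maps to the internal interval ``(s - 1, e)``;
BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .features import AnnotationError, DERecord, GenomicFeature, check_unique_ids

DE_COLUMNS = ("feature_id", "log2fc", "padj")


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    format: str = "gff3",
    role_field: str = "type",
    class_field: str = "lnc_class",
    class_map: Optional[Mapping[str, str]] = None,
) -> list[GenomicFeature]:
    """Read an annotation file into a list of :class:`GenomicFeature`.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"gff3"``, ``"bed"`` (BED6) or ``"tsv"`` (the package's own tabular
        dump, already 0-based half-open).
    role_field:
        For GFF3: ``"type"`` to take the role from the feature-type column,
        otherwise the name of an attribute holding the role.
    class_field:
        GFF3 attribute (or TSV column) holding the lncRNA class.
    class_map:
        For BED input: mapping of lncRNA feature_id to class; features
        present in the map are lncRNAs, the rest are genes. See
        :func:`read_class_map`.
    """
    fmt = format.lower()
    if fmt == "gff3":
        feats = _read_gff3(Path(path), role_field, class_field)
    elif fmt == "bed":
        feats = _read_bed(Path(path), class_map or {})
    elif fmt == "tsv":
        feats = _read_annotation_tsv(Path(path), class_field)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    check_unique_ids(feats)
    return feats


def _read_gff3(path: Path, role_field: str, class_field: str) -> list[GenomicFeature]:
    features: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed GFF3 line ({exc})"
                ) from exc
            attrs = {k: v[0] for k, v in f.attributes.items() if v}
            feature_id = attrs.get("ID")
            if feature_id is None:
                raise AnnotationError(f"{path}:{lineno}: feature without ID attribute")
            if f.strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: unstranded feature {feature_id!r}"
                )
            role = f.featuretype if role_field == "type" else attrs.get(role_field)
            if role not in ("gene", "lncRNA"):
                raise AnnotationError(
                    f"{path}:{lineno}: feature {feature_id!r} has "
                    f"unrecognized role {role!r} (expected 'gene' or 'lncRNA')"
                )
            lnc_class = attrs.get(class_field)
            if role == "gene" and lnc_class is not None:
                raise AnnotationError(
                    f"{path}:{lineno}: gene {feature_id!r} carries a lnc_class"
                )
            try:
                features.append(
                    GenomicFeature(
                        feature_id=feature_id,
                        chrom=f.seqid,
                        start=f.start - 1,  # 1-based inclusive -> 0-based half-open
                        end=f.end,
                        strand=f.strand,
                        role=role,
                        lnc_class=lnc_class,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return features


def _read_bed(path: Path, class_map: Mapping[str, str]) -> list[GenomicFeature]:
    features: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unstranded feature {name!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            lnc_class = class_map.get(name)
            try:
                features.append(
                    GenomicFeature(
                        feature_id=name,
                        chrom=chrom,
                        start=start_i,
                        end=end_i,
                        strand=strand,
                        role="lncRNA" if lnc_class is not None else "gene",
                        lnc_class=lnc_class,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return features


def _read_annotation_tsv(path: Path, class_field: str) -> list[GenomicFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "chrom", "start", "end", "strand", "role"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    features = []
    for row in df.itertuples(index=False):
        cls = getattr(row, class_field, None)
        if cls is not None and (not isinstance(cls, str) or cls == ""):
            cls = None  # NaN from pandas
        features.append(
            GenomicFeature(
                feature_id=row.feature_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                role=row.role,
                lnc_class=cls,
            )
        )
    return features


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (``feature_id<TAB>lnc_class``) sidecar for BED input."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "lnc_class"],
                     dtype=str, comment="#")
    return dict(zip(df["feature_id"], df["lnc_class"]))


# ---------------------------------------------------------------------------
# annotation writers
# ---------------------------------------------------------------------------

def write_gff3(features: Sequence[GenomicFeature], path: str | Path,
               source: str = "lncpair") -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.lnc_class is not None:
                attrs += f";lnc_class={f.lnc_class}"
            fh.write(
                f"{f.chrom}\t{source}\t{f.role}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_bed(features: Sequence[GenomicFeature], path: str | Path,
              class_map_path: Optional[str | Path] = None) -> None:
    """Write BED6; lncRNA classes go to a sidecar TSV if a path is given."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t.\t{f.strand}\n")
    if class_map_path is not None:
        with open(class_map_path, "w") as fh:
            for f in features:
                if f.role == "lncRNA":
                    fh.write(f"{f.feature_id}\t{f.lnc_class}\n")


def write_annotation_tsv(features: Sequence[GenomicFeature], path: str | Path) -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "role": f.role,
            "lnc_class": f.lnc_class if f.lnc_class is not None else "",
        }
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path, comparison: str,
                  known_comparisons: Optional[Iterable[str]] = None
                  ) -> list[DERecord]:
    """Read a DE table (TSV with header ``feature_id  log2fc  padj``).

    Rows with a missing padj are retained with ``padj = 1`` (treated as not
    significant). Duplicate feature ids and non-numeric fold-changes are
    errors.
    """
    if known_comparisons is not None and comparison not in set(known_comparisons):
        raise ValueError(
            f"unknown comparison {comparison!r}; expected one of "
            f"{sorted(known_comparisons)}"
        )
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str},
                     float_precision="round_trip")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    dup = df["feature_id"][df["feature_id"].duplicated()]
    if len(dup):
        raise ValueError(
            f"{path}: duplicate (feature_id, comparison) for "
            f"{sorted(dup.unique())} in {comparison}"
        )
    records = []
    for row in df.itertuples(index=False):
        try:
            lfc = float(row.log2fc)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric log2fc {row.log2fc!r} for "
                f"{row.feature_id!r}"
            ) from exc
        if math.isnan(lfc):
            raise ValueError(f"{path}: missing log2fc for {row.feature_id!r}")
        padj = float(row.padj) if not pd.isna(row.padj) else 1.0
        records.append(DERecord(row.feature_id, comparison, lfc, padj))
    return records


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"feature_id": r.feature_id, "log2fc": r.log2fc, "padj": r.padj}
         for r in records]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
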