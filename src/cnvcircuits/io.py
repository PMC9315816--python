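"""Readers and writers for the plain-text formats the pipeline touches.

Formats: GMT gene sets, BED / 1-based-inclusive interval tables, TSV PPI
edge lists (fractional or STRING-style 0-1000 integer scores), expression
matrix + sample-metadata TSV pairs, YAML circuit maps, subject tables and
one-symbol-per-line gene lists.  Every writer is the inverse of its
reader on its own output.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    AGE_UNITS,
    AnnotationTable,
    CircuitMap,
    DEFAULT_REGION_VOCAB,
    ExpressionBundle,
    GeneAnnotation,
    GeneSetCollection,
    GenomicInterval,
    ParseError,
    PPIEdge,
    SubjectRecord,
    ValidationError,
)

DIALECTS = ("bed", "one_based_inclusive")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated.  The background is left
    unset; supply one separately if the reference universe is larger than
    the union of the sets.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Intervals (BED and 1-based inclusive)
# ---------------------------------------------------------------------------

def read_intervals(
    path: str | Path, dialect: str = "bed"
) -> list[tuple[str, GenomicInterval]]:
    """Read named intervals from a 4-column table (chrom, start, end, name).

    ``dialect="bed"`` stores coordinates unchanged (already 0-based
    half-open); ``dialect="one_based_inclusive"`` converts clinical-style
    coordinates by ``start - 1`` (end unchanged).
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track ", "browser ")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or end < 0:
                raise ValidationError(f"{path}: line {lineno}: negative coordinate")
            if dialect == "one_based_inclusive":
                start -= 1
            if end <= start:
                raise ValidationError(
                    f"{path}: line {lineno}: empty or inverted interval after conversion"
                )
            out.append((name, GenomicInterval(chrom, start, end)))
    return out


def write_intervals(
    records: Iterable[tuple[str, GenomicInterval]],
    path: str | Path,
    dialect: str = "bed",
) -> None:
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        for name, iv in records:
            start = iv.start + 1 if dialect == "one_based_inclusive" else iv.start
            fh.write(f"{iv.chrom}\t{start}\t{iv.end}\t{name}\n")


def read_annotation(path: str | Path, dialect: str = "bed") -> AnnotationTable:
    """Read a gene annotation table (BED-like; name column = gene symbol)."""
    return AnnotationTable(
        GeneAnnotation(symbol=name, interval=iv)
        for name, iv in read_intervals(path, dialect=dialect)
    )


def write_annotation(
    table: AnnotationTable, path: str | Path, dialect: str = "bed"
) -> None:
    write_intervals(((g.symbol, g.interval) for g in table.genes), path, dialect=dialect)


# ---------------------------------------------------------------------------
# Expression bundle
# ---------------------------------------------------------------------------

def read_expression_bundle(
    matrix_path: str | Path,
    meta_path: str | Path,
    region_vocab: Sequence[str] = DEFAULT_REGION_VOCAB,
) -> ExpressionBundle:
    """Read an expression matrix TSV (rows = genes) and sample-metadata TSV.

    The matrix header's sample ids must exactly match the metadata's
    ``sample_id`` column; sample order is taken from the matrix header.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ParseError(f"{meta_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    mat_ids, meta_ids = set(matrix.columns), set(meta.index)
    if mat_ids != meta_ids:
        raise ValidationError(
            "sample ids differ between matrix and metadata; "
            f"matrix-only: {sorted(mat_ids - meta_ids)}, "
            f"metadata-only: {sorted(meta_ids - mat_ids)}"
        )
    meta = meta.loc[list(matrix.columns)]
    return ExpressionBundle(matrix=matrix, sample_meta=meta, region_vocab=region_vocab)


def write_expression_bundle(
    bundle: ExpressionBundle, matrix_path: str | Path, meta_path: str | Path
) -> None:
    bundle.matrix.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.6f")
    meta = bundle.sample_meta.reset_index(names="sample_id")
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def read_ppi_edges(path: str | Path) -> list[PPIEdge]:
    """Read a TSV edge list (gene_a, gene_b, confidence).

    Confidences are fractional in [0, 1]; STRING-style integer scores
    (0-1000) are detected by any value exceeding 1 and divided by 1000.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric confidence") from exc
            rows.append((fields[0], fields[1], conf))
    if rows and max(conf for _, _, conf in rows) > 1.0:
        rows = [(a, b, conf / 1000.0) for a, b, conf in rows]
    return [PPIEdge(gene_a=a, gene_b=b, confidence=conf) for a, b, conf in rows]


def write_ppi_edges(edges: Iterable[PPIEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.confidence:.6f}\n")


# ---------------------------------------------------------------------------
# Circuit map
# ---------------------------------------------------------------------------

def read_circuit_map(path: str | Path) -> CircuitMap:
    """Read a circuit map from YAML (``circuit: [regions...]`` or
    ``circuit: "R1, R2"``) or from a 2-column TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: expected a mapping circuit -> regions")
        circuits = {}
        for name, regions in raw.items():
            if isinstance(regions, str):
                regions = [r.strip() for r in regions.split(",") if r.strip()]
            circuits[str(name)] = frozenset(str(r) for r in regions)
        return CircuitMap(circuits=circuits)
    circuits = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            circuits[fields[0]] = frozenset(
                r.strip() for r in fields[1].split(",") if r.strip()
            )
    return CircuitMap(circuits=circuits)


def write_circuit_map(cmap: CircuitMap, path: str | Path) -> None:
    data = {name: sorted(regions) for name, regions in sorted(cmap.circuits.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------

def _format_intervals(ivs: Sequence[GenomicInterval]) -> str:
    return ";".join(f"{iv.chrom}:{iv.start}-{iv.end}" for iv in ivs)


def _parse_intervals(text: str) -> list[GenomicInterval]:
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            chrom, span = token.rsplit(":", 1)
            start_s, end_s = span.split("-", 1)
            out.append(GenomicInterval(chrom, int(start_s), int(end_s)))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"bad interval token {token!r}: {exc}") from exc
    return out


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read a subject table TSV.

    Columns: ``subject_id``, ``microarray_status``, ``cnv_intervals``
    (semicolon-separated ``chrom:start-end``, 0-based half-open, empty for
    normal subjects), plus ``pcq_<item>`` and ``vineland_<subscale>`` score
    columns.  Empty score cells are treated as missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "cnv_intervals": str})
    required = {"subject_id", "microarray_status"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    pcq_cols = [c for c in df.columns if c.startswith("pcq_")]
    vin_cols = [c for c in df.columns if c.startswith("vineland_")]
    subjects = []
    for _, row in df.iterrows():
        raw_iv = row.get("cnv_intervals", "")
        ivs = _parse_intervals(raw_iv) if isinstance(raw_iv, str) else []
        pcq = {
            c[len("pcq_"):]: int(row[c])
            for c in pcq_cols
            if not pd.isna(row[c])
        }
        vineland = {
            c[len("vineland_"):]: float(row[c])
            for c in vin_cols
            if not pd.isna(row[c])
        }
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                microarray_status=str(row["microarray_status"]),
                cnv_intervals=ivs,
                pcq=pcq,
                vineland=vineland,
            )
        )
    return subjects


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    pcq_items = sorted({item for s in subjects for item in s.pcq})
    vin_items = sorted({item for s in subjects for item in s.vineland})
    rows = []
    for s in subjects:
        row: dict[str, object] = {
            "subject_id": s.subject_id,
            "microarray_status": s.microarray_status,
            "cnv_intervals": _format_intervals(s.cnv_intervals),
        }
        for item in pcq_items:
            row[f"pcq_{item}"] = s.pcq.get(item, "")
        for item in vin_items:
            v = s.vineland.get(item, math.nan)
            row[f"vineland_{item}"] = "" if math.isnan(v) else f"{v:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plain gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
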