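"""Readers and writers for SGD-style tables and the instance CSV.

Two tab-separated inputs drive the pipeline: a gene feature table (one
row per genomic feature with systematic name, chromosome, start, stop,
strand — the layout of SGD's ``SGD_features.tab``) and a GO Slim mapping
table (one row per gene/aspect/term — the layout of
``go_slim_mapping.tab``). Column positions drift across file versions,
so both parsers take an explicit column-map dialect; defaults match the
modern SGD layouts.

The instance CSV is the long-format training file: header
``Chromosome Number, Start, Stop, Strand, Neighbour number, Neighbour
strand, Distance, Neighbour GO aspect, Neighbour GO Slim term,
GO aspect, GO Slim term`` with ``?`` as the missing-value literal.
Datasets built with k = 0 omit the five neighbour columns; datasets
built without location omit the first four columns.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .genome import ASPECTS, GeneFeature, GenomeError, GoSlimAnnotation, normalize_chromosome
from .instances import TrainingInstance

logger = logging.getLogger(__name__)

MISSING = "?"

LOCATION_COLUMNS = ("Chromosome Number", "Start", "Stop", "Strand")
NEIGHBOUR_COLUMNS = (
    "Neighbour number",
    "Neighbour strand",
    "Distance",
    "Neighbour GO aspect",
    "Neighbour GO Slim term",
)
GENE_COLUMNS = ("GO aspect", "GO Slim term")


class FileFormatError(ValueError):
    """Input file exists but holds no usable rows / wrong layout."""


@dataclass
class ParseReport:
    """Bookkeeping for the never-invent-records invariant: kept + skipped = rows."""

    rows: int = 0
    kept: int = 0
    skipped: int = 0
    deduplicated: int = 0


@dataclass(frozen=True)
class FeatureDialect:
    """Column map for a gene feature table (0-based indices)."""

    id_col: int = 3
    chromosome_col: int = 8
    start_col: int = 9
    stop_col: int = 10
    strand_col: int = 11
    feature_type_col: int | None = 1
    #: restrict to these feature types; None keeps every row with coordinates
    feature_types: tuple[str, ...] | None = None
    strand_map: dict = field(default_factory=lambda: {"W": "W", "C": "C"})
    sep: str = "\t"


#: Modern SGD_features.tab layout.
SGD_FEATURES_DIALECT = FeatureDialect()


@dataclass(frozen=True)
class MappingDialect:
    """Column map for a GO Slim mapping table (0-based indices)."""

    gene_col: int = 0
    aspect_col: int = 3
    term_col: int = 4
    sep: str = "\t"


#: Modern go_slim_mapping.tab layout.
GO_SLIM_DIALECT = MappingDialect()


def _read_rows(path: str | Path, sep: str) -> list[list[str]]:
    path = Path(path)
    with path.open(newline="") as fh:
        return [row for row in csv.reader(fh, delimiter=sep) if row and any(c.strip() for c in row)]


def parse_gene_features(
    path: str | Path,
    dialect: FeatureDialect = SGD_FEATURES_DIALECT,
) -> tuple[list[GeneFeature], ParseReport]:
    """Parse a gene feature table into :class:`GeneFeature` records.

    Rows with unparsable coordinates, unknown chromosomes/strands, or a
    feature type outside ``dialect.feature_types`` are skipped and
    counted. Zero qualifying rows is a :class:`FileFormatError`.
    """
    rows = _read_rows(path, dialect.sep)
    report = ParseReport(rows=len(rows))
    out: list[GeneFeature] = []
    for row in rows:
        try:
            if dialect.feature_types is not None and dialect.feature_type_col is not None:
                if row[dialect.feature_type_col].strip() not in dialect.feature_types:
                    raise ValueError("feature type filtered")
            gene_id = row[dialect.id_col].strip()
            if not gene_id:
                raise ValueError("empty gene id")
            chrom = normalize_chromosome(row[dialect.chromosome_col])
            start = int(row[dialect.start_col])
            stop = int(row[dialect.stop_col])
            strand_raw = row[dialect.strand_col].strip()
            strand = dialect.strand_map.get(strand_raw, strand_raw)
            out.append(
                GeneFeature(gene_id=gene_id, chromosome=chrom, start=start, stop=stop, strand=strand)
            )
            report.kept += 1
        except (IndexError, ValueError, GenomeError):
            report.skipped += 1
    if not out:
        raise FileFormatError(f"no parsable gene feature rows in {path}")
    if report.skipped:
        logger.info("%s: skipped %d of %d rows", path, report.skipped, report.rows)
    return out, report


def parse_go_slim(
    path: str | Path,
    dialect: MappingDialect = GO_SLIM_DIALECT,
) -> tuple[list[GoSlimAnnotation], ParseReport]:
    """Parse a GO Slim mapping table into deduplicated annotations.

    Rows with an aspect outside {C, P, F} or an empty term are skipped
    and counted; duplicate (gene, aspect, term) triples are kept once.
    """
    rows = _read_rows(path, dialect.sep)
    report = ParseReport(rows=len(rows))
    seen: set[tuple[str, str, str]] = set()
    out: list[GoSlimAnnotation] = []
    for row in rows:
        try:
            gene_id = row[dialect.gene_col].strip()
            aspect = row[dialect.aspect_col].strip()
            term = row[dialect.term_col].strip()
            if not gene_id or aspect not in ASPECTS or not term:
                raise ValueError("bad row")
        except (IndexError, ValueError):
            report.skipped += 1
            continue
        key = (gene_id, aspect, term)
        if key in seen:
            report.deduplicated += 1
            report.kept += 1  # row was valid, just redundant
            continue
        seen.add(key)
        out.append(GoSlimAnnotation(gene_id=gene_id, aspect=aspect, term=term))
        report.kept += 1
    if report.skipped or report.deduplicated:
        logger.info(
            "%s: skipped %d, deduplicated %d of %d rows",
            path, report.skipped, report.deduplicated, report.rows,
        )
    return out, report


# ---------------------------------------------------------------------------
# Instance CSV

def _schema_flags(inst: TrainingInstance) -> tuple[bool, bool]:
    return inst.has_location, inst.has_neighbour_block


def instance_header(has_location: bool, has_neighbour: bool) -> list[str]:
    cols: list[str] = []
    if has_location:
        cols += LOCATION_COLUMNS
    if has_neighbour:
        cols += NEIGHBOUR_COLUMNS
    cols += GENE_COLUMNS
    return cols


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return str(int(value)) if value == int(value) else repr(value)
    return str(value)


def write_instances(instances: list[TrainingInstance], path: str | Path) -> None:
    """Write rows as CSV in the fixed column order, ``?`` for missing.

    All instances must share one schema (same presence of the location
    and neighbour blocks); an empty list writes the full header only.
    """
    path = Path(path)
    if instances:
        has_location, has_neighbour = _schema_flags(instances[0])
        for inst in instances[1:]:
            if _schema_flags(inst) != (has_location, has_neighbour):
                raise ValueError("instances do not share one schema")
    else:
        has_location, has_neighbour = True, True
    header = instance_header(has_location, has_neighbour)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for inst in instances:
            row: list[str] = []
            if has_location:
                row += [_fmt(inst.chromosome), _fmt(inst.start), _fmt(inst.stop), _fmt(inst.strand)]
            if has_neighbour:
                row += [
                    _fmt(inst.neighbour_number),
                    _fmt(inst.neighbour_strand),
                    _fmt(inst.distance),
                    _fmt(inst.neighbour_aspect),
                    _fmt(inst.neighbour_term),
                ]
            row += [_fmt(inst.gene_aspect), _fmt(inst.class_term)]
            w.writerow(row)


def read_instances(path: str | Path) -> list[TrainingInstance]:
    """Read an instance CSV back; inverse of :func:`write_instances`.

    Gene ids are not serialized, so the returned instances carry
    ``gene_id=None``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FileFormatError(f"{path} is empty") from None
        has_location = header[: len(LOCATION_COLUMNS)] == list(LOCATION_COLUMNS)
        rest = header[len(LOCATION_COLUMNS):] if has_location else header
        has_neighbour = rest[: len(NEIGHBOUR_COLUMNS)] == list(NEIGHBOUR_COLUMNS)
        if instance_header(has_location, has_neighbour) != header:
            raise FileFormatError(f"{path}: unrecognized instance header {header!r}")

        def opt(v: str, conv=str):
            return None if v == MISSING else conv(v)

        out: list[TrainingInstance] = []
        for row in reader:
            if not row:
                continue
            if len(row) != len(header):
                raise FileFormatError(f"{path}: row width {len(row)} != header width")
            i = 0
            kw: dict = {}
            if has_location:
                kw.update(
                    chromosome=opt(row[i]),
                    start=opt(row[i + 1], int),
                    stop=opt(row[i + 2], int),
                    strand=opt(row[i + 3]),
                )
                i += 4
            if has_neighbour:
                kw.update(
                    neighbour_number=opt(row[i], int),
                    neighbour_strand=opt(row[i + 1]),
                    distance=opt(row[i + 2], float),
                    neighbour_aspect=opt(row[i + 3]),
                    neighbour_term=opt(row[i + 4]),
                )
                i += 5
            out.append(TrainingInstance(gene_aspect=row[i], class_term=row[i + 1], **kw))
    return out
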