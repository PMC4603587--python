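"""Reading, validation and derived quantities for tabular protein-alignment hit tables.

A hit table is a BLAST-style tab-separated file (``-outfmt 6`` layout extended
with subject length and subject title) produced by an external ``blastx``-type
search of assembled gene sequences against one reference protein database.
This module parses those files into :class:`AlignmentHit` records, computes
protein coverage for each hit, and truncates each query's hit list to the
configured per-database maximum using the same total order that later drives
best-hit selection, so downstream results never depend on the row order a
search tool happened to emit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Default column order: the common 12-column tabular layout extended with
#: subject length (``slen``) and subject title (``stitle``).
DEFAULT_DIALECT: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "slen", "stitle",
)

#: Columns a dialect must name for a row to become an AlignmentHit.
REQUIRED_COLUMNS: frozenset[str] = frozenset(
    {"qseqid", "sseqid", "length", "evalue", "bitscore", "slen"}
)


class HitTableFormatError(ValueError):
    """The file or dialect cannot yield valid hits at all (e.g. missing column)."""


class RowValidationError(ValueError):
    """A single row failed numeric or range validation; carries the line number."""

    def __init__(self, line_number: int, message: str) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class BlastParams:
    """External search settings kept as provenance metadata.

    Stored verbatim on each :class:`DatabaseSpec`; never used in computation
    (the search itself is external to this package). ``max_hits`` is the only
    field this package reads: the per-query retention cap.
    """

    evalue_cutoff: float = 1e-4
    max_hits: int = 20
    gapopen: int = 11
    gapextend: int = 1
    word_size: int = 3
    matrix: str = "BLOSUM62"


@dataclass(frozen=True)
class DatabaseSpec:
    """Identity, species binding and arbitration priority of one reference database.

    ``kind`` is ``"species_genome"`` for a database holding proteins of a
    single organism (its name goes in ``bound_species``), or ``"general"``
    for a broad multi-organism database whose hit titles must be parsed for
    the organism. ``priority_rank`` orders the informed-annotation ladder;
    1 is the highest priority.
    """

    name: str
    kind: str
    priority_rank: int
    bound_species: str | None = None
    blast_params: BlastParams = field(default_factory=BlastParams)

    def __post_init__(self) -> None:
        if self.kind not in ("species_genome", "general"):
            raise ValueError(f"kind must be 'species_genome' or 'general', got {self.kind!r}")
        if self.priority_rank < 1:
            raise ValueError("priority_rank must be a positive integer")
        if self.kind == "species_genome" and not self.bound_species:
            raise ValueError(f"database {self.name!r} is species-bound but names no species")
        if self.kind == "general" and self.bound_species:
            raise ValueError(f"general database {self.name!r} must not bind a species")


def validate_registry(registry: Sequence[DatabaseSpec]) -> dict[str, DatabaseSpec]:
    """Check rank/name uniqueness and return a name -> spec lookup."""
    ranks = [db.priority_rank for db in registry]
    if len(set(ranks)) != len(ranks):
        raise ValueError(f"priority_rank values are not unique: {sorted(ranks)}")
    names = [db.name for db in registry]
    if len(set(names)) != len(names):
        raise ValueError(f"database names are not unique: {sorted(names)}")
    return {db.name: db for db in registry}


@dataclass(frozen=True)
class AlignmentHit:
    """One query -> subject protein alignment row plus derived coverage."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    align_length: int
    subject_length: int
    database: str
    coverage: float
    percent_identity: float = 0.0
    subject_title: str = ""

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError(f"bitscore must be > 0, got {self.bitscore}")
        if self.align_length < 1:
            raise ValueError(f"align_length must be >= 1, got {self.align_length}")
        if self.subject_length < 1:
            raise ValueError(f"subject_length must be >= 1, got {self.subject_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must lie in [0, 1], got {self.coverage}")


def compute_coverage(align_length: int, subject_length: int) -> float:
    """Protein coverage: aligned residues / subject protein length, clamped to [0, 1].

    Coverage measures how much of the database (subject) protein the alignment
    spans. Gapped alignments can exceed the subject length, hence the clamp.
    """
    if subject_length < 1:
        raise ValueError(f"subject_length must be >= 1, got {subject_length}")
    if align_length < 1:
        raise ValueError(f"align_length must be >= 1, got {align_length}")
    return min(align_length / subject_length, 1.0)


def ranking_key(hit: AlignmentHit) -> tuple:
    """Total order for hits: bitscore desc, coverage desc, e-value asc, subject id asc.

    Bitscore leads because it is database-size independent and therefore
    comparable across searches of differently sized databases (unlike the
    e-value); coverage breaks ties; the remaining keys guarantee determinism.
    """
    return (-hit.bitscore, -hit.coverage, hit.evalue, hit.subject_id)


def truncate_per_query(hits: Iterable[AlignmentHit], max_hits: int) -> list[AlignmentHit]:
    """Keep at most ``max_hits`` hits per query, the best under :func:`ranking_key`."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[AlignmentHit] = []
    for q in sorted(by_query):
        out.extend(sorted(by_query[q], key=ranking_key)[:max_hits])
    return out


def _parse_row(
    row: Sequence[str], columns: Sequence[str], db: DatabaseSpec, line_number: int
) -> AlignmentHit:
    # trailing optional columns (e.g. stitle) may be absent from short rows
    values = dict(zip(columns, row))
    missing = REQUIRED_COLUMNS - values.keys()
    if missing:
        raise RowValidationError(line_number, f"row is missing fields {sorted(missing)}")
    try:
        bitscore = float(values["bitscore"])
        evalue = float(values["evalue"])
        align_length = int(float(values["length"]))
        subject_length = int(float(values["slen"]))
        pident = float(values.get("pident", 0.0) or 0.0)
    except ValueError as exc:
        raise RowValidationError(line_number, f"non-numeric field: {exc}") from None
    try:
        coverage = compute_coverage(align_length, subject_length)
        return AlignmentHit(
            query_id=values["qseqid"],
            subject_id=values["sseqid"],
            bitscore=bitscore,
            evalue=evalue,
            align_length=align_length,
            subject_length=subject_length,
            database=db.name,
            coverage=coverage,
            percent_identity=pident,
            subject_title=values.get("stitle", "") or "",
        )
    except ValueError as exc:
        raise RowValidationError(line_number, str(exc)) from None


def parse_hit_table(
    path: str | Path,
    db: DatabaseSpec,
    dialect: Sequence[str] = DEFAULT_DIALECT,
    skip_invalid: bool = False,
) -> list[AlignmentHit]:
    """Parse one database's TSV hit table into validated :class:`AlignmentHit` records.

    Every retained row gets its protein coverage computed, and each query's
    hit list is truncated to ``db.blast_params.max_hits`` best hits under
    :func:`ranking_key`. Invalid rows raise :class:`RowValidationError` with
    their line number unless ``skip_invalid`` is set, in which case they are
    logged and dropped (reported, not silent).
    """
    missing = REQUIRED_COLUMNS - set(dialect)
    if missing:
        raise HitTableFormatError(
            f"dialect does not name required column(s): {', '.join(sorted(missing))}"
        )
    path = Path(path)
    hits: list[AlignmentHit] = []
    n_bad = 0
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for line_number, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            try:
                hits.append(_parse_row(row, dialect, db, line_number))
            except RowValidationError as exc:
                if not skip_invalid:
                    raise
                n_bad += 1
                logger.warning("%s: skipped invalid row (%s)", path.name, exc)
    if n_bad:
        logger.warning("%s: skipped %d invalid row(s) in total", path.name, n_bad)
    if not hits:
        logger.warning("%s: hit table is empty", path.name)
        return []
    return truncate_per_query(hits, db.blast_params.max_hits)


def write_hit_table(
    hits: Iterable[AlignmentHit],
    path: str | Path,
    dialect: Sequence[str] = DEFAULT_DIALECT,
) -> None:
    """Serialise hits back to TSV in dialect order, appending coverage and database."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            row_map = {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": format(h.percent_identity, "g"),
                "length": str(h.align_length),
                "mismatch": "0",
                "gapopen": "0",
                "qstart": "0",
                "qend": "0",
                "sstart": "0",
                "send": "0",
                "evalue": format(h.evalue, "g"),
                "bitscore": format(h.bitscore, "g"),
                "slen": str(h.subject_length),
                "stitle": h.subject_title,
            }
            writer.writerow([row_map.get(c, "") for c in dialect]
                            + [format(h.coverage, ".6g"), h.database])
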