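"""Cross-database best-hit arbitration: unconstrained and informed annotation.

Each assembled gene may hit proteins in several reference databases (two
species-bound genome databases plus general databases such as Swiss-Prot,
TrEMBL and NCBI nr in the motivating study design). Arbitration proceeds in
two passes:

* **unconstrained** — take the best hit per database, then the best of those
  across databases purely by score (bitscore, then protein coverage). No
  organism prior: comparable across databases because bitscore, unlike the
  e-value, does not depend on database size.
* **informed** — once the dominant organisms are known and species-bound
  databases are registered with priority ranks, hits that are nearly as good
  as the unconstrained winner (relative bitscore AND coverage deficits both
  strictly below a tolerance, 10 % by default) form a competing set, and the
  competitor from the highest-priority database wins.

Organism-of-origin is the bound species for species databases; for general
databases it is parsed from the subject title (UniProt ``OS=`` convention,
else a trailing bracketed NCBI organism).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .blast_io import AlignmentHit, DatabaseSpec, ranking_key, validate_registry

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"
UNPARSED = "unparsed"

_OS_RE = re.compile(r"\bOS=(.+?)(?:\s+(?:OX|GN|PE|SV)=|\s*$)")
_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


@dataclass(frozen=True)
class WindowRule:
    """Similarity window for the informed pass.

    A per-database best hit h competes with the top hit T when both relative
    deficits, (T.bitscore - h.bitscore)/T.bitscore and
    (T.coverage - h.coverage)/T.coverage, are strictly below the tolerances.
    Strict ``<`` resolves the boundary; relative difference keeps the rule
    scale-free.
    """

    bitscore_tolerance: float = 0.10
    coverage_tolerance: float = 0.10

    def __post_init__(self) -> None:
        for name, tol in (("bitscore_tolerance", self.bitscore_tolerance),
                          ("coverage_tolerance", self.coverage_tolerance)):
            if not 0.0 <= tol < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {tol}")

    def admits(self, top: AlignmentHit, hit: AlignmentHit) -> bool:
        b_rel = (top.bitscore - hit.bitscore) / top.bitscore
        c_rel = (top.coverage - hit.coverage) / top.coverage if top.coverage > 0 else 0.0
        return b_rel < self.bitscore_tolerance and c_rel < self.coverage_tolerance


@dataclass(frozen=True)
class AnnotationRecord:
    """Arbitration outcome for one gene."""

    query_id: str
    chosen_hit: AlignmentHit | None
    source_database: str
    organism: str
    mode: str
    competing_set: tuple[AlignmentHit, ...] = ()
    #: (database, bitscore, coverage, admitted-to-window) per per-database best hit
    arbitration_trace: tuple[tuple[str, float, float, bool], ...] = ()

    def __post_init__(self) -> None:
        if (self.chosen_hit is None) != (self.source_database == UNKNOWN):
            raise ValueError("chosen_hit is absent iff source_database is 'unknown'")
        if self.chosen_hit is None and self.organism != UNKNOWN:
            raise ValueError("a no-hit record must carry organism 'unknown'")


def parse_organism(subject_title: str) -> str:
    """Extract an organism name from a free-text subject description line.

    Recognises the UniProt ``OS=Genus species ... OX=`` convention first, then
    a trailing ``[Genus species]`` NCBI-style bracket; returns ``"unparsed"``
    when neither applies.
    """
    if subject_title:
        m = _OS_RE.search(subject_title)
        if m:
            return m.group(1).strip()
        m = _BRACKET_RE.search(subject_title)
        if m:
            return m.group(1).strip()
    return UNPARSED


def organism_of(hit: AlignmentHit, db: DatabaseSpec) -> str:
    """Organism of a hit: the database's bound species, else parsed from the title."""
    if db.kind == "species_genome":
        return db.bound_species  # type: ignore[return-value]
    return parse_organism(hit.subject_title)


def rank_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Totally order hits by bitscore desc, coverage desc, e-value asc, subject id asc."""
    ordered = sorted(hits, key=ranking_key)
    if not ordered:
        raise ValueError("rank_hits requires a non-empty hit collection")
    return ordered


def best_hit_per_database(
    hits: Iterable[AlignmentHit], registry: Sequence[DatabaseSpec]
) -> dict[str, AlignmentHit]:
    """Within-database winner for each database with at least one hit."""
    lookup = validate_registry(registry)
    per_db: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.database not in lookup:
            raise ValueError(f"hit references unregistered database {h.database!r}")
        per_db.setdefault(h.database, []).append(h)
    return {name: rank_hits(db_hits)[0] for name, db_hits in per_db.items()}


def _unknown_record(query_id: str, mode: str) -> AnnotationRecord:
    return AnnotationRecord(query_id, None, UNKNOWN, UNKNOWN, mode)


def unconstrained_select(
    query_id: str,
    per_db_best: Mapping[str, AlignmentHit],
    registry: Sequence[DatabaseSpec],
) -> AnnotationRecord:
    """Score-only winner across databases (no organism priority)."""
    lookup = validate_registry(registry)
    if not per_db_best:
        return _unknown_record(query_id, "unconstrained")
    winner = rank_hits(per_db_best.values())[0]
    trace = tuple(
        (name, h.bitscore, h.coverage, h is winner)
        for name, h in sorted(per_db_best.items())
    )
    return AnnotationRecord(
        query_id=query_id,
        chosen_hit=winner,
        source_database=winner.database,
        organism=organism_of(winner, lookup[winner.database]),
        mode="unconstrained",
        arbitration_trace=trace,
    )


def informed_select(
    query_id: str,
    per_db_best: Mapping[str, AlignmentHit],
    registry: Sequence[DatabaseSpec],
    window: WindowRule = WindowRule(),
) -> AnnotationRecord:
    """Species-priority arbitration within the similarity window.

    The unconstrained winner T anchors the window; every per-database best hit
    within the window (T included) competes, and the competitor whose database
    has the smallest priority rank is chosen. With zero tolerances this
    degenerates to the unconstrained rule.
    """
    lookup = validate_registry(registry)
    if not per_db_best:
        return _unknown_record(query_id, "informed")
    top = rank_hits(per_db_best.values())[0]
    # the top hit is always its own competitor, even at zero tolerance
    competing = [h for h in per_db_best.values()
                 if h is top or window.admits(top, h)]
    chosen = min(competing, key=lambda h: lookup[h.database].priority_rank)
    trace = tuple(
        (name, h.bitscore, h.coverage, window.admits(top, h))
        for name, h in sorted(per_db_best.items())
    )
    return AnnotationRecord(
        query_id=query_id,
        chosen_hit=chosen,
        source_database=chosen.database,
        organism=organism_of(chosen, lookup[chosen.database]),
        mode="informed",
        competing_set=tuple(sorted(competing, key=ranking_key)),
        arbitration_trace=trace,
    )


def annotate_all(
    hit_tables: Mapping[str, Iterable[AlignmentHit]],
    registry: Sequence[DatabaseSpec],
    window: WindowRule = WindowRule(),
    mode: str = "informed",
    universe: Iterable[str] | None = None,
) -> list[AnnotationRecord]:
    """Arbitrate every distinct query across all databases.

    ``hit_tables`` maps database name -> hits from that database's search.
    Genes listed in ``universe`` but absent from every table are emitted with
    organism ``"unknown"`` rather than omitted, so no-hit genes stay part of
    the accounting. Duplicate (query, database, subject) rows are deduplicated
    (best-ranked kept) with a warning. Output is deterministic given inputs.
    """
    if mode not in ("unconstrained", "informed"):
        raise ValueError(f"mode must be 'unconstrained' or 'informed', got {mode!r}")
    lookup = validate_registry(registry)

    by_query: dict[str, dict[str, list[AlignmentHit]]] = {}
    seen: dict[tuple[str, str, str], AlignmentHit] = {}
    n_dup = 0
    for db_name, hits in hit_tables.items():
        if db_name not in lookup:
            raise ValueError(f"hit table for unregistered database {db_name!r}")
        for h in hits:
            key = (h.query_id, h.database, h.subject_id)
            if key in seen:
                n_dup += 1
                if ranking_key(h) >= ranking_key(seen[key]):
                    continue
                prev = seen[key]
                by_query[prev.query_id][prev.database].remove(prev)
            seen[key] = h
            by_query.setdefault(h.query_id, {}).setdefault(h.database, []).append(h)
    if n_dup:
        logger.warning("deduplicated %d repeated (query, database, subject) row(s)", n_dup)

    query_ids = set(by_query)
    if universe is not None:
        query_ids |= set(universe)

    records: list[AnnotationRecord] = []
    for qid in sorted(query_ids):
        per_db = by_query.get(qid, {})
        per_db_best = {name: rank_hits(hits)[0] for name, hits in per_db.items() if hits}
        if mode == "unconstrained":
            records.append(unconstrained_select(qid, per_db_best, registry))
        else:
            records.append(informed_select(qid, per_db_best, registry, window))
    return records


def annotations_to_frame(records: Sequence[AnnotationRecord]):
    """Tidy table of arbitration outcomes (one row per gene)."""
    import pandas as pd

    rows = []
    for r in records:
        h = r.chosen_hit
        rows.append({
            "query_id": r.query_id,
            "organism": r.organism,
            "source_database": r.source_database,
            "bitscore": h.bitscore if h else float("nan"),
            "coverage": h.coverage if h else float("nan"),
            "evalue": h.evalue if h else float("nan"),
            "n_competing": len(r.competing_set),
            "mode": r.mode,
        })
    return pd.DataFrame(
        rows,
        columns=["query_id", "organism", "source_database", "bitscore",
                 "coverage", "evalue", "n_competing", "mode"],
    )
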