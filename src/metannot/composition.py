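"""Organism composition of the differentially expressed gene set.

Partitions annotated DE genes into taxon classes (host plant, other plants,
metazoa, bacteria, fungi, other, unknown), stratified overall and by
organ x treatment, and provides the per-source-database accounting of the
final annotation. Percentages are computed from exact unique-gene counts and
displayed at one decimal with half-up rounding; the raw counts are always
kept alongside so nothing is lost to rounding.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .arbiter import UNKNOWN, UNPARSED, AnnotationRecord

logger = logging.getLogger(__name__)

TAXON_CLASSES = (
    "host_plant", "other_plant", "metazoa", "bacteria", "fungi", "other", "unknown",
)

#: Default organism -> taxon class table for the organisms the synthetic
#: generator emits; extend or replace for real catalogues.
DEFAULT_TAXA: dict[str, str] = {
    "Salix purpurea": "host_plant",
    "Populus trichocarpa": "other_plant",
    "Arabidopsis thaliana": "other_plant",
    "Vitis vinifera": "other_plant",
    "Tetranychus urticae": "metazoa",
    "Drosophila melanogaster": "metazoa",
    "Propionibacterium acnes": "bacteria",
    "Bacillus stratosphericus": "bacteria",
    "Klebsiella pneumoniae": "bacteria",
    "Fusarium oxysporum": "fungi",
    "Saccharomyces cerevisiae": "fungi",
}


class TaxonMap:
    """Total mapping organism name -> taxon class with an ``other`` fallback.

    ``unknown`` (no hit) maps to the unknown class; ``unparsed`` titles fall
    back to ``other`` — they were annotated, just without a recognisable
    organism string.
    """

    def __init__(self, table: Mapping[str, str] | None = None) -> None:
        self.table = dict(DEFAULT_TAXA if table is None else table)
        bad = set(self.table.values()) - set(TAXON_CLASSES)
        if bad:
            raise ValueError(f"unrecognised taxon class(es): {sorted(bad)}")

    def group_of(self, organism: str) -> str:
        if organism == UNKNOWN:
            return "unknown"
        if organism == UNPARSED:
            return "other"
        return self.table.get(organism, "other")


def round_percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage from exact counts, half-up rounded for display."""
    if total <= 0:
        raise ValueError("total must be positive")
    exact = Decimal(count) * 100 / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def _organism_lookup(
    annotations: Sequence[AnnotationRecord] | pd.DataFrame,
) -> dict[str, str]:
    if isinstance(annotations, pd.DataFrame):
        return dict(zip(annotations["query_id"], annotations["organism"]))
    return {r.query_id: r.organism for r in annotations}


def _source_lookup(
    annotations: Sequence[AnnotationRecord] | pd.DataFrame,
) -> dict[str, str]:
    if isinstance(annotations, pd.DataFrame):
        return dict(zip(annotations["query_id"], annotations["source_database"]))
    return {r.query_id: r.source_database for r in annotations}


def compose(
    annotations: Sequence[AnnotationRecord] | pd.DataFrame,
    de_calls: pd.DataFrame,
    taxa: TaxonMap | None = None,
    by_organ_treatment: bool = True,
) -> pd.DataFrame:
    """Count unique DE genes per taxon class, overall and per organ x treatment.

    ``de_calls`` must already be PPDE-filtered. A gene DE in two organs counts
    once in the ``overall`` stratum and once per organ stratum; within an
    organ it is assigned to the treatment in which its mean FPKM is higher
    (the sign of its fold change), and contributes to neither treatment panel
    when the fold change is exactly zero. DE genes missing from the
    annotations are counted as ``unknown`` with a warning.
    """
    taxa = taxa or TaxonMap()
    if de_calls.empty:
        logger.warning("compose: empty DE set, returning empty table")
        return pd.DataFrame(
            columns=["stratum", "group", "unique_gene_count", "percentage"]
        )
    organism_by_gene = _organism_lookup(annotations)

    missing = set(de_calls["gene_id"]) - set(organism_by_gene)
    if missing:
        logger.warning(
            "compose: %d DE gene(s) absent from annotations, counted as unknown",
            len(missing),
        )

    def group_of(gene: str) -> str:
        return taxa.group_of(organism_by_gene.get(gene, UNKNOWN))

    rows: list[dict] = []

    def add_stratum(label: str, genes: Iterable[str]) -> None:
        genes = set(genes)
        if not genes:
            return
        counts: dict[str, int] = {}
        for g in genes:
            counts[group_of(g)] = counts.get(group_of(g), 0) + 1
        total = len(genes)
        for group in TAXON_CLASSES:
            if group in counts:
                rows.append({
                    "stratum": label,
                    "group": group,
                    "unique_gene_count": counts[group],
                    "percentage": round_percentage(counts[group], total),
                })

    add_stratum("overall", de_calls["gene_id"])
    if by_organ_treatment:
        for organ, sub in de_calls.groupby("organ"):
            up = sub.loc[sub["log10_fc"] > 0, "gene_id"]
            down = sub.loc[sub["log10_fc"] < 0, "gene_id"]
            add_stratum(f"{organ}:contaminated", up)
            add_stratum(f"{organ}:non_contaminated", down)
    return pd.DataFrame(rows, columns=["stratum", "group", "unique_gene_count", "percentage"])


def source_database_breakdown(
    annotations: Sequence[AnnotationRecord] | pd.DataFrame,
    registry_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Unique-gene counts and percentages per source database, plus ``unknown``.

    Counts sum to the size of the annotation universe (one record per gene).
    Databases listed in ``registry_names`` appear even with zero winners.
    """
    source_by_gene = _source_lookup(annotations)
    total = len(source_by_gene)
    if total == 0:
        raise ValueError("source_database_breakdown requires at least one annotation")
    counts: dict[str, int] = {}
    for src in source_by_gene.values():
        counts[src] = counts.get(src, 0) + 1
    names = list(registry_names) if registry_names is not None else sorted(
        n for n in counts if n != UNKNOWN
    )
    for n in names:
        counts.setdefault(n, 0)
    counts.setdefault(UNKNOWN, 0)
    ordered = names + [UNKNOWN]
    return pd.DataFrame({
        "database": ordered,
        "unique_gene_count": [counts[n] for n in ordered],
        "percentage": [round_percentage(counts[n], total) for n in ordered],
    })


def foreign_fraction(table: pd.DataFrame, host_groups: Iterable[str]) -> float:
    """Percentage of DE genes from groups outside ``host_groups``.

    Computed from the unrounded counts of the ``overall`` stratum of a
    composition table: 100 * (1 - host count / total).
    """
    host_groups = set(host_groups)
    if not host_groups:
        raise ValueError("host_groups must be non-empty")
    bad = host_groups - set(TAXON_CLASSES)
    if bad:
        raise ValueError(f"unrecognised group name(s): {sorted(bad)}")
    overall = table[table["stratum"] == "overall"]
    if overall.empty:
        raise ValueError("composition table has no 'overall' stratum")
    total = int(overall["unique_gene_count"].sum())
    host = int(overall.loc[overall["group"].isin(host_groups), "unique_gene_count"].sum())
    return 100.0 * (1.0 - host / total)
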