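"""End-to-end driver: annotate -> express -> compose, with provenance capture.

All randomness lives in the synthetic generator; the analysis stages are
seed-free and fully deterministic, so identical inputs and configuration
produce identical output tables. A JSON manifest records the configuration
hash, input checksums, package version and wall-clock time of each run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .arbiter import WindowRule, annotate_all, annotations_to_frame
from .blast_io import DatabaseSpec, parse_hit_table
from .composition import TaxonMap, compose, source_database_breakdown
from .expression import (
    ExpressionMatrix,
    asymmetry,
    de_sets_by_organ,
    filter_de,
    make_de_calls,
    organ_overlap,
    weighted_fc_profile,
    DEFAULT_EPSILON,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the offending detail."""

    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage '{stage}': {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Reproducible run settings; defaults mirror the analysis conventions
    (PPDE threshold 0.95, 10 % similarity window, 20 retained hits)."""

    registry: tuple[DatabaseSpec, ...]
    window: WindowRule = field(default_factory=WindowRule)
    mode: str = "informed"
    ppde_threshold: float = 0.95
    epsilon: float = DEFAULT_EPSILON
    bin_width: float = 0.25
    taxa: TaxonMap | None = None
    out_dir: str | Path = "metannot_out"

    def to_jsonable(self) -> dict:
        return {
            "registry": [
                {
                    "name": db.name, "kind": db.kind,
                    "priority_rank": db.priority_rank,
                    "bound_species": db.bound_species,
                }
                for db in self.registry
            ],
            "window": {
                "bitscore_tolerance": self.window.bitscore_tolerance,
                "coverage_tolerance": self.window.coverage_tolerance,
            },
            "mode": self.mode,
            "ppde_threshold": self.ppde_threshold,
            "epsilon": self.epsilon,
            "bin_width": self.bin_width,
            "taxa": None if self.taxa is None else self.taxa.table,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class InputPaths:
    """File inputs of one run: per-database hit tables, the count matrix with
    metadata and lengths, and per-organ PPDE tables from the upstream DE
    model; ``universe`` optionally lists the full gene id universe so no-hit
    genes are retained as unknown."""

    hit_tables: Mapping[str, str | Path]
    counts: str | Path
    gene_lengths: str | Path
    samples: str | Path
    ppde: Mapping[str, str | Path]
    universe: str | Path | None = None

    def all_paths(self) -> dict[str, Path]:
        out = {f"hits_{k}": Path(v) for k, v in self.hit_tables.items()}
        out.update(counts=Path(self.counts), gene_lengths=Path(self.gene_lengths),
                   samples=Path(self.samples))
        out.update({f"ppde_{k}": Path(v) for k, v in self.ppde.items()})
        if self.universe is not None:
            out["universe"] = Path(self.universe)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(stage: str, path: Path, what: str) -> Path:
    if not path.exists():
        raise PipelineStageError(stage, f"missing {what}: {path}")
    return path


def load_expression_inputs(inputs: InputPaths) -> tuple[ExpressionMatrix, dict[str, pd.DataFrame]]:
    stage = "expression"
    counts = pd.read_csv(_require(stage, Path(inputs.counts), "count matrix"),
                         sep="\t", index_col=0)
    lengths = pd.read_csv(
        _require(stage, Path(inputs.gene_lengths), "gene-length table"),
        sep="\t", index_col=0,
    ).iloc[:, 0]
    samples = pd.read_csv(_require(stage, Path(inputs.samples), "sample metadata"),
                          sep="\t")
    ppde = {}
    for organ, p in inputs.ppde.items():
        ppde[organ] = pd.read_csv(
            _require(stage, Path(p), f"ppde table for organ '{organ}'"), sep="\t"
        )
    matrix = ExpressionMatrix(counts=counts, gene_lengths=lengths, samples=samples)
    return matrix, ppde


def run_all(config: RunConfig, inputs: InputPaths) -> dict:
    """Execute annotate -> express -> compose and write all output tables.

    Returns a dict of in-memory results plus the manifest. Any stage failure
    raises :class:`PipelineStageError` naming the stage and offending file.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db_by_name = {db.name: db for db in config.registry}

    # --- annotation stage -------------------------------------------------
    stage = "annotation"
    try:
        hit_tables = {}
        for name, path in inputs.hit_tables.items():
            if name not in db_by_name:
                raise PipelineStageError(stage, f"hit table for unregistered database '{name}'")
            hit_tables[name] = parse_hit_table(
                _require(stage, Path(path), f"hit table for '{name}'"), db_by_name[name]
            )
        universe = None
        if inputs.universe is not None:
            universe = _require(stage, Path(inputs.universe), "gene universe") \
                .read_text().split()
        records = annotate_all(
            hit_tables, config.registry, config.window, config.mode, universe
        )
        annotations = annotations_to_frame(records)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- expression stage -------------------------------------------------
    stage = "expression"
    try:
        matrix, ppde = load_expression_inputs(inputs)
        calls = make_de_calls(matrix, ppde, config.epsilon)
        de = filter_de(calls, config.ppde_threshold)
        organisms = dict(zip(annotations["query_id"], annotations["organism"]))
        asym = asymmetry(de, organisms)
        per_gene, bins, standouts = weighted_fc_profile(de, config.bin_width)
        sets = de_sets_by_organ(de)
        overlap = organ_overlap(sets) if len(sets) >= 2 else None
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- composition stage ------------------------------------------------
    stage = "composition"
    try:
        comp = compose(annotations, de, config.taxa)
        breakdown = source_database_breakdown(
            annotations, [db.name for db in config.registry]
        )
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    tables = {
        "annotations": annotations,
        "de_calls": de,
        "asymmetry": asym,
        "weighted_fc": per_gene,
        "weighted_fc_bins": bins,
        "weighted_fc_standouts": standouts,
        "composition": comp,
        "source_breakdown": breakdown,
    }
    if overlap is not None:
        tables["overlap"] = overlap
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                     float_format=FLOAT_FORMAT)

    manifest = {
        "tool": "metannot",
        "version": __version__,
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "inputs": {k: _sha256(p) for k, p in inputs.all_paths().items()},
        "wall_clock_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results = dict(tables)
    results["manifest"] = manifest
    return results
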