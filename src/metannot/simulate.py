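"""Ground-truth synthetic data with the statistical structure the pipeline assumes.

Emulates the shape of a dual host-pest meta-transcriptomic study: a catalogue
of assembled genes drawn from a host plant, an arthropod pest, minor
other-plant / bacterial / fungal fractions and a no-hit "unknown" remainder;
per-database protein-alignment hit tables in which the true source database
carries a controllable bitscore advantage over decoy hits; a 24-sample
(3 organs x 2 soil treatments x 4 replicates) negative-binomial count matrix
with planted differential expression whose direction is biased per group
(pest genes higher in non-contaminated trees with probability 0.99 by
default); and per-organ PPDE tables that place planted DE genes at
posterior >= 0.95. Every quantity is recorded in a truth table so recovery
can be scored exactly. Identical seed and config give byte-identical output.

The generator makes no attempt at sequence-level realism: no nucleotide or
protein sequences, no assembly artefacts, and alignment scores follow a
simple parametric model rather than alignment biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blast_io import AlignmentHit, DatabaseSpec, compute_coverage, write_hit_table
from .expression import ExpressionMatrix

#: Planted catalogue proportions (fraction of genes per taxon group);
#: host ~41 %, pest ~44 %, other plants ~8 %, trace bacteria and fungi,
#: remainder with no database hit at all.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "host_plant": 0.41,
    "metazoa": 0.44,
    "other_plant": 0.08,
    "bacteria": 0.003,
    "fungi": 0.001,
    "unknown": 0.066,
}

#: Organisms emitted per group (cycled deterministically within a group).
GROUP_ORGANISMS: dict[str, tuple[str, ...]] = {
    "host_plant": ("Salix purpurea",),
    "metazoa": ("Tetranychus urticae",),
    "other_plant": ("Populus trichocarpa", "Arabidopsis thaliana", "Vitis vinifera"),
    "bacteria": ("Propionibacterium acnes", "Bacillus stratosphericus",
                 "Klebsiella pneumoniae"),
    "fungi": ("Fusarium oxysporum", "Saccharomyces cerevisiae"),
}

#: Which database truly contains each group's proteins.
GROUP_TRUE_DB: dict[str, str] = {
    "host_plant": "host_genome",
    "metazoa": "pest_genome",
    "other_plant": "trembl",
    "bacteria": "nr",
    "fungi": "swissprot",
}

#: Databases whose titles carry NCBI-style trailing "[organism]" rather than
#: the UniProt "OS=" convention.
_NCBI_STYLE = {"nr"}


def default_registry(names: Sequence[str] | None = None) -> tuple[DatabaseSpec, ...]:
    """The five-database priority ladder the generator targets.

    Ranks: host genome (1), pest genome (2), then the general databases
    Swiss-Prot (3), TrEMBL (4) and nr (5). ``names`` selects a subset while
    keeping the relative ranks.
    """
    full = (
        DatabaseSpec("host_genome", "species_genome", 1, "Salix purpurea"),
        DatabaseSpec("pest_genome", "species_genome", 2, "Tetranychus urticae"),
        DatabaseSpec("swissprot", "general", 3),
        DatabaseSpec("trembl", "general", 4),
        DatabaseSpec("nr", "general", 5),
    )
    if names is None:
        return full
    chosen = [db for db in full if db.name in set(names)]
    if len(chosen) != len(set(names)):
        known = {db.name for db in full}
        raise ValueError(f"unknown database name(s): {sorted(set(names) - known)}")
    return tuple(chosen)


@dataclass(frozen=True)
class ScoreModel:
    """Alignment-score structure of the synthetic hit tables.

    The true source database's best hit scores ``base * (1 + advantage)``
    where ``base`` is the gene's baseline bitscore; every other database's
    best hit scores ``base * (1 + N(0, score_noise_sd))``. With the default
    advantage of 0.2 and zero noise the decoys sit 16.7 % below the winner,
    outside a 10 % similarity window, so arbitration is exactly recoverable;
    shrinking the advantage or raising the noise degrades it. Coverage is
    Beta-distributed; ``decoy_hits_per_db`` adds strictly weaker extra hits
    per database to exercise within-database best-hit selection.
    """

    base_bitscore_mean: float = 300.0
    base_bitscore_sd: float = 60.0
    true_db_advantage: float = 0.2
    score_noise_sd: float = 0.0
    coverage_alpha: float = 8.0
    coverage_beta: float = 2.0
    decoy_hits_per_db: int = 2


@dataclass(frozen=True)
class ExpressionModel:
    """Count-matrix structure: negative-binomial with planted DE effects.

    Baseline per-gene means are log-normal (median ``base_mean`` FPM-scale
    counts, natural-log sigma ``base_sigma``); counts are NB with fixed
    ``dispersion`` (variance m + dispersion * m^2). A ``de_fraction`` of each
    group's genes is planted DE in one home organ with a log10 effect size
    uniform on [effect_low, effect_high], split symmetrically between the two
    treatments. ``direction_prob`` gives, per group, the probability that a
    DE gene is higher in non-contaminated trees — 0.99 for the pest by
    default, 0.5 (no bias) elsewhere.
    """

    organs: tuple[str, ...] = ("bud", "leaf", "stem")
    replicates: int = 4
    base_mean: float = 50.0
    base_sigma: float = 0.8
    dispersion: float = 0.1
    de_fraction: float = 0.9
    effect_low: float = 0.8
    effect_high: float = 1.6
    direction_prob: Mapping[str, float] = field(
        default_factory=lambda: {"metazoa": 0.99}
    )
    default_direction_prob: float = 0.5

    def direction_prob_of(self, group: str) -> float:
        return self.direction_prob.get(group, self.default_direction_prob)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full study-shape configuration; see :class:`ScoreModel` and
    :class:`ExpressionModel` for the planted-parameter meanings."""

    n_genes: int = 8000
    proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    score: ScoreModel = field(default_factory=ScoreModel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    database_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"group proportions must sum to 1, got {total}")
        unknown_groups = set(self.proportions) - set(GROUP_ORGANISMS) - {"unknown"}
        if unknown_groups:
            raise ValueError(f"unrecognised group(s): {sorted(unknown_groups)}")
        for group, p in self.expression.direction_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"direction probability for {group!r} outside [0, 1]")
        if self.expression.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, in memory."""

    config: SyntheticConfig
    registry: tuple[DatabaseSpec, ...]
    hit_tables: dict[str, list[AlignmentHit]]
    matrix: ExpressionMatrix
    ppde_tables: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    universe: list[str]


def allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of ``n`` genes to groups."""
    items = sorted(proportions.items())
    base = {g: int(math.floor(p * n)) for g, p in items}
    short = n - sum(base.values())
    remainders = sorted(
        items, key=lambda kv: (-(kv[1] * n - math.floor(kv[1] * n)), kv[0])
    )
    for g, _ in remainders[:short]:
        base[g] += 1
    return base


def _subject_title(db: DatabaseSpec, organism: str) -> str:
    if db.kind == "species_genome":
        return ""
    if db.name in _NCBI_STYLE:
        return f"hypothetical protein [{organism}]"
    return f"Uncharacterized protein OS={organism} OX=1"


def _make_hit(
    rng: np.random.Generator,
    db: DatabaseSpec,
    gene_id: str,
    organism: str,
    bitscore: float,
    score: ScoreModel,
    tag: str,
) -> AlignmentHit:
    cov = float(np.clip(rng.beta(score.coverage_alpha, score.coverage_beta), 0.05, 1.0))
    slen = int(rng.integers(150, 800))
    align = max(1, round(cov * slen))
    bitscore = max(25.0, float(bitscore))
    return AlignmentHit(
        query_id=gene_id,
        subject_id=f"{db.name}|{gene_id}|{tag}",
        bitscore=round(bitscore, 1),
        evalue=10.0 ** (-min(bitscore / 4.0, 180.0)),
        align_length=align,
        subject_length=slen,
        database=db.name,
        coverage=compute_coverage(align, slen),
        percent_identity=float(np.round(rng.uniform(40.0, 100.0), 1)),
        subject_title=_subject_title(db, organism),
    )


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Draw one complete synthetic study from the configured model.

    Group sizes follow the configured proportions exactly (deterministic
    apportionment, not sampling); unknown-group genes receive no hits in any
    database but do receive counts and PPDE values, exercising the no-hit
    accounting path end to end.
    """
    rng = np.random.default_rng(config.seed)
    registry = default_registry(config.database_names)
    db_by_name = {db.name: db for db in registry}
    expr = config.expression
    score = config.score

    group_sizes = allocate_counts(config.n_genes, config.proportions)

    gene_rows: list[dict] = []
    i = 0
    for group in sorted(group_sizes):
        organisms = GROUP_ORGANISMS.get(group, ())
        for k in range(group_sizes[group]):
            organism = organisms[k % len(organisms)] if organisms else "unknown"
            gene_rows.append({
                "gene_id": f"GENE_{i:05d}",
                "group": group,
                "organism": organism,
            })
            i += 1
    truth = pd.DataFrame(gene_rows)
    n = len(truth)
    gene_ids = truth["gene_id"].to_numpy()

    lengths = np.clip(
        rng.lognormal(mean=math.log(1500.0), sigma=0.6, size=n), 300, 15000
    ).astype(int)
    truth["gene_length"] = lengths

    # --- plant DE effects -------------------------------------------------
    truth["de_organ"] = ""
    truth["direction"] = ""
    truth["effect_size"] = 0.0
    for group, sub in truth.groupby("group", sort=True):
        n_de = int(round(expr.de_fraction * len(sub)))
        de_idx = rng.choice(sub.index.to_numpy(), size=n_de, replace=False)
        de_idx = np.sort(de_idx)
        organs = rng.choice(expr.organs, size=n_de)
        toward_non = rng.random(n_de) < expr.direction_prob_of(group)
        effects = rng.uniform(expr.effect_low, expr.effect_high, size=n_de)
        truth.loc[de_idx, "de_organ"] = organs
        truth.loc[de_idx, "direction"] = np.where(
            toward_non, "non_contaminated", "contaminated"
        )
        truth.loc[de_idx, "effect_size"] = effects

    # --- counts -----------------------------------------------------------
    mu = rng.lognormal(mean=math.log(expr.base_mean), sigma=expr.base_sigma, size=n)
    r = 1.0 / expr.dispersion
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    de_organ = truth["de_organ"].to_numpy()
    direction = truth["direction"].to_numpy()
    effect = truth["effect_size"].to_numpy()
    for organ in expr.organs:
        in_organ = de_organ == organ
        shift = np.where(
            in_organ,
            np.where(direction == "contaminated", effect / 2.0, -effect / 2.0),
            0.0,
        )
        mean_by_treatment = {
            "contaminated": mu * 10.0 ** shift,
            "non_contaminated": mu * 10.0 ** -shift,
        }
        for treatment in ("contaminated", "non_contaminated"):
            m = mean_by_treatment[treatment]
            p = r / (r + m)
            for rep in range(1, expr.replicates + 1):
                sid = f"{organ}_{treatment[:3]}_{rep}"
                columns[sid] = rng.negative_binomial(r, p, size=n)
                meta_rows.append({
                    "sample_id": sid,
                    "organ": organ,
                    "treatment": treatment,
                    "replicate": rep,
                })
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta_rows)
    matrix = ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=counts.index, name="length"),
        samples=samples,
    )

    # --- PPDE tables ------------------------------------------------------
    ppde_tables: dict[str, pd.DataFrame] = {}
    for organ in expr.organs:
        is_de_here = de_organ == organ
        ppde = rng.uniform(0.0, 0.95, size=n)
        ppde = np.where(is_de_here, 0.95 + 0.05 * rng.random(n), ppde)
        ppde_tables[organ] = pd.DataFrame({"gene_id": gene_ids, "ppde": ppde})

    # --- hit tables -------------------------------------------------------
    hit_tables: dict[str, list[AlignmentHit]] = {db.name: [] for db in registry}
    group_arr = truth["group"].to_numpy()
    organism_arr = truth["organism"].to_numpy()
    decoy_pool = [o for orgs in GROUP_ORGANISMS.values() for o in orgs]
    for gi in range(n):
        group = group_arr[gi]
        if group == "unknown":
            continue
        gene_id = gene_ids[gi]
        true_db_name = GROUP_TRUE_DB[group]
        if true_db_name not in db_by_name:
            continue  # registry subset excludes this group's home database
        base = max(50.0, rng.normal(score.base_bitscore_mean, score.base_bitscore_sd))
        for db in registry:
            if db.name == true_db_name:
                top_score = base * (1.0 + score.true_db_advantage)
                organism = organism_arr[gi]
            else:
                noise = rng.normal(0.0, score.score_noise_sd) if score.score_noise_sd else 0.0
                top_score = base * (1.0 + noise)
                organism = decoy_pool[int(rng.integers(len(decoy_pool)))]
            hit_tables[db.name].append(
                _make_hit(rng, db, gene_id, organism, top_score, score, "t0")
            )
            for d in range(score.decoy_hits_per_db):
                weak = top_score * rng.uniform(0.5, 0.85)
                weak_org = decoy_pool[int(rng.integers(len(decoy_pool)))]
                hit_tables[db.name].append(
                    _make_hit(rng, db, gene_id, weak_org, weak, score, f"d{d}")
                )

    return SyntheticBundle(
        config=config,
        registry=registry,
        hit_tables=hit_tables,
        matrix=matrix,
        ppde_tables=ppde_tables,
        truth=truth,
        universe=list(gene_ids),
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path,
                 include_truth: bool = False) -> dict[str, Path]:
    """Write the bundle in the exact text formats the analysis stages consume.

    The truth table stays out of the pipeline's input directory unless
    explicitly requested.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, hits in bundle.hit_tables.items():
        p = out / f"hits_{name}.tsv"
        write_hit_table(hits, p)
        paths[f"hits_{name}"] = p
    p = out / "counts.tsv"
    bundle.matrix.counts.to_csv(p, sep="\t")
    paths["counts"] = p
    p = out / "gene_lengths.tsv"
    bundle.matrix.gene_lengths.rename("length").to_csv(p, sep="\t")
    paths["gene_lengths"] = p
    p = out / "samples.tsv"
    bundle.matrix.samples.to_csv(p, sep="\t", index=False)
    paths["samples"] = p
    for organ, table in bundle.ppde_tables.items():
        p = out / f"ppde_{organ}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[f"ppde_{organ}"] = p
    p = out / "universe.txt"
    p.write_text("\n".join(bundle.universe) + "\n")
    paths["universe"] = p
    if include_truth:
        p = out / "truth.tsv"
        bundle.truth.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths["truth"] = p
    return paths


#: Configuration of the miniature, hand-checkable documentation bundle:
#: 20 genes over two species-bound databases, two replicates per organ.
WORKED_EXAMPLE_CONFIG = SyntheticConfig(
    n_genes=20,
    proportions={"host_plant": 0.5, "metazoa": 0.4, "unknown": 0.1},
    database_names=("host_genome", "pest_genome"),
    expression=ExpressionModel(replicates=2, de_fraction=1.0),
    seed=20,
)


def make_worked_example() -> SyntheticBundle:
    """Regenerate the fixed 20-gene, 2-database documentation bundle."""
    return generate(WORKED_EXAMPLE_CONFIG)
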