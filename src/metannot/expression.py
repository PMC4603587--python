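"""Downstream expression statistics for the annotated meta-transcriptome.

Takes a gene x sample raw fragment-count matrix with sample metadata
(organ, treatment, replicate), per-gene transcript lengths and per-organ
posterior probabilities of differential expression (PPDE) from an upstream
empirical-Bayes DE model, and computes:

* FPKM (fragments per kilobase of transcript per million mapped fragments),
* per-treatment mean FPKM per organ,
* log10 fold change with a symmetric pseudo-count,
* the PPDE >= 0.95 DE filter,
* the abundance-weighted fold-change profile (each DE gene weighted by its
  higher treatment mean),
* per-organism treatment-asymmetry fractions, and
* organ-overlap counts of DE genes.

Sign convention: positive log10 fold change means higher abundance in
contaminated-soil trees; a negative sign therefore marks genes more abundant
in non-contaminated trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ORGANS = ("bud", "leaf", "stem")
TREATMENTS = ("contaminated", "non_contaminated")

#: Symmetric pseudo-count (FPKM units) added to both treatment means before
#: the log ratio; keeps zero-mean genes finite and the ratio antisymmetric.
DEFAULT_EPSILON = 0.01

DE_CALL_COLUMNS = [
    "gene_id", "organ", "ppde",
    "mean_fpkm_contaminated", "mean_fpkm_non_contaminated",
    "log10_fc", "weight",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with lengths and complete sample metadata.

    ``counts``: non-negative integer DataFrame, genes as index, sample ids as
    columns. ``gene_lengths``: bp per gene (positive), indexed like counts.
    ``samples``: one row per sample with columns sample_id, organ, treatment,
    replicate.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.set_index("sample_id", drop=False) \
            if "sample_id" in self.samples.columns else self.samples
        missing_meta = set(self.counts.columns) - set(self.samples.index)
        if missing_meta:
            raise ValueError(f"samples without metadata: {sorted(missing_meta)[:5]}")
        for col in ("organ", "treatment", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad_treat = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise ValueError(f"unrecognised treatment labels: {sorted(bad_treat)}")
        missing_len = self.counts.index.difference(self.gene_lengths.index)
        if len(missing_len):
            raise ValueError(f"genes without a length: {list(missing_len[:5])}")
        if (self.gene_lengths.loc[self.counts.index] < 1).any():
            raise ValueError("gene lengths must be positive integers (bp)")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        lib = self.counts.sum(axis=0)
        empty = lib[lib <= 0]
        if len(empty):
            raise ValueError(f"library size must be > 0 for every sample: {list(empty.index)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def organ_samples(self, organ: str) -> pd.DataFrame:
        sel = self.samples[self.samples["organ"] == organ]
        if sel.empty:
            raise ValueError(f"organ {organ!r} absent from sample metadata")
        return sel


def fpkm(count: float, gene_length: int, library_size: float) -> float:
    """FPKM = count * 1e9 / (gene length in bp * mapped-fragment library size)."""
    if gene_length < 1:
        raise ValueError(f"gene_length must be >= 1, got {gene_length}")
    if library_size < 1:
        raise ValueError(f"library_size must be >= 1, got {library_size}")
    return count * 1.0e9 / (gene_length * library_size)


def fpkm_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample FPKM for every gene (library size = column sum of counts)."""
    lib = matrix.library_sizes.to_numpy(dtype=float)
    lengths = matrix.gene_lengths.loc[matrix.counts.index].to_numpy(dtype=float)
    values = matrix.counts.to_numpy(dtype=float) * 1.0e9 / np.outer(lengths, lib)
    return pd.DataFrame(values, index=matrix.counts.index, columns=matrix.counts.columns)


def treatment_means(matrix: ExpressionMatrix, organ: str) -> pd.DataFrame:
    """Arithmetic mean FPKM over replicates, per treatment, within one organ.

    Returns a DataFrame indexed by gene with columns
    ``mean_fpkm_contaminated`` and ``mean_fpkm_non_contaminated``.
    """
    meta = matrix.organ_samples(organ)
    fk = fpkm_matrix(matrix)
    out = {}
    for treatment in TREATMENTS:
        cols = meta.index[meta["treatment"] == treatment]
        if len(cols) == 0:
            raise ValueError(f"organ {organ!r} has no {treatment!r} replicates")
        out[f"mean_fpkm_{treatment}"] = fk[cols].mean(axis=1)
    return pd.DataFrame(out)


def log10_fold_change(
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> float | np.ndarray:
    """log10((a + eps) / (b + eps)); antisymmetric under swapping a and b."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("treatment means must be non-negative")
    result = np.log10((a + epsilon) / (b + epsilon))
    return float(result) if result.ndim == 0 else result


def make_de_calls(
    matrix: ExpressionMatrix,
    ppde_tables: Mapping[str, pd.DataFrame],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Join per-organ PPDE tables with treatment means, fold change and weight.

    ``ppde_tables`` maps organ -> DataFrame with columns gene_id, ppde (the
    upstream DE model's posterior for that organ). One output row per
    (gene, organ) pair present in the PPDE tables; weight is the higher of
    the two treatment means; positive log10_fc = higher in contaminated.
    The result is unfiltered — apply :func:`filter_de` for the DE subset.
    """
    frames = []
    for organ, table in ppde_tables.items():
        if not {"gene_id", "ppde"} <= set(table.columns):
            raise ValueError(f"PPDE table for organ {organ!r} needs gene_id and ppde columns")
        bad = table[(table["ppde"] < 0) | (table["ppde"] > 1)]
        if len(bad):
            raise ValueError(f"PPDE outside [0, 1] for organ {organ!r}")
        means = treatment_means(matrix, organ)
        sub = table[["gene_id", "ppde"]].copy()
        sub = sub[sub["gene_id"].isin(means.index)]
        mc = means.loc[sub["gene_id"], "mean_fpkm_contaminated"].to_numpy()
        mn = means.loc[sub["gene_id"], "mean_fpkm_non_contaminated"].to_numpy()
        sub["organ"] = organ
        sub["mean_fpkm_contaminated"] = mc
        sub["mean_fpkm_non_contaminated"] = mn
        sub["log10_fc"] = log10_fold_change(mc, mn, epsilon)
        sub["weight"] = np.maximum(mc, mn)
        frames.append(sub)
    if not frames:
        raise ValueError("no PPDE tables supplied")
    calls = pd.concat(frames, ignore_index=True)[DE_CALL_COLUMNS]
    return calls.sort_values(["organ", "gene_id"], ignore_index=True)


def filter_de(calls: pd.DataFrame, threshold: float = 0.95) -> pd.DataFrame:
    """Retain calls with PPDE >= threshold (inclusive boundary)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return calls[calls["ppde"] >= threshold].reset_index(drop=True)


def de_sets_by_organ(de: pd.DataFrame) -> dict[str, set[str]]:
    """Per-organ sets of DE gene ids."""
    return {organ: set(sub["gene_id"]) for organ, sub in de.groupby("organ")}


def weighted_fc_profile(
    de: pd.DataFrame,
    bin_width: float = 0.25,
    standout_fc: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Abundance-weighted fold-change profile of the DE set.

    Returns ``(per_gene, bins, standouts)``: the per-call (fc, weight) table;
    half-open bins [k*w, (k+1)*w) with summed weights (every call lands in
    exactly one bin, so bin sums total the weight sum); and the standout list
    — calls with \\|fc\\| >= ``standout_fc`` ranked by weight descending, the
    high-abundance genes that dominate the weighted view.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if de.empty:
        raise ValueError("weighted_fc_profile requires a non-empty DE set")
    per_gene = de[["gene_id", "organ", "log10_fc", "weight"]].copy()
    idx = np.floor(per_gene["log10_fc"].to_numpy() / bin_width).astype(int)
    per_gene["bin_index"] = idx
    bins = (
        per_gene.groupby("bin_index")
        .agg(weight_sum=("weight", "sum"), n_genes=("gene_id", "count"))
        .reset_index()
        .sort_values("bin_index", ignore_index=True)
    )
    bins["bin_left"] = bins["bin_index"] * bin_width
    bins["bin_right"] = (bins["bin_index"] + 1) * bin_width
    standouts = (
        per_gene[per_gene["log10_fc"].abs() >= standout_fc]
        .sort_values(["weight", "gene_id"], ascending=[False, True], ignore_index=True)
    )
    return per_gene, bins, standouts


def asymmetry(de: pd.DataFrame, organisms: Mapping[str, str]) -> pd.DataFrame:
    """Treatment-direction balance of DE calls, per organism and overall.

    For each organism group (and an ``overall`` row): how many DE calls are
    higher in contaminated trees (fc > 0), higher in non-contaminated trees
    (fc < 0), or tied (fc = 0, excluded from the denominator), and the
    fraction higher in non-contaminated = n(fc<0) / n(fc!=0) — the quantity
    whose extreme value for the pest marks the study's expression asymmetry.
    Ties leave the fraction NaN when no call has a direction.
    """
    if de.empty:
        raise ValueError("asymmetry requires a non-empty DE set")
    work = de[["gene_id", "log10_fc"]].copy()
    work["group"] = [organisms.get(g, "unknown") for g in work["gene_id"]]

    def summarise(sub: pd.DataFrame, label: str) -> dict:
        fc = sub["log10_fc"].to_numpy()
        n_up = int((fc > 0).sum())
        n_down = int((fc < 0).sum())
        n_tied = int((fc == 0).sum())
        directed = n_up + n_down
        return {
            "group": label,
            "n_higher_contaminated": n_up,
            "n_higher_non_contaminated": n_down,
            "n_tied": n_tied,
            "fraction_higher_non_contaminated":
                n_down / directed if directed else float("nan"),
        }

    rows = [summarise(sub, group) for group, sub in work.groupby("group")]
    rows.append(summarise(work, "overall"))
    return pd.DataFrame(rows)


def organ_overlap(de_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Partition the union of DE genes by how many organ sets contain each.

    Returns one row per membership cardinality (1 = unique to one organ,
    2 = shared between two organs, ...); the counts sum to the union size.
    """
    sets = {organ: set(genes) for organ, genes in de_sets.items()}
    if len(sets) < 2:
        raise ValueError("organ_overlap requires at least two organ sets")
    union: set[str] = set().union(*sets.values())
    card = pd.Series(
        [sum(g in s for s in sets.values()) for g in union], dtype=int
    )
    counts = card.value_counts().sort_index()
    return pd.DataFrame({
        "n_organs": counts.index.to_numpy(),
        "n_genes": counts.to_numpy(),
    })
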