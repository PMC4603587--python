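# Methods

This note documents the models and procedures `metannot` implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions. It is the package's own account
of its science; every number quoted here is computed by the test suite or
by `scripts/acceptance.py`.

## 1. Hit tables and protein coverage

Input hit tables are BLAST-style tab-separated files, one per reference
database, in the common 12-column tabular layout extended with subject
length (`slen`) and subject title (`stitle`); a dialect specification can
remap column order. The external search settings (e-value cutoff 1e-4, up
to 20 retained hits per query, gap open 11, gap extend 1, word size 3,
BLOSUM62) are stored verbatim on each database specification as provenance
only — the search itself is external, and none of these values enter any
computation except the 20-hit retention cap.

**Protein coverage** is defined subject-side:

    coverage = min(aligned residues / subject protein length, 1.0)

Coverage measures how much of the database protein the alignment spans;
the clamp handles gapped alignments that exceed the subject length. The
query-side alternative (aligned fraction of the translated query) was
considered and rejected: assembled transcripts have untranslated regions
and variable completeness, so subject-side coverage is the more stable
selection quantity. Multiple HSPs of the same query–subject pair are not
merged; each row stands alone.

**Per-query truncation** to the 20-hit cap is applied at parse time using
the same total order as best-hit selection (below), so results never depend
on which 20 rows the upstream search tool happened to emit first. Parsing
then re-serialising a table is lossless for the dialect's columns.

## 2. Best-hit ranking

Hits are totally ordered by

1. bitscore, descending — database-size independent, hence comparable
   across databases of very different sizes, which the e-value is not;
2. protein coverage, descending;
3. e-value, ascending;
4. subject id, ascending (pure determinism tie-break).

The first two keys are the scientific selection parameters; the last two
only guarantee that arbitration is a deterministic function of its inputs.

## 3. Two-pass arbitration

Let `per_db_best` be the within-database winners for one gene.

**Unconstrained pass** — the best of `per_db_best` under the ranking above
wins; no organism prior. A gene with no hits in any database is emitted as
`unknown` (not dropped) whenever a gene universe is supplied, so no-hit
genes remain part of all downstream accounting.

**Informed pass** — given database priority ranks (1 = highest; in the
motivating design: host genome, pest genome, Swiss-Prot, TrEMBL, nr), the
unconstrained winner T anchors a similarity window. A per-database best hit
h competes iff

    (T.bitscore − h.bitscore) / T.bitscore < 0.10   AND
    (T.coverage − h.coverage) / T.coverage < 0.10

with strict `<` on both axes; T itself is always a competitor, so the rule
degenerates exactly to the unconstrained pass at zero tolerance. The
competitor whose database has the smallest priority rank is chosen.

Design choices made where the convention was genuinely open:

* *Relative vs absolute window.* The 10 % window is interpreted as relative
  deficit from the top hit's own bitscore and coverage. Relative difference
  is scale-free (a 10-bit gap means something different at bitscore 60 than
  at 600); the tolerances are exposed as configuration for anyone wanting
  absolute-percentage-point semantics on coverage.
* *Strict boundary.* A hit exactly 10 % below the top is excluded.
* *Both axes required.* The window requires bitscore AND coverage within
  tolerance; a high-scoring but short alignment cannot displace a
  full-length one.

**Organism of origin** is the bound species for species-bound databases.
For general databases it is parsed from the subject title: the UniProt
`OS=...` convention first, then a trailing NCBI-style `[organism]` bracket,
else `unparsed`. `unparsed` genes are annotated (they have a protein
identity) but fall into the `other` taxon class.

The informed rule is verified against an independent brute-force reference
(explicit enumeration of admitted hits) on 10,000 randomized instances with
tie- and boundary-rich score grids; agreement is 100 %.

## 4. Expression statistics

* **FPKM** = count × 10⁹ / (gene length in bp × library size), with library
  size the column sum of the supplied count matrix. Recomputing FPKM from
  raw counts keeps the package self-contained; an effective-length column
  can be supplied as the gene-length table to emulate estimators that use
  effective lengths. FPKM is invariant to uniform count rescaling.
* **Treatment means** are arithmetic means of replicate FPKM values within
  an organ, per treatment.
* **Fold change** is log₁₀((mean_c + ε)/(mean_n + ε)) with a symmetric
  pseudo-count ε = 0.01 FPKM added to both means (configurable, reported in
  output headers). Positive sign = higher in contaminated-soil trees. The
  symmetric ε keeps the quantity finite at zero means and exactly
  antisymmetric under treatment swap. ε = 0.01 sits two orders of magnitude
  below typical expressed-gene FPKM, so it perturbs no direction call while
  bounding the magnitude for on/off genes at |log₁₀ fc| ≈ 4–5.
* **DE filter**: PPDE ≥ 0.95, inclusive. PPDE values are consumed from
  upstream per-organ posterior tables; the empirical-Bayes model that
  produces them is out of scope.
* **Abundance-weighted fold change**: each DE call contributes its weight —
  the larger of its two treatment means — at its fold change. Bins are
  half-open [k·w, (k+1)·w) with default width 0.25 log₁₀ units (the display
  resolution is a free choice; 0.25 gives 8 bins per decade). Because the
  bins partition the line, bin sums conserve total weight exactly. The
  standout list ranks calls with |fc| ≥ 1 by weight, surfacing the
  high-abundance genes that dominate the weighted view.
* **Asymmetry**: per organism group and overall, the counts of DE calls
  with fc > 0, fc < 0, fc = 0 and the fraction higher in non-contaminated
  trees, n(fc<0)/n(fc≠0). Zero-fold-change calls have no direction and are
  excluded from the denominator (counted separately); an all-tied group
  reports its counts with an undefined fraction. Counting is per
  (gene, organ) DE call; a gene DE in two organs contributes twice, each
  time with that organ's own direction.
* **Organ overlap** partitions the union of per-organ DE sets by membership
  cardinality (unique to one organ / shared by exactly two / shared by
  all); the partition sizes sum to the union size.

## 5. Composition

DE genes are mapped organism → taxon class through a flat, user-extensible
table (host plant, other plants, metazoa, bacteria, fungi, other, unknown;
fallback `other`). Counts are unique gene ids per class: once in the
`overall` stratum, and once per organ stratum where a gene is assigned to
the treatment panel in which its mean FPKM is higher (fc sign); fc = 0
genes join neither panel. Percentages are computed from exact counts and
displayed at one decimal with half-up rounding; counts are always emitted
alongside, so rounding loses nothing.

One display caveat worth recording: for a published accounting with
per-database unique-gene counts (3193, 2960, 33, 324, 26, 739; total 7275),
half-up rounding of the exact ratios gives 43.9 % and 40.7 % for the two
genome databases where the original report prints 43.8 % and 40.6 % (the
other four percentages agree). The discrepancy is one display tenth of a
point with no effect on counts; this package reports the half-up values and
documents the difference rather than reproducing an unknown rounding
convention.

The foreign fraction is 100 × (1 − host count / total), computed from
unrounded counts of the `overall` stratum with a configurable host group
set (typically host plant + other plants).

## 6. Synthetic studies

The generator emulates the *statistical shape* of a dual host–pest
meta-transcriptomic experiment so that every stage is testable against a
planted truth. Defaults:

* **Catalogue**: 8,000 genes apportioned deterministically (largest
  remainder, not sampling) to host plant 0.41, pest (metazoa) 0.44, other
  plants 0.08, bacteria 0.003, fungi 0.001, unknown 0.066. The unknown
  fraction receives counts and PPDE values but no hits in any database,
  exercising the no-hit path. Gene lengths are log-normal, 300–15,000 bp.
* **Hit tables**: each annotated gene gets a baseline bitscore
  B ~ N(300, 60²); its true source database's best hit scores
  B × (1 + advantage) with advantage 0.2, every other database's best hit
  scores B × (1 + N(0, noise)) with noise 0 by default, and each database
  additionally carries two strictly weaker decoy hits. Coverage is
  Beta(8, 2) (mean 0.8). With the default advantage and zero noise, decoys
  sit 16.7 % below the winner — outside the 10 % window — so organism
  recovery is exact; shrinking the advantage below the window width or
  adding noise degrades it, which the tests use to confirm the expected
  monotone degradation.
* **Counts**: 3 organs × 2 treatments × 4 replicates = 24 samples.
  Negative-binomial counts (dispersion 0.1, the standard bulk RNA-seq
  assumption) around log-normal baseline means (median 50, σ = 0.8). 90 %
  of each group's genes are planted DE in one home organ with a log₁₀
  effect size uniform on [0.8, 1.6] split symmetrically between treatments;
  the direction is toward non-contaminated with probability 0.99 for pest
  genes and 0.5 elsewhere. At four replicates these effect sizes make
  direction recovery essentially error-free, so the measured pest
  asymmetry is a clean estimate of the planted 0.99 (the acceptance script
  reports ≈ 99.1 % at 3,168 pest DE calls, inside the exact binomial 95 %
  interval).
* **PPDE**: planted DE genes draw posteriors uniformly in [0.95, 1], all
  others in [0, 0.95). Mapping flags to bands keeps the 0.95 filter
  exercised without re-deriving an empirical-Bayes posterior, which is
  upstream of this package.

What the generator does **not** emulate: nucleotide or protein sequences,
alignment biology (scores are parametric, not alignment-derived), assembly
artefacts such as chimeras or fragmentation, isoform structure, organ- or
gene-length-dependent expression, and correlated replicates. Passing
recovery tests therefore demonstrates the correctness of the arbitration
and accounting logic under the stated statistical assumptions — not
robustness to real alignment noise or assembly error.

Problem sizes used by the tests and the acceptance script (8,000-gene
default study for asymmetry; 2,000-gene noiseless study for exact
composition recovery; 10,000 arbitration instances) were chosen as the
smallest sizes at which the planted-parameter checks are statistically
meaningful.

The exact-composition check runs the noiseless study with every gene
planted DE (de_fraction 1.0): with a fractional DE rate, per-group
rounding of DE counts makes exact percentage equality unattainable by
arithmetic, so the full-catalogue DE set is the natural noiseless regime
for that invariant.

## 7. Pipeline and provenance

`run_all` executes annotate → express → compose; any failure aborts with
the stage name and offending file. All randomness lives in the generator —
the analysis stages are seed-free — so identical inputs and configuration
give identical output tables (verified byte-for-byte in the tests). A JSON
manifest records the configuration hash, SHA-256 of every input, package
version and wall-clock time; configuration hash plus input hashes suffice
to recognise a re-run. Output tables are TSV with floats at six significant
digits for reproducible diffs.

## 8. Known limitations

* Taxonomic assignment is best-hit based; no lowest-common-ancestor
  reconciliation across near-tied hits from related organisms.
* The organism title parser covers the UniProt `OS=` and NCBI bracket
  conventions only; other title styles fall back to `unparsed`/`other`.
* Annotation operates at the assembled-gene level; isoform-level analysis
  is out of scope.
* The window semantics (relative, strict, both axes) are one defensible
  reading of a "<10 % difference" rule; the tolerances are configurable for
  sensitivity analysis, and coverage-absolute semantics are not currently
  implemented.
* Counts-to-FPKM uses annotated lengths unless an effective-length table is
  supplied; quantifier-specific effective-length corrections are not
  reproduced.
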