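import random

import numpy as np
import pytest

from metannot.arbiter import (
    WindowRule,
    annotate_all,
    annotations_to_frame,
    best_hit_per_database,
    informed_select,
    parse_organism,
    rank_hits,
    unconstrained_select,
)
from oracle_utils import (
    brute_force_best_per_db,
    brute_force_informed,
    random_instance,
)


@pytest.mark.parametrize("title,expected", [
    ("Uncharacterized protein OS=Populus trichocarpa OX=3694 GN=X PE=4 SV=1",
     "Populus trichocarpa"),
    ("Protein kinase OS=Arabidopsis thaliana", "Arabidopsis thaliana"),
    ("hypothetical protein [Bacillus stratosphericus]", "Bacillus stratosphericus"),
    ("glycosyl hydrolase family 65 [Propionibacterium acnes] ", "Propionibacterium acnes"),
    ("some protein with no organism markup", "unparsed"),
    ("", "unparsed"),
])
def test_parse_organism_conventions(title, expected):
    assert parse_organism(title) == expected


class TestRankHits:
    def test_bitscore_dominates_coverage(self, hit_factory):
        hits = [hit_factory(bitscore=100, coverage=0.5),
                hit_factory(bitscore=90, coverage=0.9, subject="s2")]
        assert rank_hits(hits)[0].bitscore == 100

    def test_coverage_breaks_bitscore_tie(self, hit_factory):
        a = hit_factory(bitscore=100, coverage=0.5, subject="X")
        b = hit_factory(bitscore=100, coverage=0.9, subject="Y")
        assert rank_hits([a, b])[0] is b

    def test_evalue_then_subject_id_break_remaining_ties(self, hit_factory):
        a = hit_factory(bitscore=100, coverage=0.8, evalue=1e-40, subject="B")
        b = hit_factory(bitscore=100, coverage=0.8, evalue=1e-30, subject="A")
        c = hit_factory(bitscore=100, coverage=0.8, evalue=1e-40, subject="A")
        assert rank_hits([a, b, c]) == [c, a, b]

    def test_total_order_is_permutation_invariant(self, hit_factory, rng):
        hits = [hit_factory(subject=f"s{i}", bitscore=float(rng.choice([90, 100])),
                            coverage=float(rng.choice([0.5, 0.8])))
                for i in range(12)]
        expected = rank_hits(hits)
        for seed in range(5):
            shuffled = hits[:]
            random.Random(seed).shuffle(shuffled)
            assert rank_hits(shuffled) == expected

    def test_empty_input_is_a_domain_error(self):
        with pytest.raises(ValueError):
            rank_hits([])


class TestBestHitPerDatabase:
    def test_single_database(self, hit_factory, registry5):
        hits = [hit_factory(database="trembl", bitscore=b) for b in (50, 80)]
        best = best_hit_per_database(hits, registry5)
        assert set(best) == {"trembl"} and best["trembl"].bitscore == 80

    def test_matches_brute_force_per_database(self, registry5, rng):
        for _ in range(50):
            hits = random_instance(rng, registry5)
            assert best_hit_per_database(hits, registry5) == brute_force_best_per_db(hits)

    def test_no_hits_gives_empty_map(self, registry5):
        assert best_hit_per_database([], registry5) == {}

    def test_unregistered_database_is_a_configuration_error(self, hit_factory, registry5):
        with pytest.raises(ValueError, match="unregistered"):
            best_hit_per_database([hit_factory(database="mystery")], registry5)


class TestUnconstrainedSelect:
    def test_empty_map_gives_unknown(self, registry5):
        rec = unconstrained_select("g1", {}, registry5)
        assert rec.chosen_hit is None
        assert rec.source_database == "unknown" and rec.organism == "unknown"

    def test_score_only_no_priority(self, hit_factory, registry5):
        general = hit_factory(database="trembl", bitscore=120,
                              title="P OS=Vitis vinifera")
        species = hit_factory(database="host_genome", bitscore=100, subject="s2")
        rec = unconstrained_select(
            "g1", {"trembl": general, "host_genome": species}, registry5)
        assert rec.source_database == "trembl"
        assert rec.organism == "Vitis vinifera"

    def test_species_db_organism_is_bound_species(self, hit_factory, registry5):
        rec = unconstrained_select(
            "g1", {"host_genome": hit_factory(database="host_genome")}, registry5)
        assert rec.organism == "Salix purpurea"

    def test_exact_tie_resolved_by_subject_id(self, hit_factory, registry5):
        a = hit_factory(database="trembl", bitscore=100, coverage=0.8, subject="A")
        b = hit_factory(database="nr", bitscore=100, coverage=0.8, subject="B")
        rec = unconstrained_select("g1", {"trembl": a, "nr": b}, registry5)
        assert rec.chosen_hit is a


class TestInformedSelect:
    def test_window_plus_priority_prefers_host_genome(self, hit_factory, registry5):
        top = hit_factory(database="trembl", bitscore=100, coverage=0.80)
        host = hit_factory(database="host_genome", bitscore=95, coverage=0.78,
                           subject="s2")
        rec = informed_select("g1", {"trembl": top, "host_genome": host}, registry5)
        assert rec.source_database == "host_genome"
        assert rec.organism == "Salix purpurea"
        assert host in rec.competing_set and top in rec.competing_set

    def test_window_excludes_fifteen_percent_deficit(self, hit_factory, registry5):
        top = hit_factory(database="trembl", bitscore=100, coverage=0.8)
        host = hit_factory(database="host_genome", bitscore=85, coverage=0.8,
                           subject="s2")
        rec = informed_select("g1", {"trembl": top, "host_genome": host}, registry5)
        assert rec.source_database == "trembl"

    def test_exact_ten_percent_boundary_is_excluded(self, hit_factory, registry5):
        top = hit_factory(database="trembl", bitscore=100, coverage=0.8)
        host = hit_factory(database="host_genome", bitscore=90, coverage=0.8,
                           subject="s2")
        rec = informed_select("g1", {"trembl": top, "host_genome": host}, registry5)
        assert rec.source_database == "trembl"
        assert host not in rec.competing_set

    def test_both_axes_must_be_within_window(self, hit_factory, registry5):
        top = hit_factory(database="trembl", bitscore=100, coverage=1.0)
        host = hit_factory(database="host_genome", bitscore=99, coverage=0.5,
                           subject="s2")
        rec = informed_select("g1", {"trembl": top, "host_genome": host}, registry5)
        assert rec.source_database == "trembl"

    def test_zero_tolerance_degenerates_to_unconstrained(self, registry5, rng):
        zero = WindowRule(0.0, 0.0)
        for _ in range(300):
            hits = random_instance(rng, registry5)
            per_db = best_hit_per_database(hits, registry5)
            inf = informed_select("q", per_db, registry5, zero)
            unc = unconstrained_select("q", per_db, registry5)
            assert inf.chosen_hit == unc.chosen_hit

    def test_agrees_with_brute_force_oracle(self, registry5, rng):
        window = WindowRule()
        for _ in range(1000):
            hits = random_instance(rng, registry5)
            per_db = best_hit_per_database(hits, registry5)
            expected = brute_force_informed(per_db, registry5, 0.10, 0.10)
            got = informed_select("q", per_db, registry5, window)
            assert got.chosen_hit == expected

    def test_window_monotonicity_competing_set_never_shrinks(self, registry5, rng):
        for _ in range(200):
            hits = random_instance(rng, registry5)
            per_db = best_hit_per_database(hits, registry5)
            narrow = informed_select("q", per_db, registry5, WindowRule(0.05, 0.05))
            wide = informed_select("q", per_db, registry5, WindowRule(0.20, 0.20))
            assert set(narrow.competing_set) <= set(wide.competing_set)

    def test_priority_monotonicity(self, registry5, rng):
        """Promoting a database to rank 1 never loses it any gene."""
        from metannot.blast_io import DatabaseSpec

        promoted = tuple(
            DatabaseSpec(db.name, db.kind, {1: 4, 4: 1}.get(db.priority_rank,
                                                            db.priority_rank),
                         db.bound_species)
            for db in registry5
        )  # trembl moves from rank 4 to rank 1; host_genome takes rank 4
        base_wins = promoted_wins = 0
        for _ in range(300):
            hits = random_instance(rng, registry5)
            per_db = best_hit_per_database(hits, registry5)
            if informed_select("q", per_db, registry5).source_database == "trembl":
                base_wins += 1
            if informed_select("q", per_db, promoted).source_database == "trembl":
                promoted_wins += 1
        assert promoted_wins >= base_wins


class TestAnnotateAll:
    def test_universe_genes_without_hits_are_unknown(self, hit_factory, registry5):
        tables = {"trembl": [hit_factory(query="g1", database="trembl")],
                  "nr": [hit_factory(query="g2", database="nr")]}
        records = annotate_all(tables, registry5, universe=["g1", "g2", "g3"])
        by_id = {r.query_id: r for r in records}
        assert len(records) == 3
        assert by_id["g3"].organism == "unknown"
        assert by_id["g1"].chosen_hit is not None

    def test_duplicate_rows_are_deduplicated_with_warning(self, hit_factory,
                                                          registry5, caplog):
        h = hit_factory(query="g1", database="trembl")
        with caplog.at_level("WARNING"):
            records = annotate_all({"trembl": [h, h]}, registry5)
        assert len(records) == 1
        assert "dedup" in caplog.text

    def test_deterministic_and_row_order_invariant(self, registry5, rng):
        import dataclasses

        hits = []
        for q in ("g1", "g2", "g3"):
            for h in random_instance(rng, registry5):
                hits.append(dataclasses.replace(h, query_id=q))
        by_db = {}
        for h in hits:
            by_db.setdefault(h.database, []).append(h)
        frame1 = annotations_to_frame(annotate_all(by_db, registry5))
        shuffled = {db: random.Random(5).sample(v, len(v)) for db, v in by_db.items()}
        frame2 = annotations_to_frame(annotate_all(shuffled, registry5))
        assert frame1.equals(frame2)

    def test_mode_unconstrained_ignores_priority(self, hit_factory, registry5):
        tables = {
            "trembl": [hit_factory(query="g1", database="trembl", bitscore=100,
                                   title="P OS=Vitis vinifera")],
            "host_genome": [hit_factory(query="g1", database="host_genome",
                                        bitscore=95, subject="s2")],
        }
        unc = annotate_all(tables, registry5, mode="unconstrained")[0]
        inf = annotate_all(tables, registry5, mode="informed")[0]
        assert unc.source_database == "trembl"
        assert inf.source_database == "host_genome"
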