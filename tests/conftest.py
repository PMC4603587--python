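import numpy as np
import pytest

from metannot.blast_io import AlignmentHit, DatabaseSpec
from metannot.simulate import SyntheticConfig, generate


def make_hit(
    query="g1",
    subject="s1",
    bitscore=100.0,
    coverage=0.8,
    evalue=1e-30,
    database="dbA",
    subject_length=1000,
    title="",
):
    """Build a valid AlignmentHit with a given coverage (align length derived)."""
    align = max(1, round(coverage * subject_length))
    return AlignmentHit(
        query_id=query,
        subject_id=subject,
        bitscore=bitscore,
        evalue=evalue,
        align_length=align,
        subject_length=subject_length,
        database=database,
        coverage=min(align / subject_length, 1.0),
        subject_title=title,
    )


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture
def registry5():
    """Five-database ladder: two species-bound, three general."""
    return (
        DatabaseSpec("host_genome", "species_genome", 1, "Salix purpurea"),
        DatabaseSpec("pest_genome", "species_genome", 2, "Tetranychus urticae"),
        DatabaseSpec("swissprot", "general", 3),
        DatabaseSpec("trembl", "general", 4),
        DatabaseSpec("nr", "general", 5),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One modest noiseless synthetic study reused across read-only tests."""
    return generate(SyntheticConfig(n_genes=1000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
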