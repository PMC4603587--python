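"""Independent brute-force arbitration reference used to cross-check the
package's informed/unconstrained selection on randomized instances.

Deliberately written as explicit pairwise loops over all hits, sharing no
code with metannot.arbiter beyond the data types.
"""

import numpy as np

from conftest import make_hit


def _strictly_better(a, b):
    """Pairwise score comparison: bitscore, coverage, e-value, subject id."""
    if a.bitscore != b.bitscore:
        return a.bitscore > b.bitscore
    if a.coverage != b.coverage:
        return a.coverage > b.coverage
    if a.evalue != b.evalue:
        return a.evalue < b.evalue
    return a.subject_id < b.subject_id


def brute_force_top(hits):
    top = hits[0]
    for h in hits[1:]:
        if _strictly_better(h, top):
            top = h
    return top


def brute_force_best_per_db(hits):
    out = {}
    for h in hits:
        if h.database not in out or _strictly_better(h, out[h.database]):
            out[h.database] = h
    return out


def brute_force_informed(per_db_best, registry, bitscore_tol, coverage_tol):
    """Enumerate every hit, test the window predicate directly, take the one
    with the smallest priority rank among admitted hits."""
    hits = list(per_db_best.values())
    if not hits:
        return None
    top = brute_force_top(hits)
    rank = {db.name: db.priority_rank for db in registry}
    chosen = None
    for h in hits:
        b_ok = (top.bitscore - h.bitscore) / top.bitscore < bitscore_tol
        c_ok = True
        if top.coverage > 0:
            c_ok = (top.coverage - h.coverage) / top.coverage < coverage_tol
        if h is top or (b_ok and c_ok):
            if chosen is None or rank[h.database] < rank[chosen.database]:
                chosen = h
    return chosen


# score grids mixing continuous draws with discrete values that force exact
# ties and exact 10 % window boundaries
_BITSCORES = np.array([50.0, 90.0, 95.0, 99.0, 100.0, 108.0, 110.0, 200.0])
_COVERAGES = np.array([0.45, 0.5, 0.72, 0.8, 0.88, 0.9, 1.0])


def random_instance(rng, registry, max_hits_per_db=4):
    """Random per-database hit lists over a random subset of <=5 databases."""
    dbs = [db for db in registry if rng.random() < 0.7]
    if not dbs:
        dbs = [registry[int(rng.integers(len(registry)))]]
    hits = []
    for db in dbs:
        for j in range(int(rng.integers(1, max_hits_per_db + 1))):
            if rng.random() < 0.5:
                bitscore = float(rng.choice(_BITSCORES))
            else:
                bitscore = float(np.round(rng.uniform(40, 250), 1))
            if rng.random() < 0.5:
                coverage = float(rng.choice(_COVERAGES))
            else:
                coverage = float(np.round(rng.uniform(0.1, 1.0), 3))
            hits.append(make_hit(
                query="q", subject=f"{db.name}_s{j}", bitscore=bitscore,
                coverage=coverage, evalue=float(10.0 ** -rng.integers(5, 80)),
                database=db.name,
            ))
    return hits
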