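import random

import pytest

from slimgo.formats_io import HitRecord


def make_hit(query="q1", subject="s1", pident=90.0, length=100, evalue=1e-10,
             bitscore=200.0, mismatches=5, gap_opens=0):
    return HitRecord(
        query_id=query, subject_id=subject, percent_identity=pident,
        alignment_length=length, mismatches=mismatches, gap_opens=gap_opens,
        q_start=1, q_end=3 * length, s_start=1, s_end=length,
        evalue=evalue, bitscore=bitscore)


def random_hits(rng: random.Random, n_queries=20, max_hits=5,
                tie_prone=True):
    """Random hit lists; small value pools so metric ties are common."""
    evalues = [1e-5, 1e-8, 1e-10, 1e-10, 1e-20, 1e-30]
    bitscores = [50.0, 100.0, 100.0, 150.0, 200.0]
    lengths = [30, 50, 50, 100, 150]
    pidents = [25.0, 40.0, 40.0, 60.0, 95.0]
    if not tie_prone:
        evalues = sorted({e * (1 + i) for i, e in enumerate(evalues)})
    hits = []
    for i in range(n_queries):
        for j in range(rng.randint(1, max_hits)):
            hits.append(make_hit(
                query=f"q{i}", subject=f"s{i}_{j}",
                pident=rng.choice(pidents),
                length=rng.choice(lengths),
                evalue=rng.choice(evalues),
                bitscore=rng.choice(bitscores)))
    rng.shuffle(hits)
    return hits


def brute_force_best(hits, metric):
    """Independent per-query argmin/argmax scan with the stated tie-breaks."""
    by_query = {}
    for idx, h in enumerate(hits):
        by_query.setdefault(h.query_id, []).append((idx, h))
    winners = {}
    for q, rows in by_query.items():
        def sort_key(row):
            idx, h = row
            value = -h.evalue if metric == "evalue" else getattr(h, metric)
            return (value, h.bitscore, -idx)
        winners[q] = max(rows, key=sort_key)[1]
    return winners


@pytest.fixture
def rng():
    return random.Random(20230811)
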