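"""Cross-assembly matching under the coordinate-wiggle rule and
Venn-style shared/unique counts."""

import itertools

import numpy as np
import pytest

from te_exonize.compare import (
    MatchItem,
    match_records,
    venn_counts,
)
from te_exonize.models import GenomicInterval


def item(rid, start, end, chrom="chr1", strand="+"):
    return MatchItem(rid, GenomicInterval(chrom, start, end, strand))


def test_wiggle_boundary():
    ok = match_records([item("a", 100, 200)], [item("b", 110, 205)], wiggle=10)
    assert len(ok.pairs) == 1 and ok.pairs[0][2] == 15
    off = match_records([item("a", 100, 200)], [item("b", 111, 200)], wiggle=10)
    assert not off.pairs and off.unmatched_a and off.unmatched_b


def test_nearest_candidate_wins():
    res = match_records(
        [item("a", 100, 200)],
        [item("b1", 102, 202), item("b2", 105, 195)],
        wiggle=10,
    )
    assert res.pairs[0][1].record_id == "b1"  # distance 4 beats 10


def test_strand_and_chrom_must_match():
    assert not match_records(
        [item("a", 100, 200, strand="+")], [item("b", 100, 200, strand="-")]
    ).pairs
    assert not match_records(
        [item("a", 100, 200)], [item("b", 100, 200, chrom="chr2")]
    ).pairs


def test_negative_wiggle_rejected():
    with pytest.raises(ValueError, match="wiggle"):
        match_records([], [], wiggle=-1)


def test_zero_wiggle_equals_exact_equality():
    a = [item("a1", 100, 200), item("a2", 300, 400)]
    b = [item("b1", 100, 200), item("b2", 301, 400)]
    res = match_records(a, b, wiggle=0)
    assert [(x.record_id, y.record_id) for x, y, _ in res.pairs] == [("a1", "b1")]


def test_pair_count_monotone_in_wiggle_and_symmetric():
    rng = np.random.default_rng(5)
    a = [item(f"a{i}", s, s + 100) for i, s in
         enumerate(rng.integers(0, 2000, size=30).tolist())]
    b = [item(f"b{i}", s, s + 100) for i, s in
         enumerate(rng.integers(0, 2000, size=30).tolist())]
    counts = [len(match_records(a, b, wiggle=w).pairs) for w in (0, 2, 5, 10, 20)]
    assert counts == sorted(counts)
    for w in (0, 5, 10):
        assert len(match_records(a, b, w).pairs) == len(match_records(b, a, w).pairs)


def brute_force_min_assignment(set_a, set_b, wiggle):
    """Independent oracle: enumerate all one-to-one assignments over the
    candidate pairs; return (max cardinality, min total distance)."""
    cands = {}
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if (
                a.interval.chrom == b.interval.chrom
                and a.interval.strand == b.interval.strand
                and abs(a.interval.start - b.interval.start) <= wiggle
                and abs(a.interval.end - b.interval.end) <= wiggle
            ):
                cands[(i, j)] = (
                    abs(a.interval.start - b.interval.start)
                    + abs(a.interval.end - b.interval.end)
                )
    best = (0, 0)
    edges = list(cands)
    for r in range(len(edges), -1, -1):
        found = None
        for combo in itertools.combinations(edges, r):
            if len({i for i, _ in combo}) == r and len({j for _, j in combo}) == r:
                total = sum(cands[e] for e in combo)
                if found is None or total < found:
                    found = total
        if found is not None:
            best = (r, found)
            break
    return best


def test_greedy_equals_min_assignment_on_jittered_instances():
    """On realistic instances — one assembly a jittered copy of the other
    plus extras — greedy matching attains the brute-force optimum."""
    rng = np.random.default_rng(99)
    for _ in range(40):
        n = int(rng.integers(2, 5))
        a = []
        for i in range(n):
            s = int(rng.integers(0, 500))
            a.append(item(f"a{i}", s, s + int(rng.integers(80, 120))))
        b = []
        for i, x in enumerate(a):
            if rng.random() < 0.8:
                ds, de = rng.integers(-4, 5, size=2)
                b.append(
                    item(
                        f"b{i}",
                        max(0, x.interval.start + int(ds)),
                        x.interval.end + int(de),
                    )
                )
        for k in range(int(rng.integers(0, 2))):
            s = int(rng.integers(0, 500))
            b.append(item(f"bx{k}", s, s + 100))
        res = match_records(a, b, wiggle=10)
        card, total = brute_force_min_assignment(a, b, wiggle=10)
        assert len(res.pairs) == card
        assert sum(d for _, _, d in res.pairs) == total


def test_venn_counts_and_missing_flags():
    a = [item("a1", 100, 200), item("a2", 500, 600)]
    b = [item("b1", 101, 201), item("b2", 900, 1000)]
    res = match_records(a, b, wiggle=10)
    venn = venn_counts(
        res,
        {"a1": True, "a2": False},
        {"b1": True, "b2": True},
    )
    assert (venn.n_a, venn.n_b, venn.shared) == (2, 2, 1)
    assert (venn.n_a_te, venn.n_b_te, venn.shared_te) == (1, 2, 1)
    with pytest.raises(KeyError):
        venn_counts(res, {"a1": True}, {"b1": True, "b2": True})


def test_planted_shared_fraction_recovered(small_bundle):
    """The generator plants a known shared fraction between assemblies;
    matched pairs recover the planted a<->b identity map."""
    from te_exonize.compare import items_from_transcripts

    res = match_records(
        items_from_transcripts(small_bundle.transcripts_a),
        items_from_transcripts(small_bundle.transcripts_b),
        wiggle=10,
    )
    planted = set(
        zip(small_bundle.shared_truth["a_id"], small_bundle.shared_truth["b_id"])
    )
    got = {(a.record_id, b.record_id) for a, b, _ in res.pairs}
    # all planted pairs must be recovered; spurious extras are possible but
    # rare (novel records landing within 10bp of an A span)
    assert planted <= got
    assert len(got) - len(planted) <= 0.02 * len(planted)
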