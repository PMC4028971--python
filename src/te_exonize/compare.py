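"""Cross-assembly matching of transcripts/exons under a coordinate wiggle.

Two records from different assemblies are candidate matches when they lie
on the same chromosome and strand and both boundary shifts are within the
wiggle tolerance (default 10 bp on start AND end). Among the candidates a
one-to-one matching is computed that first maximizes the number of matched
pairs and then minimizes the total boundary distance sum(|dstart| +
|dend|), so shared/unique (Venn-style) counts never double-count a record
and agree with exhaustive-enumeration assignment on any instance. (A
simpler greedy pass by ascending distance is not used: when records
cluster within the wiggle, taking the globally cheapest pair first can
starve a neighbour of its only partner and lose a match.)

The assignment is solved exactly with the Hungarian algorithm on each
connected component of the candidate graph; components are tiny for
realistic jittered assemblies, so this stays linear in practice.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .models import ExonRecord, GenomicInterval, TranscriptRecord

DEFAULT_WIGGLE = 10

_INFEASIBLE = 10**7  # dwarfs any feasible total distance (<= 2*wiggle per pair)


@dataclass(frozen=True)
class MatchItem:
    """A matchable record: an id plus the interval compared under the
    wiggle rule (exon interval, or transcript genomic span)."""

    record_id: str
    interval: GenomicInterval


@dataclass
class MatchResult:
    pairs: list[tuple[MatchItem, MatchItem, int]]
    unmatched_a: list[MatchItem]
    unmatched_b: list[MatchItem]
    wiggle: int


def items_from_transcripts(
    transcripts: Iterable[TranscriptRecord],
) -> list[MatchItem]:
    """Transcript-level matching compares the genomic span (start of first
    exon to end of last)."""
    return [MatchItem(t.transcript_id, t.span) for t in transcripts]


def items_from_exons(exons: Iterable[ExonRecord]) -> list[MatchItem]:
    return [
        MatchItem(f"{e.transcript_id}:{e.interval.start}-{e.interval.end}", e.interval)
        for e in exons
    ]


def _candidate_edges(
    set_a: Sequence[MatchItem], set_b: Sequence[MatchItem], wiggle: int
) -> dict[tuple[int, int], int]:
    """All (i, j) pairs within the wiggle on both boundaries, with their
    distance |dstart| + |dend|."""
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for j, item in enumerate(set_b):
        groups.setdefault(
            (item.interval.chrom, item.interval.strand), []
        ).append((item.interval.start, j))
    for key in groups:
        groups[key].sort()
    edges: dict[tuple[int, int], int] = {}
    for i, a in enumerate(set_a):
        group = groups.get((a.interval.chrom, a.interval.strand))
        if not group:
            continue
        starts = [s for s, _ in group]
        lo = bisect_left(starts, a.interval.start - wiggle)
        hi = bisect_right(starts, a.interval.start + wiggle)
        for _, j in group[lo:hi]:
            b = set_b[j]
            d_end = abs(a.interval.end - b.interval.end)
            if d_end > wiggle:
                continue
            edges[(i, j)] = abs(a.interval.start - b.interval.start) + d_end
    return edges


def _components(edges: dict[tuple[int, int], int]) -> list[tuple[list[int], list[int]]]:
    """Connected components of the bipartite candidate graph, as sorted
    (A-indices, B-indices) lists."""
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, j in edges:
        union(("a", i), ("b", j))
    comps: dict[tuple[str, int], tuple[list[int], list[int]]] = {}
    for node in parent:
        side, idx = node
        comp = comps.setdefault(find(node), ([], []))
        comp[0 if side == "a" else 1].append(idx)
    return [(sorted(a_idx), sorted(b_idx)) for a_idx, b_idx in comps.values()]


def match_records(
    set_a: Sequence[MatchItem],
    set_b: Sequence[MatchItem],
    wiggle: int = DEFAULT_WIGGLE,
) -> MatchResult:
    """One-to-one matching of maximal cardinality and minimal total
    distance over the wiggle-feasible candidate pairs.

    wiggle=0 degenerates to exact coordinate equality. Output pair order
    is deterministic: (chrom, A start, A end, A id).
    """
    if wiggle < 0:
        raise ValueError(f"wiggle must be >= 0, got {wiggle}")
    edges = _candidate_edges(set_a, set_b, wiggle)
    used_a: set[int] = set()
    used_b: set[int] = set()
    raw_pairs: list[tuple[int, int, int]] = []
    for a_idx, b_idx in _components(edges):
        cost = np.full((len(a_idx), len(b_idx)), _INFEASIBLE, dtype=np.int64)
        for ai, i in enumerate(a_idx):
            for bj, j in enumerate(b_idx):
                d = edges.get((i, j))
                if d is not None:
                    cost[ai, bj] = d
        rows, cols = linear_sum_assignment(cost)
        for ai, bj in zip(rows, cols):
            if cost[ai, bj] < _INFEASIBLE:
                i, j = a_idx[ai], b_idx[bj]
                raw_pairs.append((i, j, int(cost[ai, bj])))
                used_a.add(i)
                used_b.add(j)
    raw_pairs.sort(
        key=lambda p: (
            set_a[p[0]].interval.chrom,
            set_a[p[0]].interval.start,
            set_a[p[0]].interval.end,
            set_a[p[0]].record_id,
        )
    )
    return MatchResult(
        pairs=[(set_a[i], set_b[j], d) for i, j, d in raw_pairs],
        unmatched_a=[a for i, a in enumerate(set_a) if i not in used_a],
        unmatched_b=[b for j, b in enumerate(set_b) if j not in used_b],
        wiggle=wiggle,
    )


@dataclass
class VennCounts:
    """Shared/unique counts for all records and for the TE-derived subset
    (a shared-TE pair requires both members TE-derived)."""

    n_a: int
    n_b: int
    shared: int
    n_a_te: int
    n_b_te: int
    shared_te: int


def venn_counts(
    match: MatchResult,
    te_flags_a: dict[str, bool],
    te_flags_b: dict[str, bool],
) -> VennCounts:
    all_a = [a for a, _, _ in match.pairs] + match.unmatched_a
    all_b = [b for _, b, _ in match.pairs] + match.unmatched_b
    for item in all_a:
        if item.record_id not in te_flags_a:
            raise KeyError(f"missing TE flag for A record {item.record_id!r}")
    for item in all_b:
        if item.record_id not in te_flags_b:
            raise KeyError(f"missing TE flag for B record {item.record_id!r}")
    return VennCounts(
        n_a=len(all_a),
        n_b=len(all_b),
        shared=len(match.pairs),
        n_a_te=sum(te_flags_a[a.record_id] for a in all_a),
        n_b_te=sum(te_flags_b[b.record_id] for b in all_b),
        shared_te=sum(
            te_flags_a[a.record_id] and te_flags_b[b.record_id]
            for a, b, _ in match.pairs
        ),
    )
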