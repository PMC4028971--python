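"""Deterministic interval-overlap queries, the computational core of
co-location.

Backed by :mod:`intervaltree` (one tree per chromosome). Overlap is "any
shared base": two half-open intervals overlap iff max(starts) < min(ends).
Strand is ignored by default — TE/exon and signal/exon co-location is not
strand-conditioned — but strand-matched queries are available via a flag.
"""

from __future__ import annotations

from typing import Any, Iterable

from intervaltree import IntervalTree

from .models import GenomicInterval


class IntervalIndex:
    """Searchable index over (GenomicInterval, payload) pairs.

    Duplicate intervals are preserved: each entry carries a serial number
    so identical coordinates with identical payloads remain distinct.
    Query results are returned in deterministic (start, end, insertion)
    order.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0

    def __len__(self) -> int:
        return self._n

    def add(self, interval: GenomicInterval, payload: Any = None) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, (self._n, interval, payload))
        self._n += 1

    def query(
        self, query: GenomicInterval, ignore_strand: bool = True
    ) -> list[tuple[GenomicInterval, Any]]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = []
        for hit in tree.overlap(query.start, query.end):
            serial, interval, payload = hit.data
            if not ignore_strand and interval.strand != query.strand:
                continue
            hits.append((serial, interval, payload))
        hits.sort(key=lambda h: (h[1].start, h[1].end, h[0]))
        return [(interval, payload) for _, interval, payload in hits]


def build_index(
    intervals: Iterable[tuple[GenomicInterval, Any]]
) -> IntervalIndex:
    """Build an :class:`IntervalIndex` from (interval, payload) pairs.
    Empty input yields an index that answers every query with []."""
    index = IntervalIndex()
    for interval, payload in intervals:
        index.add(interval, payload)
    return index


def query_overlaps(
    query: GenomicInterval, index: IntervalIndex, ignore_strand: bool = True
) -> list[tuple[GenomicInterval, Any]]:
    """All stored intervals on ``query.chrom`` sharing >= 1 bp with
    ``query``."""
    return index.query(query, ignore_strand=ignore_strand)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if disjoint or on
    different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))
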