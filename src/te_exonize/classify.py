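"""TE-derived classification of exons and transcripts, first-exon/TSS
identification, and fraction summaries.

An exon is *TE-derived* when any part of it overlaps a repeat annotation
(any overlap, >= 1 bp, no minimum fraction). A transcript is TE-derived
when any of its exons is; a separate flag records whether its *first* exon
(5'-most in transcription order) is TE-derived, since TEs donating an
alternative TSS plus first exon is the biologically distinct event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import IntervalIndex, build_index, query_overlaps
from .models import ExonRecord, FractionSummary, TEAnnotation, TranscriptRecord

UNIVERSES = ("all_exons", "first_exons", "transcripts")


@dataclass
class ExonCall:
    """Per-exon classification outcome with the overlapping repeats kept
    for downstream family attribution."""

    exon: ExonRecord
    te_derived: bool
    tes: list[TEAnnotation] = field(default_factory=list)


@dataclass
class ClassificationResult:
    exon_calls: list[ExonCall]
    first_exon_calls: list[ExonCall] = field(default_factory=list)
    transcript_te_derived: dict[str, bool] = field(default_factory=dict)
    transcript_te_first_exon: dict[str, bool] = field(default_factory=dict)


def build_te_index(tes: Iterable[TEAnnotation]) -> IntervalIndex:
    return build_index((te.interval, te) for te in tes)


def classify_exons(
    exons: Iterable[ExonRecord], te_index: IntervalIndex
) -> list[ExonCall]:
    """Flag each exon TE-derived iff it overlaps >= 1 repeat (strand
    ignored); the overlapping repeats are recorded on the call."""
    calls = []
    for exon in exons:
        hits = query_overlaps(exon.interval, te_index, ignore_strand=True)
        tes = [payload for _, payload in hits]
        calls.append(ExonCall(exon=exon, te_derived=bool(tes), tes=tes))
    return calls


def first_exon(transcript: TranscriptRecord) -> ExonRecord:
    """The 5'-most exon in transcription order.

    On ``+`` the exon with minimal start; on ``-`` the exon with maximal
    end. Ties go to the longer exon, then to coordinate order, so the
    choice is deterministic.
    """
    strand = transcript.strand
    if strand == "+":
        key = lambda e: (e.interval.start, -e.interval.length, e.interval.end)
        return min(transcript.exons, key=key)
    key = lambda e: (-e.interval.end, -e.interval.length, e.interval.start)
    return min(transcript.exons, key=key)


def tss(transcript: TranscriptRecord) -> tuple[str, int]:
    """Transcription start site: the first transcribed base. On ``-`` this
    is the last covered base of the first exon (end - 1 in half-open
    coordinates)."""
    fe = first_exon(transcript).interval
    pos = fe.start if transcript.strand == "+" else fe.end - 1
    return (fe.chrom, pos)


def classify_transcriptome(
    transcripts: Sequence[TranscriptRecord], te_index: IntervalIndex
) -> ClassificationResult:
    """Classify every exon of every transcript and derive transcript-level
    and first-exon flags.

    The all-exon universe counts exon records as emitted by the assembly —
    no coordinate-based deduplication — matching how assembler exon totals
    are tallied.
    """
    exon_calls: list[ExonCall] = []
    first_calls: list[ExonCall] = []
    t_flag: dict[str, bool] = {}
    f_flag: dict[str, bool] = {}
    for t in transcripts:
        calls = classify_exons(t.exons, te_index)
        exon_calls.extend(calls)
        fe = first_exon(t)
        fe_call = next(c for c in calls if c.exon is fe)
        first_calls.append(fe_call)
        t_flag[t.transcript_id] = any(c.te_derived for c in calls)
        f_flag[t.transcript_id] = fe_call.te_derived
    return ClassificationResult(
        exon_calls=exon_calls,
        first_exon_calls=first_calls,
        transcript_te_derived=t_flag,
        transcript_te_first_exon=f_flag,
    )


def fraction_te_derived(
    result: ClassificationResult, universe: str = "all_exons"
) -> FractionSummary:
    """TE-derived fraction over one of three universes: every exon record,
    one first exon per transcript, or whole transcripts."""
    if universe == "all_exons":
        items = [c.te_derived for c in result.exon_calls]
    elif universe == "first_exons":
        items = [c.te_derived for c in result.first_exon_calls]
    elif universe == "transcripts":
        items = list(result.transcript_te_derived.values())
    else:
        raise ValueError(f"universe must be one of {UNIVERSES}, got {universe!r}")
    if not items:
        raise ValueError(f"empty universe {universe!r}: fraction undefined")
    return FractionSummary(
        label=universe, numerator=sum(items), denominator=len(items)
    )
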