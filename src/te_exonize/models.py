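"""Core genomic record types shared across the pipeline.

All coordinates are 0-based half-open internally. GTF input (1-based
closed) is converted on read and back on write; BED-style inputs are used
natively. Every record type validates its invariants at construction so
downstream code can assume well-formed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

STRANDS = ("+", "-", ".")

#: Six TE families tracked explicitly; everything else maps to "other".
TE_FAMILIES = ("Alu", "L1", "LTR", "DNA", "L2", "MIR")

# Prefix rules mapping a RepeatMasker class/family string to a family group.
# Order matters: first matching prefix wins.
_FAMILY_PREFIXES = (
    ("SINE/Alu", "Alu"),
    ("SINE/MIR", "MIR"),
    ("LINE/L1", "L1"),
    ("LINE/L2", "L2"),
    ("LTR", "LTR"),
    ("DNA", "DNA"),
)


def family_group_of(raw_class: str) -> str:
    """Map a RepeatMasker class/family string to one of the six named TE
    families (Alu, L1, LTR, DNA, L2, MIR) or ``"other"``."""
    for prefix, family in _FAMILY_PREFIXES:
        if raw_class.startswith(prefix):
            return family
    return "other"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for reported
    percentages), unlike Python's default banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExonRecord:
    """One exon of an assembled transcript. Strand must be + or - because
    first-exon calling is strand-dependent."""

    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    assembly_label: str = ""

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"exon strand must be + or -, got {self.interval.strand!r} "
                f"(transcript {self.transcript_id})"
            )


@dataclass
class TranscriptRecord:
    """An assembled gene model: ordered exons on one chromosome/strand plus
    per-sample FPKM expression values."""

    transcript_id: str
    gene_id: str
    exons: list[ExonRecord]
    fpkm: dict[str, float] = field(default_factory=dict)
    assembly_label: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.interval.chrom for e in self.exons}
        strands = {e.interval.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        by_start = sorted(self.exons, key=lambda e: e.interval.start)
        for a, b in zip(by_start, by_start[1:]):
            if b.interval.start < a.interval.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        for v in self.fpkm.values():
            if v < 0:
                raise ValueError(
                    f"transcript {self.transcript_id} has negative FPKM"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint: start of leftmost exon to end of rightmost."""
        return GenomicInterval(
            self.chrom,
            min(e.interval.start for e in self.exons),
            max(e.interval.end for e in self.exons),
            self.strand,
        )

    def mean_fpkm(self) -> float:
        if not self.fpkm:
            return 0.0
        return sum(self.fpkm.values()) / len(self.fpkm)


@dataclass
class TEAnnotation:
    """One repeat instance. ``millidiv`` is divergence from the family
    consensus in substitutions per 1000 bases, a proxy for element age."""

    interval: GenomicInterval
    name: str
    raw_class: str
    millidiv: float
    family_group: str = ""

    def __post_init__(self) -> None:
        if self.millidiv < 0:
            raise ValueError(f"millidiv must be >= 0, got {self.millidiv}")
        derived = family_group_of(self.raw_class)
        if not self.family_group:
            self.family_group = derived
        elif self.family_group != derived:
            raise ValueError(
                f"family_group {self.family_group!r} inconsistent with "
                f"raw_class {self.raw_class!r} (expected {derived!r})"
            )


@dataclass
class SignalFeature:
    """A peak/cluster call from one epigenetic track (histone mark, DHS,
    CAGE)."""

    interval: GenomicInterval
    track: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.track:
            raise ValueError("track must be non-empty")
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")


@dataclass
class FractionSummary:
    """A numerator/denominator pair with its reported percentage.

    ``percent`` is the raw ratio times 100; ``percent_reported`` applies
    the half-up rounding to one decimal used for display. The raw ratio is
    the source of truth.
    """

    label: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError(f"{self.label}: denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"{self.label}: numerator {self.numerator} outside "
                f"[0, {self.denominator}]"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def percent_reported(self) -> float:
        return round_half_up(self.percent, 1)
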