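"""Per-family TE contribution normalized by genomic background abundance,
millidiv-based age ranking, and a chi-square test of heterogeneity.

The contribution of a family is hits / abundance: the number of TE-derived
exons attributed to the family divided by how common the family is in the
genome (element count by default, total bp optionally). Family age is
proxied by mean millidiv — divergence from the consensus accumulates with
time, so a smaller mean means a younger family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .classify import ClassificationResult
from .models import TE_FAMILIES, TEAnnotation

ABUNDANCE_MODES = ("elements", "bp")


@dataclass
class FamilyContribution:
    family_group: str
    hits: int
    abundance: float
    normalized: float | None  # None when abundance is 0 (undefined)
    mean_millidiv: float | None = None
    age_rank: int | None = None


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def attribute_hits(classification: ClassificationResult) -> dict[str, int]:
    """Count TE-derived exons per family. An exon overlapping repeats of
    two families counts once for each family (distinct families per
    exon)."""
    counts: Counter[str] = Counter()
    for call in classification.exon_calls:
        if not call.te_derived:
            continue
        for family in {te.family_group for te in call.tes}:
            counts[family] += 1
    return dict(counts)


def genomic_abundance(
    tes: Sequence[TEAnnotation], mode: str = "elements"
) -> dict[str, float]:
    """Background abundance per family: annotation-record count
    (``elements``) or summed interval length (``bp``)."""
    if mode not in ABUNDANCE_MODES:
        raise ValueError(f"mode must be one of {ABUNDANCE_MODES}, got {mode!r}")
    if not tes:
        raise ValueError("empty TE annotation: abundance undefined")
    out: dict[str, float] = {}
    for te in tes:
        weight = 1.0 if mode == "elements" else float(te.interval.length)
        out[te.family_group] = out.get(te.family_group, 0.0) + weight
    return out


def mean_millidiv(tes: Sequence[TEAnnotation]) -> dict[str, float]:
    sums: dict[str, float] = {}
    ns: Counter[str] = Counter()
    for te in tes:
        sums[te.family_group] = sums.get(te.family_group, 0.0) + te.millidiv
        ns[te.family_group] += 1
    return {fam: sums[fam] / ns[fam] for fam in sums}


def age_rank(tes: Sequence[TEAnnotation]) -> list[str]:
    """Rank the six named families youngest-first by mean millidiv
    (ascending; ties alphabetical). ``other`` repeats are excluded from
    the ranking."""
    means = mean_millidiv(tes)
    ranked = [fam for fam in means if fam in TE_FAMILIES]
    ranked.sort(key=lambda fam: (means[fam], fam))
    return ranked


def normalize_contribution(
    hits: Mapping[str, int],
    abundance: Mapping[str, float],
    millidivs: Mapping[str, float] | None = None,
) -> list[FamilyContribution]:
    """hits / abundance per family. Families with zero abundance are
    flagged missing (normalized=None), never divided. Output order: the
    six named families by age rank when millidivs are given (else fixed
    order), then ``other``."""
    families = sorted(set(hits) | set(abundance) | set(millidivs or {}))
    named = [f for f in families if f in TE_FAMILIES]
    if millidivs:
        named.sort(key=lambda f: (millidivs.get(f, float("inf")), f))
    else:
        named.sort(key=TE_FAMILIES.index)
    ordered = named + [f for f in families if f not in TE_FAMILIES]
    out = []
    for rank, fam in enumerate(ordered, start=1):
        ab = abundance.get(fam, 0.0)
        h = int(hits.get(fam, 0))
        out.append(
            FamilyContribution(
                family_group=fam,
                hits=h,
                abundance=ab,
                normalized=(h / ab) if ab > 0 else None,
                mean_millidiv=(millidivs or {}).get(fam),
                age_rank=rank if fam in TE_FAMILIES else None,
            )
        )
    return out


def chi_square_families(
    hits: Mapping[str, int], abundance: Mapping[str, float]
) -> ChiSquareResult:
    """Chi-square goodness-of-fit of observed per-family hit counts against
    abundance-proportional expectations.

    expected_i = total_hits * abundance_i / sum(abundance);
    statistic = sum (obs_i - exp_i)^2 / exp_i with df = k - 1. The
    statistic is 0 iff hits are exactly proportional to abundance.
    """
    families = sorted(set(hits) | set(abundance))
    obs = [float(hits.get(f, 0)) for f in families]
    ab = [float(abundance.get(f, 0.0)) for f in families]
    total_hits = sum(obs)
    total_ab = sum(ab)
    if len([a for a in ab if a > 0]) < 2:
        raise ValueError("need >= 2 families with positive abundance")
    if total_hits < 1:
        raise ValueError("no hits: chi-square undefined")
    expected = [total_hits * a / total_ab for a in ab]
    if any(e == 0 for e in expected):
        zero = [f for f, e in zip(families, expected) if e == 0]
        raise ValueError(f"zero expected count for families {zero}")
    statistic = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
    df = len(families) - 1
    return ChiSquareResult(
        statistic=statistic, df=df, p=float(stats.chi2.sf(statistic, df))
    )
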