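"""Expression-binned epigenetic signal profiles over TE-derived exons.

Exons are sorted by expression (FPKM) and split into equal-count bins
(default 100); per bin, the mean expression and mean per-exon signal
(peak/cluster count by default) are computed per track. The strength of
the expression-signal trend is the Pearson correlation of the bin means,
with significance from the Student's-t approximation of the sampling
distribution of r:

    t = r * sqrt(n - 2) / sqrt(1 - r^2),  df = n - 2

Equal-count (quantile) bins are used rather than equal-width FPKM bins:
FPKM is heavy-tailed, and equal membership is the only reading under which
the bins are "equal sized".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import IntervalIndex, overlap_length, query_overlaps
from .models import ExonRecord, GenomicInterval, SignalFeature

SIGNAL_MODES = ("count", "bp", "score")
DEFAULT_NBINS = 100


@dataclass
class BinProfile:
    bin_index: int  # 1-based, ascending expression
    n_exons: int
    mean_fpkm: float
    mean_signal: dict[str, float]


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float

    @property
    def df(self) -> int:
        return self.n - 2


def bin_by_expression(
    exon_fpkm: Sequence[tuple[ExonRecord, float]],
    nbins: int = DEFAULT_NBINS,
) -> list[list[tuple[ExonRecord, float]]]:
    """Split exons into ``nbins`` equal-count bins of ascending FPKM.

    Ties are ordered by (chrom, start, transcript_id) so bin membership is
    reproducible. With n = q*nbins + rem, the first ``rem`` bins hold q+1
    exons and the rest q.
    """
    if nbins < 1:
        raise ValueError(f"nbins must be >= 1, got {nbins}")
    n = len(exon_fpkm)
    if n < nbins:
        raise ValueError(f"cannot split {n} exons into {nbins} bins")
    ordered = sorted(
        exon_fpkm,
        key=lambda ef: (
            ef[1], ef[0].interval.chrom, ef[0].interval.start, ef[0].transcript_id,
        ),
    )
    q, rem = divmod(n, nbins)
    bins = []
    pos = 0
    for i in range(nbins):
        size = q + 1 if i < rem else q
        bins.append(ordered[pos : pos + size])
        pos += size
    return bins


def signal_per_exon(
    exon: ExonRecord,
    signals: IntervalIndex,
    mode: str = "count",
    flank: int = 0,
) -> float:
    """Signal intensity of one exon from a single-track index.

    ``count``: number of overlapping features; ``bp``: summed overlap
    length; ``score``: summed feature scores. ``flank`` widens the exon on
    both sides before querying (default 0: the exon itself).
    """
    if mode not in SIGNAL_MODES:
        raise ValueError(f"mode must be one of {SIGNAL_MODES}, got {mode!r}")
    iv = exon.interval
    query = GenomicInterval(
        iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.strand
    )
    hits = query_overlaps(query, signals, ignore_strand=True)
    if mode == "count":
        return float(len(hits))
    if mode == "bp":
        return float(sum(overlap_length(query, h) for h, _ in hits))
    total = 0.0
    for h_iv, feat in hits:
        if feat.score is None:
            raise ValueError(
                f"score mode requires scored features; {feat.track} feature at "
                f"{h_iv.chrom}:{h_iv.start}-{h_iv.end} has none"
            )
        total += feat.score
    return total


def bin_profile(
    bins: Sequence[Sequence[tuple[ExonRecord, float]]],
    signal_indexes: Mapping[str, IntervalIndex],
    mode: str = "count",
    flank: int = 0,
) -> list[BinProfile]:
    """Per-bin mean FPKM and per-track mean per-exon signal."""
    if not bins:
        raise ValueError("no bins")
    profiles = []
    for i, members in enumerate(bins, start=1):
        fpkms = [f for _, f in members]
        mean_signal = {}
        for track, index in signal_indexes.items():
            values = [
                signal_per_exon(exon, index, mode=mode, flank=flank)
                for exon, _ in members
            ]
            mean_signal[track] = float(np.mean(values))
        profiles.append(
            BinProfile(
                bin_index=i,
                n_exons=len(members),
                mean_fpkm=float(np.mean(fpkms)),
                mean_signal=mean_signal,
            )
        )
    return profiles


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    r = float(xc @ yc) / denom
    return max(-1.0, min(1.0, r))


def pearson_t(r: float, n: int) -> CorrelationResult:
    """Significance of a correlation via the t approximation
    t = r*sqrt(n-2)/sqrt(1-r^2) with df = n-2; two-sided p."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, t=t, p=min(1.0, p))


def correlate_profile(
    profiles: Sequence[BinProfile], track: str
) -> CorrelationResult:
    """Pearson r (with t/p) of per-bin mean signal against per-bin mean
    FPKM — the significance of the plotted binned trend."""
    x = [p.mean_fpkm for p in profiles]
    y = [p.mean_signal[track] for p in profiles]
    return pearson_t(pearson_r(x, y), len(profiles))
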