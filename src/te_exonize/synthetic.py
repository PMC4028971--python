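"""Ground-truth-labeled synthetic inputs for the whole pipeline.

The generator emulates the statistical structure of the real inputs — a
RepeatMasker-style TE landscape of six families with family-specific
abundances and divergence (millidiv) distributions, assembled gene models
whose first exons overlap TEs more often than later exons, two-condition
replicated FPKM values with a planted differentially-expressed subset, a
partially overlapping second assembly with jittered coordinates, and
peak tracks whose per-exon intensity rises with log expression — while
recording every planted label in sidecar truth tables so recovery can be
checked exactly.

It does not emulate sequence content (no FASTA), splice-site motifs,
read-level noise, or the clustered/nested arrangement of real repeats;
placements are uniform given the planted overlap structure.

Determinism: one ``numpy`` generator seeded from ``config.seed`` drives
everything, so the same config yields a byte-identical output bundle.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation_io
from .models import (
    ExonRecord,
    GenomicInterval,
    TEAnnotation,
    TranscriptRecord,
)


@dataclass
class FamilyParams:
    """Per-family landscape parameters: element count, element length
    (normal, bp), and divergence (normal truncated at 0, millidiv)."""

    count: int
    length_mean: float
    length_sd: float
    millidiv_mean: float
    millidiv_sd: float


@dataclass
class TrackParams:
    """Per-track signal model: expected peak count per exon is
    max(0, a + b*ln(FPKM+1)) + Normal(0, noise_sd), rounded. b = 0 gives a
    null track uncoupled from expression."""

    intercept: float = 0.5
    slope: float = 1.0
    noise_sd: float = 0.5


def _default_families() -> dict[str, FamilyParams]:
    # Counts equal across families; millidiv means ordered youngest to
    # oldest: Alu < L1 < LTR < DNA < L2 < MIR. Lengths are loosely
    # family-typical (Alu ~300 bp, full/partial L1 ~900 bp, MIR ~260 bp).
    return {
        "Alu": FamilyParams(600, 300, 50, 80, 30),
        "L1": FamilyParams(600, 900, 250, 130, 30),
        "LTR": FamilyParams(600, 500, 150, 180, 30),
        "DNA": FamilyParams(600, 400, 100, 230, 30),
        "L2": FamilyParams(600, 450, 120, 280, 30),
        "MIR": FamilyParams(600, 260, 60, 330, 30),
    }


def _default_tracks() -> dict[str, TrackParams]:
    return {
        "H3K4me3": TrackParams(0.5, 1.0, 0.5),
        "H3K9ac": TrackParams(0.5, 0.9, 0.5),
        "H3K27ac": TrackParams(0.4, 0.8, 0.5),
        "H3K36me3": TrackParams(0.5, 0.7, 0.5),
        "DHS": TrackParams(0.3, 0.7, 0.4),
        "CAGE": TrackParams(0.2, 0.5, 0.4),
    }


_RAW_CLASS = {
    "Alu": "SINE/Alu",
    "MIR": "SINE/MIR",
    "L1": "LINE/L1",
    "L2": "LINE/L2",
    "LTR": "LTR/ERVL",
    "DNA": "DNA/hAT-Charlie",
}


@dataclass
class SyntheticConfig:
    """All planted parameters. Defaults give a desk-scale dataset (two
    5 Mb chromosomes, 2000 transcripts, 600 elements per family) that runs
    the full pipeline in well under a minute."""

    seed: int = 0
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 5_000_000), ("chr2", 5_000_000)]
    )
    te_families: dict[str, FamilyParams] = field(default_factory=_default_families)
    n_transcripts: int = 2000
    exon_mean_extra: float = 1.5  # exons per transcript = 1 + Poisson(this)
    exon_length_log_mean: float = 5.0  # ln-scale; median exon ~148 bp
    exon_length_log_sd: float = 0.5
    intron_min: int = 50
    intron_max: int = 2000
    rho_first: float = 0.4
    rho_later: float = 0.1
    fpkm_log2_mean: float = 3.0
    fpkm_log2_sd: float = 2.0
    replicate_log2_sd: float = 0.15  # ~10% CV on the FPKM scale
    n_samples_per_group: int = 2
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    tracks: dict[str, TrackParams] = field(default_factory=_default_tracks)
    peak_width: int = 50
    shared_fraction: float = 0.6
    novel_fraction: float = 0.3
    jitter_max: int = 3  # per-boundary jitter for shared assembly-B records
    assembly_a_label: str = "nonref"
    assembly_b_label: str = "refguided"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genome" in raw:
            raw["genome"] = [tuple(item) for item in raw["genome"]]
        if "te_families" in raw:
            raw["te_families"] = {
                fam: FamilyParams(**params)
                for fam, params in raw["te_families"].items()
            }
        if "tracks" in raw:
            raw["tracks"] = {
                name: TrackParams(**params) for name, params in raw["tracks"].items()
            }
        return cls(**raw)


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, in memory."""

    config: SyntheticConfig
    tes: list[TEAnnotation]
    transcripts_a: list[TranscriptRecord]
    transcripts_b: list[TranscriptRecord]
    exon_truth: pd.DataFrame  # transcript_id, exon_index, coords, te_overlap, is_first
    de_truth: pd.DataFrame  # gene_id, is_de, log2fc
    shared_truth: pd.DataFrame  # a_id, b_id
    fpkm: dict[str, dict[str, float]]
    signals: dict[str, list]  # track -> SignalFeatures

    @property
    def sample_labels(self) -> tuple[list[str], list[str]]:
        n = self.config.n_samples_per_group
        return (
            [f"A_{i + 1}" for i in range(n)],
            [f"B_{i + 1}" for i in range(n)],
        )


def simulate_te_landscape(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[TEAnnotation]:
    """Place each family's elements uniformly on the genome (within
    chromosome bounds; elements may overlap each other, as nested repeats
    do) with truncated-normal millidiv."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if not config.genome:
        raise ValueError("genome must be non-empty")
    chrom_names = [c for c, _ in config.genome]
    chrom_lens = np.array([l for _, l in config.genome], dtype=float)
    genome_bp = chrom_lens.sum()
    demanded = sum(
        p.count * p.length_mean for p in config.te_families.values()
    )
    if demanded > genome_bp:
        raise ValueError(
            f"requested ~{demanded:.0f} TE bp exceeds genome size {genome_bp:.0f}"
        )
    probs = chrom_lens / genome_bp
    tes: list[TEAnnotation] = []
    for fam in sorted(config.te_families):
        params = config.te_families[fam]
        for i in range(params.count):
            length = max(30, int(round(rng.normal(params.length_mean, params.length_sd))))
            ci = int(rng.choice(len(chrom_names), p=probs))
            chrom, clen = chrom_names[ci], int(chrom_lens[ci])
            start = int(rng.integers(0, max(1, clen - length)))
            millidiv = max(0.0, float(rng.normal(params.millidiv_mean, params.millidiv_sd)))
            strand = "+" if rng.random() < 0.5 else "-"
            tes.append(
                TEAnnotation(
                    interval=GenomicInterval(chrom, start, start + length, strand),
                    name=f"{fam}_syn{i}",
                    raw_class=_RAW_CLASS[fam],
                    millidiv=millidiv,
                )
            )
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end, t.name))
    return tes


class _TELookup:
    """Per-chromosome sorted TE arrays for fast 'TEs ahead of the cursor'
    and 'does this window touch a TE' queries during exon placement."""

    def __init__(self, tes: Sequence[TEAnnotation]):
        self.by_chrom: dict[str, list[TEAnnotation]] = {}
        for te in tes:
            self.by_chrom.setdefault(te.interval.chrom, []).append(te)
        self.starts: dict[str, list[int]] = {}
        self.max_end_prefix: dict[str, list[int]] = {}
        for chrom, items in self.by_chrom.items():
            items.sort(key=lambda t: (t.interval.start, t.interval.end))
            self.starts[chrom] = [t.interval.start for t in items]
            prefix, best = [], 0
            for t in items:
                best = max(best, t.interval.end)
                prefix.append(best)
            self.max_end_prefix[chrom] = prefix

    def in_window(self, chrom: str, lo: int, hi: int) -> list[TEAnnotation]:
        """TEs whose start lies in [lo, hi)."""
        items = self.by_chrom.get(chrom, [])
        starts = self.starts.get(chrom, [])
        return items[bisect_left(starts, lo) : bisect_left(starts, hi)]

    def touches(self, chrom: str, start: int, end: int) -> bool:
        """Any TE overlapping [start, end)?"""
        items = self.by_chrom.get(chrom)
        if not items:
            return False
        starts = self.starts[chrom]
        i = bisect_left(starts, end)  # TEs starting before `end`
        if i == 0:
            return False
        return self.max_end_prefix[chrom][i - 1] > start


def _place_transcript(
    config: SyntheticConfig,
    rng: np.random.Generator,
    lookup: _TELookup,
    chrom_names: list[str],
    chrom_lens: list[int],
    probs: np.ndarray,
    labels_genomic: list[bool],
) -> tuple[str, list[tuple[int, int]]] | None:
    """Try to place one transcript's exons left-to-right; returns
    (chrom, exon coordinate pairs), or None when placement fails."""
    ci = int(rng.choice(len(chrom_names), p=probs))
    chrom, clen = chrom_names[ci], chrom_lens[ci]
    cursor = int(rng.integers(0, int(clen * 0.9)))
    coords: list[tuple[int, int]] = []
    for i, te_label in enumerate(labels_genomic):
        gap = 0 if i == 0 else int(rng.integers(config.intron_min, config.intron_max))
        length = max(
            20,
            int(round(math.exp(rng.normal(config.exon_length_log_mean,
                                          config.exon_length_log_sd)))),
        )
        lo = cursor + gap
        if te_label:
            window = lookup.in_window(chrom, lo, lo + 50_000)
            window = [t for t in window if t.interval.end - 1 >= lo]
            if not window:
                return None
            te = window[int(rng.integers(0, len(window)))]
            # exon must share >= 1 bp with the chosen TE and start >= lo
            smin = max(lo, te.interval.start - length + 1)
            smax = te.interval.end - 1
            if smax < smin:
                return None
            start = int(rng.integers(smin, smax + 1))
        else:
            start = None
            for _ in range(60):
                cand = lo + int(rng.integers(0, 5000))
                if cand + length > clen:
                    break
                if not lookup.touches(chrom, cand, cand + length):
                    start = cand
                    break
            if start is None:
                return None
        end = start + length
        if end > clen:
            return None
        coords.append((start, end))
        cursor = end
    return (chrom, coords)


def simulate_transcriptome(
    config: SyntheticConfig,
    tes: Sequence[TEAnnotation],
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptRecord], pd.DataFrame, list[TranscriptRecord], pd.DataFrame]:
    """Generate assembly A with planted per-exon TE-overlap labels, plus a
    second assembly B sharing a fraction of A's transcripts with jittered
    coordinates and additional novel transcripts.

    The first exon (in transcription order) overlaps a TE with probability
    ``rho_first``, later exons with ``rho_later``. Non-TE exons are
    rejection-sampled to be TE-free, so the planted label equals the
    overlap-based classification exactly.

    Returns (transcripts_a, exon_truth, transcripts_b, shared_truth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lookup = _TELookup(tes)
    chrom_names = [c for c, _ in config.genome]
    chrom_lens = [l for _, l in config.genome]
    probs = np.asarray(chrom_lens, dtype=float)
    probs = probs / probs.sum()

    transcripts: list[TranscriptRecord] = []
    truth_rows = []
    for idx in range(config.n_transcripts):
        tid, gid = f"t{idx:05d}", f"g{idx:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = 1 + int(rng.poisson(config.exon_mean_extra))
        labels_tx = [bool(rng.random() < config.rho_first)] + [
            bool(rng.random() < config.rho_later) for _ in range(n_exons - 1)
        ]
        labels_genomic = labels_tx if strand == "+" else labels_tx[::-1]
        placed = None
        for _attempt in range(40):
            result = _place_transcript(
                config, rng, lookup, chrom_names, chrom_lens, probs, labels_genomic
            )
            if result is not None:
                placed = result
                break
        if placed is None:
            raise RuntimeError(
                f"could not place transcript {tid} after bounded retries; "
                "genome too crowded for the requested structure"
            )
        chrom, coords = placed
        exons = [
            ExonRecord(
                interval=GenomicInterval(chrom, s, e, strand),
                transcript_id=tid,
                gene_id=gid,
                assembly_label=config.assembly_a_label,
            )
            for s, e in coords
        ]
        order = exons if strand == "+" else exons[::-1]
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid, gene_id=gid, exons=order,
                assembly_label=config.assembly_a_label,
            )
        )
        for gi, (exon, label) in enumerate(zip(exons, labels_genomic)):
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gid,
                    "exon_index": gi,
                    "chrom": chrom,
                    "start": exon.interval.start,
                    "end": exon.interval.end,
                    "strand": strand,
                    "te_overlap": label,
                    "is_first": exon is order[0],
                }
            )
    exon_truth = pd.DataFrame(truth_rows)

    # Assembly B: jittered copies of a shared subset plus novel records.
    n_shared = int(round(config.shared_fraction * config.n_transcripts))
    shared_idx = rng.choice(config.n_transcripts, size=n_shared, replace=False)
    shared_idx.sort()
    transcripts_b: list[TranscriptRecord] = []
    shared_rows = []
    for idx in shared_idx:
        src = transcripts[int(idx)]
        bid = f"b{src.transcript_id}"
        jittered = []
        for e in sorted(src.exons, key=lambda e: e.interval.start):
            ds = int(rng.integers(-config.jitter_max, config.jitter_max + 1))
            de = int(rng.integers(-config.jitter_max, config.jitter_max + 1))
            start = max(0, e.interval.start + ds)
            end = max(start + 1, e.interval.end + de)
            jittered.append(
                ExonRecord(
                    interval=GenomicInterval(e.interval.chrom, start, end, e.interval.strand),
                    transcript_id=bid,
                    gene_id=f"b{src.gene_id}",
                    assembly_label=config.assembly_b_label,
                )
            )
        order = jittered if src.strand == "+" else jittered[::-1]
        transcripts_b.append(
            TranscriptRecord(
                transcript_id=bid, gene_id=f"b{src.gene_id}", exons=order,
                assembly_label=config.assembly_b_label,
            )
        )
        shared_rows.append({"a_id": src.transcript_id, "b_id": bid})

    n_novel = int(round(config.novel_fraction * config.n_transcripts))
    for k in range(n_novel):
        tid, gid = f"bn{k:05d}", f"bgn{k:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = 1 + int(rng.poisson(config.exon_mean_extra))
        labels_tx = [bool(rng.random() < config.rho_first)] + [
            bool(rng.random() < config.rho_later) for _ in range(n_exons - 1)
        ]
        labels_genomic = labels_tx if strand == "+" else labels_tx[::-1]
        placed = None
        for _attempt in range(40):
            result = _place_transcript(
                config, rng, lookup, chrom_names, chrom_lens, probs, labels_genomic
            )
            if result is not None:
                placed = result
                break
        if placed is None:
            raise RuntimeError(f"could not place novel transcript {tid}")
        chrom, coords = placed
        exons = [
            ExonRecord(
                interval=GenomicInterval(chrom, s, e, strand),
                transcript_id=tid,
                gene_id=gid,
                assembly_label=config.assembly_b_label,
            )
            for s, e in coords
        ]
        order = exons if strand == "+" else exons[::-1]
        transcripts_b.append(
            TranscriptRecord(
                transcript_id=tid, gene_id=gid, exons=order,
                assembly_label=config.assembly_b_label,
            )
        )
    shared_truth = pd.DataFrame(shared_rows, columns=["a_id", "b_id"])
    return transcripts, exon_truth, transcripts_b, shared_truth


def simulate_expression(
    config: SyntheticConfig,
    transcripts: Sequence[TranscriptRecord],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Two-condition replicated FPKM per transcript.

    Per-gene baseline log2-FPKM ~ Normal(mu, sigma); replicate noise on
    the log2 scale; a ``de_fraction`` of genes gets a +/- ``de_log2fc``
    shift in group B. FPKM values (2^log2) are attached to the transcript
    records in place and also returned with the truth table.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = sorted({t.gene_id for t in transcripts})
    n_genes = len(genes)
    baseline = rng.normal(config.fpkm_log2_mean, config.fpkm_log2_sd, size=n_genes)
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = set(map(int, rng.choice(n_genes, size=n_de, replace=False)))
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    n = config.n_samples_per_group
    samples_a = [f"A_{i + 1}" for i in range(n)]
    samples_b = [f"B_{i + 1}" for i in range(n)]

    gene_expr: dict[str, dict[str, float]] = {}
    truth_rows = []
    for gi, gene in enumerate(genes):
        is_de = gi in de_idx
        shift = signs[gi] * config.de_log2fc if is_de else 0.0
        values = {}
        for s in samples_a:
            values[s] = float(
                2.0 ** (baseline[gi] + rng.normal(0, config.replicate_log2_sd))
            )
        for s in samples_b:
            values[s] = float(
                2.0 ** (baseline[gi] + shift + rng.normal(0, config.replicate_log2_sd))
            )
        gene_expr[gene] = values
        truth_rows.append(
            {"gene_id": gene, "is_de": is_de, "log2fc": shift}
        )

    fpkm: dict[str, dict[str, float]] = {}
    for t in transcripts:
        values = dict(gene_expr[t.gene_id])
        t.fpkm = values
        fpkm[t.transcript_id] = values
    return fpkm, pd.DataFrame(truth_rows, columns=["gene_id", "is_de", "log2fc"])


def simulate_signal_tracks(
    config: SyntheticConfig,
    transcripts: Sequence[TranscriptRecord],
    rng: np.random.Generator | None = None,
) -> dict[str, list]:
    """Peak features per track: for each exon the expected peak count is
    max(0, a + b*ln(mean FPKM + 1)) plus Gaussian noise, rounded, and that
    many fixed-width peaks are dropped uniformly inside the exon."""
    from .models import SignalFeature

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out: dict[str, list] = {}
    for track in sorted(config.tracks):
        params = config.tracks[track]
        feats = []
        for t in transcripts:
            x = math.log(t.mean_fpkm() + 1.0)
            for e in t.exons:
                lam = max(0.0, params.intercept + params.slope * x)
                lam += rng.normal(0.0, params.noise_sd)
                k = max(0, int(round(lam)))
                iv = e.interval
                width = min(config.peak_width, iv.length)
                for _ in range(k):
                    start = int(rng.integers(iv.start, iv.end - width + 1))
                    feats.append(
                        SignalFeature(
                            interval=GenomicInterval(iv.chrom, start, start + width),
                            track=track,
                        )
                    )
        feats.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end))
        out[track] = feats
    return out


def simulate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Run the whole generator with one seeded RNG (landscape ->
    transcriptome -> expression -> signals)."""
    config = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    tes = simulate_te_landscape(config, rng)
    transcripts_a, exon_truth, transcripts_b, shared_truth = simulate_transcriptome(
        config, tes, rng
    )
    fpkm, de_truth = simulate_expression(config, transcripts_a, rng)
    signals = simulate_signal_tracks(config, transcripts_a, rng)
    return SyntheticBundle(
        config=config,
        tes=tes,
        transcripts_a=transcripts_a,
        transcripts_b=transcripts_b,
        exon_truth=exon_truth,
        de_truth=de_truth,
        shared_truth=shared_truth,
        fpkm=fpkm,
        signals=signals,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the file formats the pipeline consumes:
    te.bed (rmsk-bed dialect), assembly_a.gtf, assembly_b.gtf, fpkm.tsv,
    signals/<track>.bed, truth/*.tsv. Deterministic byte-for-byte given
    the same bundle."""
    out_dir = Path(out_dir)
    (out_dir / "signals").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["te"] = out_dir / "te.bed"
    annotation_io.write_repeatmasker_bed(bundle.tes, paths["te"])
    paths["assembly_a"] = out_dir / "assembly_a.gtf"
    annotation_io.write_gtf(bundle.transcripts_a, paths["assembly_a"])
    paths["assembly_b"] = out_dir / "assembly_b.gtf"
    annotation_io.write_gtf(bundle.transcripts_b, paths["assembly_b"])
    paths["fpkm"] = out_dir / "fpkm.tsv"
    annotation_io.write_fpkm_tsv(bundle.fpkm, paths["fpkm"])
    for track, feats in bundle.signals.items():
        p = out_dir / "signals" / f"{track}.bed"
        annotation_io.write_bed_features(feats, p)
        paths[f"signal:{track}"] = p
    for name, df in (
        ("exon_labels", bundle.exon_truth),
        ("de_genes", bundle.de_truth),
        ("shared", bundle.shared_truth),
    ):
        p = out_dir / "truth" / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth:{name}"] = p
    return paths
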