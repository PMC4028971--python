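"""End-to-end orchestration: classify -> compare -> families -> episignal
-> diffexp from one run configuration, with per-stage TSV outputs and a
machine-readable JSON summary.

Every stage is a pure function of its inputs and the configuration: the
summary from a rerun on the same inputs is identical. Stage failures abort
the run with the stage name; outputs written so far are retained alongside
a FAILED marker file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_io, classify, compare, diffexp, episignal, families
from .intervals import build_index

logger = logging.getLogger("te_exonize")

DEFAULT_WIGGLE = 10
DEFAULT_NBINS = 100
DEFAULT_ALPHA = 0.05


@dataclass
class RunConfig:
    """Inputs and parameters for one full run. Defaults carry the study
    constants: 10 bp wiggle, 100 expression bins, q < 0.05."""

    gtf_a: str
    te: str
    out_dir: str
    gtf_b: str | None = None
    fpkm: str | None = None
    te_dialect: str = "bed"
    signals: dict[str, str] = field(default_factory=dict)  # track -> BED path
    groups: dict[str, list[str]] = field(default_factory=dict)
    wiggle: int = DEFAULT_WIGGLE
    nbins: int = DEFAULT_NBINS
    alpha: float = DEFAULT_ALPHA
    abundance_mode: str = "elements"
    signal_mode: str = "count"
    flank: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [
            ("gtf_a", self.gtf_a),
            ("te", self.te),
            ("gtf_b", self.gtf_b),
            ("fpkm", self.fpkm),
            *[(f"signal {t}", p) for t, p in self.signals.items()],
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} input does not exist: {p}")
        if self.wiggle < 0:
            raise ValueError("wiggle must be >= 0")
        if self.nbins < 1:
            raise ValueError("nbins must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fractions_table(result) -> pd.DataFrame:
    rows = []
    for universe in classify.UNIVERSES:
        summary = classify.fraction_te_derived(result, universe)
        rows.append(
            {
                "label": summary.label,
                "numerator": summary.numerator,
                "denominator": summary.denominator,
                "percent": summary.percent,
                "percent_reported": summary.percent_reported,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute all applicable stages in dependency order and return the
    summary dict (also written to ``summary.json``)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {"parameters": {
        "wiggle": config.wiggle, "nbins": config.nbins, "alpha": config.alpha,
        "abundance_mode": config.abundance_mode, "signal_mode": config.signal_mode,
        "flank": config.flank,
    }}
    stage = "load"
    try:
        t0 = time.monotonic()
        transcripts_a = annotation_io.read_gtf(
            config.gtf_a, assembly_label="A", fpkm_path=config.fpkm
        )
        tes = annotation_io.read_repeatmasker(config.te, dialect=config.te_dialect)
        logger.info(
            "load: %d transcripts, %d TEs (%.2fs)",
            len(transcripts_a), len(tes), time.monotonic() - t0,
        )

        stage = "classify"
        t0 = time.monotonic()
        te_index = classify.build_te_index(tes)
        result_a = classify.classify_transcriptome(transcripts_a, te_index)
        fractions = _fractions_table(result_a)
        annotation_io.write_table(fractions, out_dir / "fractions.tsv")
        exon_flags = pd.DataFrame(
            {
                "chrom": [c.exon.interval.chrom for c in result_a.exon_calls],
                "start": [c.exon.interval.start for c in result_a.exon_calls],
                "end": [c.exon.interval.end for c in result_a.exon_calls],
                "transcript_id": [c.exon.transcript_id for c in result_a.exon_calls],
                "te_derived": [int(c.te_derived) for c in result_a.exon_calls],
                "strand": [c.exon.interval.strand for c in result_a.exon_calls],
            }
        )
        exon_flags.to_csv(
            out_dir / "exon_flags.bed", sep="\t", index=False, header=False
        )
        summary["fractions"] = fractions.to_dict(orient="records")
        logger.info("classify: %s (%.2fs)", summary["fractions"], time.monotonic() - t0)

        if config.gtf_b:
            stage = "compare"
            t0 = time.monotonic()
            transcripts_b = annotation_io.read_gtf(config.gtf_b, assembly_label="B")
            result_b = classify.classify_transcriptome(transcripts_b, te_index)
            items_a = compare.items_from_transcripts(transcripts_a)
            items_b = compare.items_from_transcripts(transcripts_b)
            match = compare.match_records(items_a, items_b, wiggle=config.wiggle)
            venn = compare.venn_counts(
                match, result_a.transcript_te_derived, result_b.transcript_te_derived
            )
            pairs = pd.DataFrame(
                [
                    {"a_id": a.record_id, "b_id": b.record_id, "distance": d}
                    for a, b, d in match.pairs
                ],
                columns=["a_id", "b_id", "distance"],
            )
            annotation_io.write_table(pairs, out_dir / "match_pairs.tsv")
            annotation_io.write_table([venn], out_dir / "venn_counts.tsv")
            summary["venn"] = vars(venn)
            logger.info("compare: %s (%.2fs)", summary["venn"], time.monotonic() - t0)

        stage = "families"
        t0 = time.monotonic()
        hits = families.attribute_hits(result_a)
        abundance = families.genomic_abundance(tes, mode=config.abundance_mode)
        millidivs = families.mean_millidiv(tes)
        contributions = families.normalize_contribution(hits, abundance, millidivs)
        chi = families.chi_square_families(hits, abundance)
        annotation_io.write_table(contributions, out_dir / "family_contribution.tsv")
        annotation_io.write_table([chi], out_dir / "family_chi_square.tsv")
        summary["family_age_order"] = families.age_rank(tes)
        summary["family_chi_square"] = vars(chi)
        logger.info(
            "families: chi2=%.1f p=%.3g (%.2fs)",
            chi.statistic, chi.p, time.monotonic() - t0,
        )

        if config.signals:
            stage = "episignal"
            t0 = time.monotonic()
            fpkm_by_tid = {t.transcript_id: t.mean_fpkm() for t in transcripts_a}
            te_exons = [
                (c.exon, fpkm_by_tid.get(c.exon.transcript_id, 0.0))
                for c in result_a.exon_calls
                if c.te_derived
            ]
            signal_indexes = {
                track: build_index(
                    (f.interval, f)
                    for f in annotation_io.read_bed_features(path, track)
                )
                for track, path in config.signals.items()
            }
            bins = episignal.bin_by_expression(te_exons, nbins=config.nbins)
            profiles = episignal.bin_profile(
                bins, signal_indexes, mode=config.signal_mode, flank=config.flank
            )
            profile_rows = [
                {
                    "bin_index": p.bin_index,
                    "n_exons": p.n_exons,
                    "mean_fpkm": p.mean_fpkm,
                    "track": track,
                    "mean_signal": p.mean_signal[track],
                }
                for p in profiles
                for track in sorted(signal_indexes)
            ]
            annotation_io.write_table(
                pd.DataFrame(profile_rows), out_dir / "bin_profiles.tsv"
            )
            correlations = {
                track: episignal.correlate_profile(profiles, track)
                for track in sorted(signal_indexes)
            }
            annotation_io.write_table(
                pd.DataFrame(
                    [
                        {"track": track, "r": c.r, "n": c.n, "t": c.t, "p": c.p}
                        for track, c in correlations.items()
                    ]
                ),
                out_dir / "correlations.tsv",
            )
            summary["correlations"] = {
                track: {"r": c.r, "n": c.n, "t": c.t, "p": c.p}
                for track, c in correlations.items()
            }
            logger.info(
                "episignal: %d TE exons, %d tracks (%.2fs)",
                len(te_exons), len(signal_indexes), time.monotonic() - t0,
            )

        if config.groups:
            stage = "diffexp"
            t0 = time.monotonic()
            expr = diffexp.gene_expression_table(transcripts_a)
            de = diffexp.run_diffexp(
                expr, config.groups, alpha=config.alpha
            )
            gene_flags = _gene_first_exon_flags(transcripts_a, result_a)
            de_te = diffexp.de_te_first_exon_genes(de, gene_flags, alpha=config.alpha)
            annotation_io.write_table(de, out_dir / "diffexp.tsv")
            annotation_io.write_table(de_te, out_dir / "de_te_first_exon_genes.tsv")
            summary["diffexp"] = {
                "n_tested": int(len(de)),
                "n_significant": int(de["significant"].sum()),
                "n_de_te_first_exon": int(len(de_te)),
            }
            logger.info("diffexp: %s (%.2fs)", summary["diffexp"], time.monotonic() - t0)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _gene_first_exon_flags(transcripts, result) -> dict[str, bool]:
    """A gene carries a TE-derived first exon when any of its transcripts
    does."""
    flags: dict[str, bool] = {}
    for t in transcripts:
        flag = result.transcript_te_first_exon[t.transcript_id]
        flags[t.gene_id] = flags.get(t.gene_id, False) or flag
    return flags
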