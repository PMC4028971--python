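"""Readers and writers for the genomic file formats the pipeline touches.

Supported inputs: GTF gene models (exon features), RepeatMasker ``.out``
files and rmsk-style BED repeat tables, BED peak/cluster tracks, and a
sidecar FPKM TSV. All coordinates are normalized to 0-based half-open on
read; GTF is converted back to 1-based closed on write.

The parsers are line-oriented and report the offending line number on
malformed input — assembler and annotation dumps fail in practice on a
single bad row, and "column 5 of line 1234" beats a stack trace. No
installed library parses RepeatMasker ``.out``, and library GTF readers do
not surface line-level diagnostics, so these small format readers live
here.
"""

from __future__ import annotations

import dataclasses
import re
from collections import OrderedDict
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from .models import (
    ExonRecord,
    GenomicInterval,
    SignalFeature,
    TEAnnotation,
    TranscriptRecord,
)


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


_ATTR_RE = re.compile(r'([^;\s"]+)\s+"([^"]*)"|([^;\s"]+)\s+([^;\s"]+)')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(field):
        if m.group(1) is not None:
            attrs[m.group(1)] = m.group(2)
        else:
            attrs[m.group(3)] = m.group(4)
    return attrs


def read_gtf(
    path: str | Path,
    assembly_label: str = "",
    fpkm_path: str | Path | None = None,
) -> list[TranscriptRecord]:
    """Parse exon features from a GTF file into transcripts.

    GTF 1-based closed coordinates become 0-based half-open (start-1, end).
    Exons are returned in transcription order: ascending start on ``+``,
    descending start on ``-``. Non-exon feature lines are ignored.
    Unstranded exons are rejected (first-exon calling needs strand).

    Expression is attached from ``fpkm_path`` (TSV: transcript_id, sample,
    fpkm) when given, else from a per-line ``FPKM`` attribute if present.
    """
    path = Path(path)
    exons_by_tid: "OrderedDict[str, list[ExonRecord]]" = OrderedDict()
    gene_by_tid: dict[str, str] = {}
    fpkm_attr: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 9 tab-delimited "
                    f"columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if end1 < start1:
                raise ParseError(
                    f"{path.name} line {lineno}: end {end1} < start {start1}"
                )
            attrs = _parse_gtf_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(
                    f"{path.name} line {lineno}: missing transcript_id attribute"
                )
            gid = attrs.get("gene_id", tid)
            try:
                exon = ExonRecord(
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                    transcript_id=tid,
                    gene_id=gid,
                    assembly_label=assembly_label,
                )
            except ValueError as exc:
                raise ParseError(f"{path.name} line {lineno}: {exc}") from None
            exons_by_tid.setdefault(tid, []).append(exon)
            gene_by_tid[tid] = gid
            if "FPKM" in attrs:
                fpkm_attr.setdefault(tid, {})["FPKM"] = float(attrs["FPKM"])

    fpkm = read_fpkm_tsv(fpkm_path) if fpkm_path is not None else fpkm_attr
    transcripts = []
    for tid, exons in exons_by_tid.items():
        strand = exons[0].interval.strand
        exons.sort(
            key=lambda e: e.interval.start, reverse=(strand == "-")
        )
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene_by_tid[tid],
                exons=exons,
                fpkm=dict(fpkm.get(tid, {})),
                assembly_label=assembly_label,
            )
        )
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts as GTF exon features (1-based closed coordinates).

    Rows are ordered by (chrom, span start, transcript_id), exons within a
    transcript by ascending start, so output is deterministic.
    """
    transcripts = sorted(
        transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id)
    )
    with open(path, "w") as fh:
        for t in transcripts:
            for e in sorted(t.exons, key=lambda e: e.interval.start):
                iv = e.interval
                fh.write(
                    f"{iv.chrom}\tte_exonize\texon\t{iv.start + 1}\t{iv.end}\t"
                    f".\t{iv.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n'
                )


def read_fpkm_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a sidecar expression table (columns: transcript_id, sample,
    fpkm) into ``{transcript_id: {sample: fpkm}}``."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "sample", "fpkm"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"FPKM table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    out: dict[str, dict[str, float]] = {}
    for tid, sample, value in zip(df["transcript_id"], df["sample"], df["fpkm"]):
        if value < 0:
            raise ParseError(f"negative FPKM for transcript {tid}")
        out.setdefault(str(tid), {})[str(sample)] = float(value)
    return out


def write_fpkm_tsv(
    fpkm: dict[str, dict[str, float]], path: str | Path
) -> None:
    rows = [
        {"transcript_id": tid, "sample": sample, "fpkm": value}
        for tid in sorted(fpkm)
        for sample, value in sorted(fpkm[tid].items())
    ]
    pd.DataFrame(rows, columns=["transcript_id", "sample", "fpkm"]).to_csv(
        path, sep="\t", index=False
    )


# RepeatMasker .out columns (whitespace-delimited, after 3 header lines):
# score perc_div perc_del perc_ins query q_begin q_end q_left strand
# repeat class/family r_begin r_end r_left id
def read_repeatmasker(
    path: str | Path, dialect: str = "out"
) -> list[TEAnnotation]:
    """Read repeat annotations from a RepeatMasker ``.out`` file or an
    rmsk-style BED.

    ``out`` dialect: 1-based closed query coordinates are converted; the
    percent-divergence column is stored per-mille (x10). ``bed`` dialect:
    tab-delimited chrom, start, end, name, millidiv, strand, class/family
    with native 0-based half-open coordinates. The two encodings of the
    same repeat yield identical :class:`TEAnnotation` values.
    """
    if dialect not in ("out", "bed"):
        raise ValueError(f"unknown RepeatMasker dialect {dialect!r}")
    path = Path(path)
    tes: list[TEAnnotation] = []
    with open(path) as fh:
        if dialect == "out":
            for lineno, raw in enumerate(fh, start=1):
                fields = raw.split()
                if not fields or not fields[0].lstrip("-").isdigit():
                    continue  # header / blank lines
                if len(fields) < 11:
                    raise ParseError(
                        f"{path.name} line {lineno}: expected >= 11 fields, "
                        f"got {len(fields)}"
                    )
                perc_div = float(fields[1])
                if perc_div < 0:
                    raise ParseError(
                        f"{path.name} line {lineno}: negative divergence"
                    )
                chrom, begin1, end1 = fields[4], int(fields[5]), int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                tes.append(
                    TEAnnotation(
                        interval=GenomicInterval(chrom, begin1 - 1, end1, strand),
                        name=fields[9],
                        raw_class=fields[10],
                        millidiv=perc_div * 10.0,
                    )
                )
        else:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 7:
                    raise ParseError(
                        f"{path.name} line {lineno}: expected 7 tab-delimited "
                        f"columns, got {len(fields)}"
                    )
                millidiv = float(fields[4])
                if millidiv < 0:
                    raise ParseError(
                        f"{path.name} line {lineno}: negative divergence"
                    )
                tes.append(
                    TEAnnotation(
                        interval=GenomicInterval(
                            fields[0], int(fields[1]), int(fields[2]), fields[5]
                        ),
                        name=fields[3],
                        raw_class=fields[6],
                        millidiv=millidiv,
                    )
                )
    return tes


def write_repeatmasker_bed(
    tes: Iterable[TEAnnotation], path: str | Path
) -> None:
    """Write repeats in the rmsk-style BED dialect, sorted by coordinates."""
    tes = sorted(tes, key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end, t.name))
    with open(path, "w") as fh:
        for t in tes:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.name}\t"
                f"{t.millidiv:g}\t{iv.strand}\t{t.raw_class}\n"
            )


def read_bed_features(path: str | Path, track: str) -> list[SignalFeature]:
    """Read a BED3+/BED5 peak or cluster file as signal features for one
    track. BED is natively 0-based half-open; score comes from column 5
    when present."""
    path = Path(path)
    feats: list[SignalFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name} line {lineno}: expected >= 3 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from None
            if end <= start:
                raise ParseError(
                    f"{path.name} line {lineno}: end {end} <= start {start}"
                )
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                score = float(fields[4])
            strand = fields[5] if len(fields) >= 6 else "."
            feats.append(
                SignalFeature(
                    interval=GenomicInterval(fields[0], start, end, strand),
                    track=track,
                    score=score,
                )
            )
    return feats


def write_bed_features(
    feats: Iterable[SignalFeature], path: str | Path
) -> None:
    feats = sorted(
        feats, key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end)
    )
    with open(path, "w") as fh:
        for i, f in enumerate(feats):
            iv = f.interval
            score = f.score if f.score is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.track}_{i}\t{score:g}\t"
                f"{iv.strand}\n"
            )


def _record_to_row(record: Any) -> dict[str, Any]:
    if isinstance(record, dict):
        return record
    if dataclasses.is_dataclass(record):
        row: dict[str, Any] = {}
        for f in dataclasses.fields(record):
            value = getattr(record, f.name)
            if isinstance(value, GenomicInterval):
                row.update(
                    chrom=value.chrom, start=value.start, end=value.end,
                    strand=value.strand,
                )
            else:
                row[f.name] = value
        # surface computed percent fields alongside raw counts
        for extra in ("percent", "percent_reported"):
            if hasattr(record, extra):
                row[extra] = getattr(record, extra)
        return row
    raise TypeError(f"cannot tabulate record of type {type(record)!r}")


def write_table(
    records: Any,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write results as a UTF-8 TSV with a header row.

    Accepts a DataFrame or an iterable of dataclasses/dicts. Rows keep
    their input order (callers are responsible for a documented sort key);
    an empty input with explicit ``columns`` produces a header-only file.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [_record_to_row(r) for r in records]
        df = pd.DataFrame(rows, columns=columns if not rows else None)
    df.to_csv(path, sep="\t", index=False)
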