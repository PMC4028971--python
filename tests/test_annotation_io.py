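"""GTF/RepeatMasker/BED parsing: coordinate conventions, strand ordering,
dialect equivalence, error reporting, and round-trips."""

import pytest

from te_exonize import annotation_io as aio
from te_exonize.models import GenomicInterval, family_group_of


GTF_LINE = 'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'


def test_gtf_coordinates_become_zero_based_half_open(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(GTF_LINE)
    (t,) = aio.read_gtf(p)
    e = t.exons[0].interval
    assert (e.chrom, e.start, e.end, e.strand) == ("chr1", 100, 200, "+")
    assert e.length == 200 - 101 + 1  # GTF closed-interval length preserved


def test_gtf_minus_strand_exons_in_transcription_order(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        'chr1\ts\texon\t301\t400\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\ts\texon\t101\t200\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
    )
    (t,) = aio.read_gtf(p)
    assert t.exons[0].interval.end == 400  # 5'-most exon listed first
    assert t.exons[1].interval.end == 200


def test_gtf_empty_file_and_non_exon_lines(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text("")
    assert aio.read_gtf(p) == []
    p.write_text(
        'chr1\ts\tCDS\t1\t9\t.\t+\t.\tgene_id "g"; transcript_id "t";\n' + GTF_LINE
    )
    assert len(aio.read_gtf(p)) == 1


@pytest.mark.parametrize(
    "line,fragment",
    [
        ("chr1\tsrc\texon\t101\t200\t.\t+\t.\n", "9 tab-delimited"),
        ('chr1\ts\texon\tx\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n', "non-integer"),
        ('chr1\ts\texon\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n', "end"),
        ('chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n', "transcript_id"),
        ('chr1\ts\texon\t101\t200\t.\t.\t.\tgene_id "g"; transcript_id "t";\n', "strand"),
    ],
)
def test_gtf_malformed_lines_name_the_line(tmp_path, line, fragment):
    p = tmp_path / "bad.gtf"
    p.write_text(line)
    with pytest.raises(aio.ParseError, match="line 1"):
        aio.read_gtf(p)
    with pytest.raises(aio.ParseError, match=fragment):
        aio.read_gtf(p)


def test_gtf_fpkm_attribute_fallback(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        'chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t"; FPKM "3.5";\n'
    )
    (t,) = aio.read_gtf(p)
    assert t.fpkm == {"FPKM": 3.5}


def test_gtf_round_trip_preserves_coordinates_and_ids(tmp_path, small_bundle):
    out = tmp_path / "rt.gtf"
    aio.write_gtf(small_bundle.transcripts_a, out)
    back = aio.read_gtf(out)
    orig = {t.transcript_id: t for t in small_bundle.transcripts_a}
    assert len(back) == len(orig)
    for t in back:
        src = orig[t.transcript_id]
        assert t.gene_id == src.gene_id
        assert [
            (e.interval.start, e.interval.end) for e in t.exons
        ] == [(e.interval.start, e.interval.end) for e in src.exons]


OUT_HEADER = (
    "   SW  perc perc perc  query      position in query    matching repeat\n"
    "score  div. del. ins.  sequence   begin end   (left)   repeat class/family\n"
    "\n"
)


def test_repeatmasker_out_dialect_unit_conversion(tmp_path):
    p = tmp_path / "rm.out"
    p.write_text(
        OUT_HEADER
        + " 1500  8.5  0.1  0.2  chr1  101  400  (5000)  +  AluSx  SINE/Alu  1  300  (0)  1\n"
    )
    (te,) = aio.read_repeatmasker(p, dialect="out")
    assert te.millidiv == 85.0  # percent divergence x 10
    assert te.family_group == "Alu"
    assert (te.interval.start, te.interval.end) == (100, 400)


def test_repeatmasker_dialect_equivalence(tmp_path):
    out_p = tmp_path / "rm.out"
    out_p.write_text(
        OUT_HEADER
        + " 1500  8.5  0.1  0.2  chr1  101  400  (5000)  C  AluSx  SINE/Alu  1  300  (0)  1\n"
    )
    bed_p = tmp_path / "rm.bed"
    bed_p.write_text("chr1\t100\t400\tAluSx\t85\t-\tSINE/Alu\n")
    (a,) = aio.read_repeatmasker(out_p, dialect="out")
    (b,) = aio.read_repeatmasker(bed_p, dialect="bed")
    assert a == b


@pytest.mark.parametrize(
    "raw_class,family",
    [
        ("SINE/Alu", "Alu"), ("SINE/MIR", "MIR"), ("LINE/L1", "L1"),
        ("LINE/L2", "L2"), ("LTR/ERVL-MaLR", "LTR"), ("DNA/hAT", "DNA"),
        ("Satellite", "other"), ("Simple_repeat", "other"), ("SINE/tRNA", "other"),
    ],
)
def test_family_prefix_mapping(raw_class, family):
    assert family_group_of(raw_class) == family


def test_repeatmasker_errors(tmp_path):
    p = tmp_path / "rm.bed"
    p.write_text("chr1\t100\t400\tAluSx\t-5\t-\tSINE/Alu\n")
    with pytest.raises(aio.ParseError, match="negative divergence"):
        aio.read_repeatmasker(p, dialect="bed")
    with pytest.raises(ValueError, match="dialect"):
        aio.read_repeatmasker(p, dialect="gff")


def test_bed_features_score_and_errors(tmp_path):
    p = tmp_path / "p.bed"
    p.write_text("chr1\t150\t160\tp1\t7\nchr2\t5\t9\n")
    feats = aio.read_bed_features(p, track="DHS")
    assert feats[0].score == 7
    assert feats[0].interval == GenomicInterval("chr1", 150, 160)
    assert feats[1].score is None
    p.write_text("chr1\t160\t150\n")
    with pytest.raises(aio.ParseError, match="line 1"):
        aio.read_bed_features(p, track="DHS")


def test_write_table_shapes(tmp_path):
    from te_exonize.models import FractionSummary

    p = tmp_path / "t.tsv"
    aio.write_table([FractionSummary("all_exons", 1, 4)], p)
    header, row = p.read_text().strip().split("\n")
    assert header.split("\t") == [
        "label", "numerator", "denominator", "percent", "percent_reported"
    ]
    assert row.split("\t")[3] == "25.0"
    aio.write_table([], p, columns=["a", "b"])
    assert p.read_text() == "a\tb\n"
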