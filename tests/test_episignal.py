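"""Expression binning, per-exon signal aggregation, and the Pearson/t
trend machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from te_exonize.episignal import (
    bin_by_expression,
    bin_profile,
    correlate_profile,
    pearson_r,
    pearson_t,
    signal_per_exon,
)
from te_exonize.intervals import build_index
from te_exonize.models import ExonRecord, GenomicInterval, SignalFeature


def exon(start, end, tid="t1"):
    return ExonRecord(GenomicInterval("chr1", start, end, "+"), tid, "g1")


def peak(start, end, track="DHS", score=None):
    return SignalFeature(GenomicInterval("chr1", start, end), track, score)


def index_of(feats):
    return build_index((f.interval, f) for f in feats)


def make_items(n):
    return [(exon(i * 1000, i * 1000 + 100, f"t{i}"), float(i)) for i in range(n)]


def test_equal_count_binning_remainder_rule():
    sizes = [len(b) for b in bin_by_expression(make_items(1000), 100)]
    assert sizes == [10] * 100
    sizes = [len(b) for b in bin_by_expression(make_items(105), 100)]
    assert sizes == [2] * 5 + [1] * 95
    assert len(bin_by_expression(make_items(10), 1)[0]) == 10


def test_binning_sorted_ascending_and_conserves():
    items = make_items(50)[::-1]
    bins = bin_by_expression(items, 10)
    assert sum(len(b) for b in bins) == 50
    flat = [f for b in bins for _, f in b]
    assert flat == sorted(flat)
    with pytest.raises(ValueError, match="bins"):
        bin_by_expression(make_items(5), 10)


def test_signal_modes():
    idx = index_of([peak(150, 160, score=7), peak(250, 300, score=3)])
    e = exon(100, 200)
    assert signal_per_exon(e, idx, "count") == 1
    assert signal_per_exon(e, idx, "bp") == 10
    assert signal_per_exon(e, idx, "score") == 7
    assert signal_per_exon(exon(5000, 5100), idx, "count") == 0
    assert signal_per_exon(e, idx, "count", flank=60) == 2  # flank reaches 250


def test_score_mode_requires_scores():
    idx = index_of([peak(150, 160)])
    with pytest.raises(ValueError, match="score"):
        signal_per_exon(exon(100, 200), idx, "score")


def test_bin_profile_means():
    items = [(exon(0, 100, "t0"), 1.0), (exon(1000, 1100, "t1"), 3.0)]
    idx = index_of([peak(0, 50), peak(10, 60)])  # 2 peaks on first exon only
    (profile,) = bin_profile([items], {"DHS": idx})
    assert profile.mean_fpkm == 2.0
    assert profile.mean_signal["DHS"] == 1.0  # (2 + 0) / 2


def test_pearson_r_known_values():
    assert pearson_r([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
    # hand-computed: cov=1.25, sd_x*sd_y=1.25*... -> r=0.6
    assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)
    with pytest.raises(ValueError, match="variance"):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError, match="3 points"):
        pearson_r([1, 2], [1, 2])


def test_pearson_t_identities():
    res = pearson_t(0.6, 27)
    assert res.t == pytest.approx(3.75, rel=1e-12)  # 0.6*5/0.8
    assert res.df == 25
    neg = pearson_t(-0.6, 27)
    assert neg.t == pytest.approx(-3.75, rel=1e-12)
    assert neg.p == pytest.approx(res.p)
    for n in (3, 10, 100):
        null = pearson_t(0.0, n)
        assert null.t == 0.0 and null.p == 1.0
    with pytest.raises(ValueError):
        pearson_t(1.0, 10)
    with pytest.raises(ValueError):
        pearson_t(0.5, 2)


def test_pearson_t_monotone_in_r_and_n():
    ts = [pearson_t(r, 30).t for r in (-0.9, -0.5, 0.0, 0.5, 0.9)]
    assert ts == sorted(ts)
    ts_n = [pearson_t(0.5, n).t for n in (5, 10, 50, 500)]
    assert ts_n == sorted(ts_n)


@settings(derandomize=True, max_examples=100)
@given(
    ab=st.tuples(
        st.floats(0.1, 10), st.floats(-5, 5), st.floats(0.1, 10), st.floats(-5, 5)
    )
)
def test_pearson_affine_invariance(ab):
    a1, b1, a2, b2 = ab
    x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
    y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    base = pearson_r(x, y)
    assert pearson_r(a1 * x + b1, a2 * y + b2) == pytest.approx(base, abs=1e-9)
    assert pearson_r(-x, y) == pytest.approx(-base, abs=1e-9)


def test_planted_positive_trend_recovered(small_bundle):
    """With planted slope b > 0, the binned profile rises with expression:
    bin means correlate with bin index (Spearman > 0.9) and the trend is
    highly significant."""
    from scipy import stats as ss

    from te_exonize.classify import build_te_index, classify_transcriptome

    idx = build_te_index(small_bundle.tes)
    result = classify_transcriptome(small_bundle.transcripts_a, idx)
    fpkm = {t.transcript_id: t.mean_fpkm() for t in small_bundle.transcripts_a}
    te_exons = [
        (c.exon, fpkm[c.exon.transcript_id])
        for c in result.exon_calls if c.te_derived
    ]
    bins = bin_by_expression(te_exons, nbins=50)
    track = "H3K4me3"
    sig_idx = index_of(small_bundle.signals[track])
    profiles = bin_profile(bins, {track: sig_idx})
    means = [p.mean_signal[track] for p in profiles]
    rho = ss.spearmanr(range(len(means)), means).statistic
    assert rho > 0.9
    corr = correlate_profile(profiles, track)
    assert corr.r > 0 and corr.p < 0.01
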