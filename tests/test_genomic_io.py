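"""Parsers, writers, round-trips, and rpm normalization."""

from __future__ import annotations

import numpy as np
import pytest

from enhancerscope.genomic_io import (
    DegenerateTrackError,
    EnhancerRegion,
    ExpressionRecord,
    FormatError,
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    ValidationError,
    parse_bed,
    parse_bedgraph,
    parse_enhancers,
    parse_expression,
    parse_gene_table,
    parse_narrowpeak,
    to_rpm,
    write_bed,
    write_bedgraph,
    write_enhancers,
    write_expression,
    write_gene_table,
    write_narrowpeak,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def test_interval_rejects_empty_and_negative():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 100, 50)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", -1, 50)


def test_peak_summit_must_lie_inside_interval():
    iv = GenomicInterval("chr1", 100, 200)
    Peak(iv, 100, 1.0, "p", "F")  # boundary start ok
    Peak(iv, 199, 1.0, "p", "F")  # last base ok
    with pytest.raises(ValidationError):
        Peak(iv, 200, 1.0, "p", "F")


def test_gene_model_strand_orientation():
    GeneModel("g", "chr1", "+", 100, 500)
    GeneModel("g", "chr1", "-", 500, 100)
    with pytest.raises(ValidationError):
        GeneModel("g", "chr1", "-", 100, 500)
    with pytest.raises(ValidationError):
        GeneModel("g", "chr1", ".", 100, 500)


def test_enhancer_class_restricted():
    iv = GenomicInterval("chr1", 0, 100)
    with pytest.raises(ValidationError):
        EnhancerRegion(iv, "superduper", "e1")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def _np_line(chrom="chr1", start=100, end=400, name="p1", offset=50):
    return f"{chrom}\t{start}\t{end}\t{name}\t0\t.\t5.5\t-1\t-1\t{offset}"


def test_parse_narrowpeak_summit_from_offset(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text(_np_line(offset=50) + "\n")
    peaks = parse_narrowpeak(p, "Ctr9")
    assert len(peaks) == 1
    assert peaks[0].summit == 150
    assert peaks[0].factor == "Ctr9"
    assert peaks[0].score == 5.5


def test_parse_narrowpeak_missing_summit_uses_midpoint(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text(_np_line(start=100, end=401, offset=-1) + "\n")
    (peak,) = parse_narrowpeak(p, "F")
    assert peak.summit == 100 + 301 // 2


def test_parse_narrowpeak_reports_bad_line_number(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text(_np_line() + "\nchr1\t1\t2\n")
    with pytest.raises(FormatError, match=":2:"):
        parse_narrowpeak(p, "F")


def test_parse_narrowpeak_rejects_offset_outside_interval(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text(_np_line(start=100, end=200, offset=100) + "\n")
    with pytest.raises(ValidationError):
        parse_narrowpeak(p, "F")


def test_narrowpeak_round_trip(tmp_path):
    peaks = [
        Peak(GenomicInterval("chr2", 50, 350), 120, 3.0, "b", "F"),
        Peak(GenomicInterval("chr1", 10, 400), 55, 1.25, "a", "F"),
    ]
    p1, p2 = tmp_path / "w1", tmp_path / "w2"
    write_narrowpeak(peaks, p1)
    write_narrowpeak(parse_narrowpeak(p1, "F"), p2)
    assert p1.read_bytes() == p2.read_bytes()
    reread = parse_narrowpeak(p2, "F")
    assert [(q.chrom, q.interval.start, q.summit, q.score) for q in reread] == [
        ("chr1", 10, 55, 1.25),
        ("chr2", 50, 120, 3.0),
    ]


# ---------------------------------------------------------------------------
# BED / enhancers
# ---------------------------------------------------------------------------

def test_parse_bed_minimal_and_strand(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t20\nchr1\t30\t40\tx\t0\t-\n")
    ivs = parse_bed(p)
    assert ivs[0] == GenomicInterval("chr1", 10, 20)
    assert ivs[1].strand == "-"


def test_parse_bed_rejects_inverted(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t20\t10\n")
    with pytest.raises(ValidationError, match=":1:"):
        parse_bed(p)


def test_enhancer_round_trip_with_targets(tmp_path):
    regions = [
        EnhancerRegion(GenomicInterval("chr1", 100, 10100), "SE", "SE_0", ("G_1", "G_2")),
        EnhancerRegion(GenomicInterval("chr1", 20000, 21000), "TE", "TE_0"),
    ]
    p1, p2 = tmp_path / "e1.bed", tmp_path / "e2.bed"
    write_enhancers(regions, p1)
    back = parse_enhancers(p1)
    assert back == regions
    write_enhancers(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_parse_enhancers_rejects_unknown_class(tmp_path):
    p = tmp_path / "e.bed"
    p.write_text("chr1\t0\t100\tXX\te1\t.\n")
    with pytest.raises(ValidationError):
        parse_enhancers(p)


# ---------------------------------------------------------------------------
# gene table (1-based on disk)
# ---------------------------------------------------------------------------

def test_gene_table_converts_one_based(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("gene_id\tchrom\tstrand\ttss\ttes\nG1\tchr1\t+\t1001\t2001\n")
    (g,) = parse_gene_table(p)
    assert (g.tss, g.tes) == (1000, 2000)


def test_gene_table_round_trip(tmp_path):
    genes = [
        GeneModel("G2", "chr1", "-", 900, 100),
        GeneModel("G1", "chr1", "+", 0, 500),
    ]
    p1, p2 = tmp_path / "g1.tsv", tmp_path / "g2.tsv"
    write_gene_table(genes, p1)
    back = parse_gene_table(p1)
    assert sorted(back, key=lambda g: g.gene_id) == sorted(genes, key=lambda g: g.gene_id)
    write_gene_table(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_gene_table_requires_header(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("G1\tchr1\t+\t1001\t2001\n")
    with pytest.raises(FormatError, match="header"):
        parse_gene_table(p)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_round_trip(tmp_path):
    records = [
        ExpressionRecord("G1", 10.0, 5.0, None, "SE"),
        ExpressionRecord("G2", 0.0, 0.0, None, "other"),
    ]
    p1, p2 = tmp_path / "x1.tsv", tmp_path / "x2.tsv"
    write_expression(records, p1)
    back = parse_expression(p1)
    assert back == records
    write_expression(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_expression_collapses_transcripts_by_max_control(tmp_path):
    p = tmp_path / "x.tsv"
    p.write_text(
        "gene_id\ttpm_control\ttpm_knockdown\tgroup\n"
        "G1\t2\t1\tSE\nG1\t9\t3\tSE\nG1\t4\t2\tSE\n"
    )
    (rec,) = parse_expression(p)
    assert (rec.tpm_control, rec.tpm_knockdown) == (9.0, 3.0)
    assert len(parse_expression(p, collapse_transcripts=False)) == 3


def test_expression_rejects_negative_tpm(tmp_path):
    with pytest.raises(ValidationError):
        ExpressionRecord("G1", -1.0, 0.0)


# ---------------------------------------------------------------------------
# bedGraph / SignalTrack / rpm
# ---------------------------------------------------------------------------

def test_parse_bedgraph_length_weighted_bins(tmp_path):
    p = tmp_path / "t.bedGraph"
    # interval straddles the bin boundary at 10: bin0 gets 5bp, bin1 gets 5bp
    p.write_text("chr1\t5\t15\t4\n")
    track = parse_bedgraph(p, bin_width=10)
    assert track.total_mass == 40.0
    np.testing.assert_allclose(track.values("chr1"), [2.0, 2.0])


def test_bedgraph_round_trip_track_mass(tmp_path):
    rng = np.random.default_rng(0)
    data = {"chr1": rng.integers(0, 5, 37).astype(float), "chr2": rng.integers(0, 5, 12).astype(float)}
    track = SignalTrack(
        data=data, bin_width=10, total_mass=float(sum(a.sum() for a in data.values()) * 10)
    )
    p = tmp_path / "t.bedGraph"
    write_bedgraph(track, p)
    back = parse_bedgraph(p, 10, chrom_sizes={"chr1": 370, "chr2": 120})
    for chrom in data:
        np.testing.assert_allclose(back.values(chrom), data[chrom])
    assert back.total_mass == pytest.approx(track.total_mass)


def test_to_rpm_scales_and_preserves_ratios():
    data = {"chr1": np.array([2.0, 6.0, 0.0])}
    track = SignalTrack(data=data, bin_width=10, total_mass=80.0)
    rpm = to_rpm(track)
    np.testing.assert_allclose(rpm.values("chr1"), np.array([2.0, 6.0, 0.0]) * 1e6 / 80.0)
    # total rpm mass is one million by construction
    assert rpm.mass() == pytest.approx(1e6)
    # ratios between bins unchanged
    assert rpm.values("chr1")[1] / rpm.values("chr1")[0] == pytest.approx(3.0)
    # idempotent
    assert to_rpm(rpm) is rpm


def test_to_rpm_rejects_zero_mass():
    track = SignalTrack(data={"chr1": np.zeros(5)}, bin_width=10, total_mass=0.0)
    with pytest.raises(DegenerateTrackError):
        to_rpm(track)


def test_rpm_ratio_invariance_random_tracks():
    rng = np.random.default_rng(3)
    for _ in range(20):
        arr = rng.uniform(0.1, 50.0, rng.integers(2, 40))
        track = SignalTrack(data={"c": arr}, bin_width=5, total_mass=float(arr.sum() * 5))
        rpm = to_rpm(track).values("c")
        np.testing.assert_allclose(rpm / rpm[0], arr / arr[0], rtol=1e-12)
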