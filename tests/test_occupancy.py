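"""Occupancy calling, annotation, state classification, and prediction."""

from __future__ import annotations

import numpy as np
import pytest

from enhancerscope.genomic_io import EnhancerRegion, GeneModel, GenomicInterval, Peak
from enhancerscope.occupancy import (
    annotate_peak,
    call_occupancy,
    classify_states,
    intersects,
    merge_intervals,
    predict_active_enhancers,
    venn_counts,
)


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def _peak(start, end, chrom="chr1", name="p", factor="F", score=1.0):
    return Peak(_iv(start, end, chrom), (start + end) // 2, score, name, factor)


def _region(start, end, enh_id, cls="TE", chrom="chr1"):
    return EnhancerRegion(_iv(start, end, chrom), cls, enh_id)


# ---------------------------------------------------------------------------
# intersects: the 1-bp rule
# ---------------------------------------------------------------------------

def test_intersects_one_bp_overlap():
    assert intersects(_iv(0, 101), _iv(100, 200))


def test_intersects_half_open_adjacency_is_not_overlap():
    assert not intersects(_iv(0, 100), _iv(100, 200))


def test_intersects_requires_same_chrom():
    assert not intersects(_iv(0, 100, "chr1"), _iv(0, 100, "chr2"))


def test_intersects_containment():
    assert intersects(_iv(0, 1000), _iv(400, 500))


# ---------------------------------------------------------------------------
# call_occupancy
# ---------------------------------------------------------------------------

def test_call_occupancy_no_peaks_all_unbound():
    regions = [_region(0, 100, "e1"), _region(200, 300, "e2")]
    m = call_occupancy(regions, {"Ctr9": []})
    assert not m.table.values.any()


def test_call_occupancy_chrom_spanning_peak_binds_same_chrom_only():
    regions = [_region(0, 100, "e1", chrom="chr1"), _region(0, 100, "e2", chrom="chr2")]
    m = call_occupancy(regions, {"F": [_peak(0, 10_000, chrom="chr1")]})
    assert m.bound("e1", "F") and not m.bound("e2", "F")


def test_call_occupancy_duplicate_region_ids_rejected():
    regions = [_region(0, 100, "dup"), _region(200, 300, "dup")]
    with pytest.raises(ValueError, match="dup"):
        call_occupancy(regions, {"F": []})


def test_call_occupancy_records_supporting_peaks():
    regions = [_region(50, 150, "e1")]
    m = call_occupancy(regions, {"F": [_peak(0, 60, name="pa"), _peak(140, 300, name="pb")]})
    assert m.supporting_peaks("e1", "F") == ("pa", "pb")


def _brute_occupancy(regions, peaks_by_factor):
    return {
        (r.enh_id, f): any(intersects(r.interval, p.interval) for p in ps)
        for r in regions
        for f, ps in peaks_by_factor.items()
    }


def test_call_occupancy_matches_all_pairs_oracle_random():
    rng = np.random.default_rng(17)
    for _ in range(30):
        chroms = ["chr1", "chr2"]
        regions = []
        for i in range(int(rng.integers(1, 25))):
            s = int(rng.integers(0, 5000))
            regions.append(
                _region(s, s + int(rng.integers(1, 400)), f"e{i}", chrom=chroms[int(rng.integers(2))])
            )
        peaks_by_factor = {}
        for f in ("A", "B"):
            ps = []
            for j in range(int(rng.integers(0, 25))):
                s = int(rng.integers(0, 5000))
                ps.append(_peak(s, s + int(rng.integers(1, 300)), chrom=chroms[int(rng.integers(2))], name=f"{f}{j}", factor=f))
            peaks_by_factor[f] = ps
        m = call_occupancy(regions, peaks_by_factor)
        brute = _brute_occupancy(regions, peaks_by_factor)
        for (rid, f), expect in brute.items():
            assert m.bound(rid, f) == expect


def test_call_occupancy_monotone_under_added_peaks():
    rng = np.random.default_rng(23)
    regions = [_region(int(s), int(s) + 100, f"e{i}") for i, s in enumerate(rng.integers(0, 3000, 10))]
    base = [_peak(int(s), int(s) + 80, name=f"p{i}") for i, s in enumerate(rng.integers(0, 3000, 5))]
    extra = base + [_peak(0, 3200, name="big")]
    m1 = call_occupancy(regions, {"F": base})
    m2 = call_occupancy(regions, {"F": extra})
    assert (m2.table.values >= m1.table.values).all()


# ---------------------------------------------------------------------------
# annotate_peak
# ---------------------------------------------------------------------------

GENES = [GeneModel("G1", "chr1", "+", 10_000, 20_000)]


def test_annotate_summit_at_tss():
    ann = annotate_peak(_peak(9_900, 10_100), GENES)
    assert (ann.context, ann.subcontext) == ("genic", "TSS")


def test_annotate_gene_body():
    ann = annotate_peak(_peak(14_000, 15_000), GENES)
    assert (ann.context, ann.subcontext) == ("genic", "gene_body")


def test_annotate_tes_beats_body():
    ann = annotate_peak(_peak(19_500, 20_500), GENES)
    assert ann.subcontext == "TES"


def test_annotate_far_peak_intergenic():
    ann = annotate_peak(_peak(50_000, 50_200), GENES)
    assert (ann.context, ann.subcontext) == ("intergenic", "intergenic")


def test_annotate_flank_is_genic_but_not_anchor():
    # inside the 2 kb genic flank, outside the 1 kb TSS window
    ann = annotate_peak(_peak(8_200, 8_600), GENES)
    assert (ann.context, ann.subcontext) == ("genic", "intergenic")


# ---------------------------------------------------------------------------
# states and venn
# ---------------------------------------------------------------------------

def _matrix_for(rows):
    regions = [_region(i * 1000, i * 1000 + 100, rid) for i, rid in enumerate(rows)]
    peaks = {"H3K27ac": [], "H3K4me1": [], "Ctr9": []}
    for i, (rid, factors) in enumerate(rows.items()):
        for f in factors:
            peaks[f].append(_peak(i * 1000, i * 1000 + 100, name=f"{f}_{rid}", factor=f))
    return call_occupancy(regions, peaks)


def test_classify_states_partition():
    m = _matrix_for(
        {
            "a": ("H3K27ac", "H3K4me1", "Ctr9"),
            "b": ("H3K4me1",),
            "c": (),
            "d": ("H3K27ac",),
        }
    )
    states = {s.region_id: s for s in classify_states(m)}
    assert states["a"].state == "active" and states["a"].ctr9_bound
    assert states["b"].state == "poised"
    assert states["c"].state == "unmarked"
    assert states["d"].state == "active" and not states["d"].ctr9_bound


def test_classify_states_missing_column_named():
    m = _matrix_for({"a": ()})
    with pytest.raises(KeyError, match="NELFA"):
        classify_states(m, h3k27ac="NELFA")


def test_venn_counts_sum_to_region_count_and_match_enumeration():
    m = _matrix_for(
        {
            "a": ("H3K27ac", "Ctr9"),
            "b": ("H3K4me1",),
            "c": (),
            "d": ("H3K27ac",),
            "e": ("H3K27ac", "Ctr9"),
        }
    )
    counts = venn_counts(m, ["H3K27ac", "H3K4me1", "Ctr9"])
    assert sum(counts.values()) == 5
    assert counts == {"H3K27ac&Ctr9": 2, "H3K4me1": 1, "none": 1, "H3K27ac": 1}


# ---------------------------------------------------------------------------
# merge / predict
# ---------------------------------------------------------------------------

def test_merge_intervals_unions_overlaps_only():
    merged = merge_intervals([_iv(0, 10, "chr2"), _iv(50, 150), _iv(0, 100), _iv(150, 200)])
    # adjacent-but-not-overlapping intervals (half-open) stay separate
    assert merged == [_iv(0, 150), _iv(150, 200), _iv(0, 10, "chr2")]


def test_predict_requires_ctr9_overlap():
    k27 = [_peak(5000, 5400, name="k1", factor="H3K27ac")]
    assert predict_active_enhancers(k27, [], GENES) == []
    ctr9 = [_peak(5300, 5600, name="c1", factor="Ctr9")]
    assert predict_active_enhancers(k27, ctr9, GENES) == [_iv(5000, 5400)]


def test_predict_excludes_promoter_touching_peaks():
    # overlaps the TSS +/- 1000 window of G1 (TSS 10_000)
    k27 = [_peak(10_500, 11_500, name="k1", factor="H3K27ac")]
    ctr9 = [_peak(10_500, 11_500, name="c1", factor="Ctr9")]
    assert predict_active_enhancers(k27, ctr9, GENES) == []


def test_predict_merges_adjacent_survivors():
    k27 = [
        _peak(50_000, 50_400, name="k1", factor="H3K27ac"),
        _peak(50_300, 50_700, name="k2", factor="H3K27ac"),
    ]
    ctr9 = [_peak(50_100, 50_600, name="c1", factor="Ctr9")]
    assert predict_active_enhancers(k27, ctr9, GENES) == [_iv(50_000, 50_700)]


def test_predict_recovers_planted_enhancers_minimal(minimal_ds):
    predicted = predict_active_enhancers(
        minimal_ds.peaks["H3K27ac"], minimal_ds.peaks["Ctr9"], minimal_ds.genes
    )
    truth = minimal_ds.plant_map["enhancers"]
    expected = {
        eid
        for eid, t in truth.items()
        if "H3K27ac" in t["factors"] and "Ctr9" in t["factors"]
    }
    recovered = set()
    for eid in expected:
        t = truth[eid]
        iv = GenomicInterval(t["chrom"], t["start"], t["end"])
        if any(intersects(iv, p) for p in predicted):
            recovered.add(eid)
    assert recovered == expected
    # and every prediction lies inside some planted Ctr9+H3K27ac enhancer
    for p in predicted:
        assert any(
            intersects(p, GenomicInterval(t["chrom"], t["start"], t["end"]))
            for t in truth.values()
            if "H3K27ac" in t["factors"] and "Ctr9" in t["factors"]
        )
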