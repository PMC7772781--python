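"""Co-occupancy calling, peak context annotation, enhancer-state
classification, and combined-mark active-enhancer prediction.

Occupancy follows the 1-bp rule: a region is bound by a factor when at least
one peak of that factor overlaps it by >= 1 bp (half-open arithmetic).
Enhancer chromatin states are derived from the two histone marks alone:
H3K27ac marks active enhancers, H3K4me1 without H3K27ac marks poised ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import EnhancerRegion, GeneModel, GenomicInterval, Peak

__all__ = [
    "intersects",
    "OccupancyMatrix",
    "call_occupancy",
    "PeakAnnotation",
    "annotate_peak",
    "EnhancerState",
    "classify_states",
    "venn_counts",
    "predict_active_enhancers",
    "merge_intervals",
]


def intersects(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share a chromosome and >= 1 bp."""
    return a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= 1


@dataclass
class OccupancyMatrix:
    """Boolean region x factor matrix with per-cell supporting peak names."""

    table: pd.DataFrame  # index: region ids; columns: factors; dtype bool
    provenance: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def factors(self) -> list[str]:
        return list(self.table.columns)

    def bound(self, region_id: str, factor: str) -> bool:
        return bool(self.table.at[region_id, factor])

    def supporting_peaks(self, region_id: str, factor: str) -> tuple[str, ...]:
        return self.provenance.get((region_id, factor), ())


def _peak_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p.name
        )
    return trees


def call_occupancy(
    regions: Sequence[EnhancerRegion],
    peaks_by_factor: Mapping[str, Sequence[Peak]],
) -> OccupancyMatrix:
    """1-bp-intersection occupancy of every region by every factor.

    Uses per-chromosome interval trees, so cost is ~O((n + m) log m) rather
    than the all-pairs scan the result is defined (and tested) against.
    """
    ids = [r.enh_id for r in regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate region ids: {dupes}")
    factors = list(peaks_by_factor)
    table = pd.DataFrame(False, index=ids, columns=factors, dtype=bool)
    provenance: dict[tuple[str, str], tuple[str, ...]] = {}
    for factor in factors:
        trees = _peak_trees(peaks_by_factor[factor])
        for region in regions:
            tree = trees.get(region.interval.chrom)
            if tree is None:
                continue
            hits = tree.overlap(region.interval.start, region.interval.end)
            if hits:
                table.at[region.enh_id, factor] = True
                provenance[(region.enh_id, factor)] = tuple(
                    sorted(h.data for h in hits)
                )
    return OccupancyMatrix(table=table, provenance=provenance)


@dataclass(frozen=True)
class PeakAnnotation:
    context: str  # genic | intergenic
    subcontext: str  # TSS | TES | gene_body | intergenic


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    genic_flank: int = 2000,
    anchor_window: int = 1000,
) -> PeakAnnotation:
    """Classify a peak as genic/intergenic and assign a summit sub-context.

    A peak is genic when its interval overlaps any gene span extended by
    ``genic_flank`` on both sides. The sub-context comes from the summit:
    within ``anchor_window`` of a TSS beats within ``anchor_window`` of a
    TES, which beats lying inside a gene body.
    """
    genic = False
    near_tss = near_tes = in_body = False
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        lo = min(gene.tss, gene.tes)
        hi = max(gene.tss, gene.tes)
        flank_iv = GenomicInterval(gene.chrom, max(0, lo - genic_flank), hi + 1 + genic_flank)
        if intersects(peak.interval, flank_iv):
            genic = True
        if abs(peak.summit - gene.tss) <= anchor_window:
            near_tss = True
        if abs(peak.summit - gene.tes) <= anchor_window:
            near_tes = True
        if lo <= peak.summit <= hi:
            in_body = True
    if near_tss:
        sub = "TSS"
    elif near_tes:
        sub = "TES"
    elif in_body:
        sub = "gene_body"
    else:
        sub = "intergenic"
    return PeakAnnotation("genic" if genic else "intergenic", sub)


@dataclass(frozen=True)
class EnhancerState:
    region_id: str
    state: str  # active | poised | unmarked
    ctr9_bound: bool


def classify_states(
    matrix: OccupancyMatrix,
    h3k27ac: str = "H3K27ac",
    h3k4me1: str = "H3K4me1",
    ctr9: str = "Ctr9",
) -> list[EnhancerState]:
    """Chromatin state per region: active (H3K27ac+), poised
    (H3K4me1+ / H3K27ac-), unmarked otherwise."""
    for col in (h3k27ac, h3k4me1, ctr9):
        if col not in matrix.table.columns:
            raise KeyError(f"occupancy matrix lacks factor column {col!r}")
    out: list[EnhancerState] = []
    for region_id, row in matrix.table.iterrows():
        if row[h3k27ac]:
            state = "active"
        elif row[h3k4me1]:
            state = "poised"
        else:
            state = "unmarked"
        out.append(EnhancerState(str(region_id), state, bool(row[ctr9])))
    return out


def venn_counts(matrix: OccupancyMatrix, factors: Sequence[str]) -> dict[str, int]:
    """Counts of regions in every exclusive factor-combination subset.

    Keys are '&'-joined factor names in the given order; regions bound by
    none of the factors appear under 'none'. Counts sum to the region count.
    """
    for f in factors:
        if f not in matrix.table.columns:
            raise KeyError(f"occupancy matrix lacks factor column {f!r}")
    counts: dict[str, int] = {}
    sub = matrix.table[list(factors)]
    for _, row in sub.iterrows():
        present = [f for f in factors if row[f]]
        key = "&".join(present) if present else "none"
        counts[key] = counts.get(key, 0) + 1
    return counts


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping (>=1 bp) intervals are merged; output
    sorted by (chrom, start)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def predict_active_enhancers(
    h3k27ac_peaks: Sequence[Peak],
    ctr9_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_exclusion: int = 1000,
) -> list[GenomicInterval]:
    """Nominate active enhancers as H3K27ac peaks co-occupied by Ctr9.

    An H3K27ac peak survives when it (i) overlaps at least one Ctr9 peak and
    (ii) does not touch any TSS +/- ``promoter_exclusion`` window (the
    promoter filter removes active-promoter H3K27ac). Surviving intervals
    are merged and sorted.
    """
    ctr9_trees = _peak_trees(ctr9_peaks)
    tss_trees: dict[str, IntervalTree] = {}
    for gene in genes:
        lo = max(0, gene.tss - promoter_exclusion)
        hi = gene.tss + promoter_exclusion + 1
        tss_trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi)
    survivors: list[GenomicInterval] = []
    for peak in h3k27ac_peaks:
        ctree = ctr9_trees.get(peak.chrom)
        if ctree is None or not ctree.overlap(peak.interval.start, peak.interval.end):
            continue
        ttree = tss_trees.get(peak.chrom)
        if ttree is not None and ttree.overlap(peak.interval.start, peak.interval.end):
            continue
        survivors.append(peak.interval)
    return merge_intervals(survivors)
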