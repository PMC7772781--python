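"""Enhancer RNA containment analysis.

eRNA intervals (derived upstream from run-on sequencing) are intersected
with enhancer regions, and eRNA-positive enhancers are cross-tabulated
against Ctr9 and RNAPII Ser2p occupancy: the headline statistic is the
fraction of eRNA-producing enhancers that are also Ctr9-bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .genomic_io import EnhancerRegion, GenomicInterval
from .occupancy import OccupancyMatrix

__all__ = ["ErnaCall", "call_erna"]


@dataclass(frozen=True)
class ErnaCall:
    region_id: str
    erna_present: bool
    ctr9_bound: bool
    ser2p_bound: bool


def call_erna(
    regions: Sequence[EnhancerRegion],
    erna_intervals: Sequence[GenomicInterval],
    matrix: OccupancyMatrix,
    ctr9: str = "Ctr9",
    ser2p: str = "Ser2p",
) -> tuple[list[ErnaCall], dict[str, float]]:
    """Per-region eRNA presence (>= 1 bp intersection) against occupancy.

    Returns the calls plus a summary with the eRNA-positive count, its
    intersections with Ctr9+ and Ser2p+ regions, and the Ctr9 containment
    fraction |eRNA+ & Ctr9+| / |eRNA+| (0 when there are no eRNAs).
    """
    region_ids = {r.enh_id for r in regions}
    matrix_ids = set(matrix.region_ids)
    if not region_ids <= matrix_ids:
        missing = sorted(region_ids - matrix_ids)[:5]
        raise ValueError(f"regions absent from occupancy matrix: {missing}")
    for col in (ctr9, ser2p):
        if col not in matrix.table.columns:
            raise KeyError(f"occupancy matrix lacks factor column {col!r}")

    trees: dict[str, IntervalTree] = {}
    for iv in erna_intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    calls: list[ErnaCall] = []
    for r in regions:
        tree = trees.get(r.interval.chrom)
        present = bool(tree and tree.overlap(r.interval.start, r.interval.end))
        calls.append(
            ErnaCall(
                r.enh_id,
                present,
                matrix.bound(r.enh_id, ctr9),
                matrix.bound(r.enh_id, ser2p),
            )
        )
    n_erna = sum(c.erna_present for c in calls)
    n_erna_ctr9 = sum(c.erna_present and c.ctr9_bound for c in calls)
    n_erna_ser2p = sum(c.erna_present and c.ser2p_bound for c in calls)
    summary = {
        "n_erna": float(n_erna),
        "n_erna_ctr9": float(n_erna_ctr9),
        "n_erna_ser2p": float(n_erna_ser2p),
        "ctr9_containment": n_erna_ctr9 / n_erna if n_erna else 0.0,
    }
    return calls, summary
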