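"""Knockdown differential-expression summaries grouped by enhancer class.

Genes are kept when expressed in the control condition (tpm >= 1 by
default), given a log2 fold change of knockdown over control tpm, and
assigned to an SE, TE, or 'other' group by proximity of their TSS to the
nearest annotated enhancer. Group contrasts report the fraction of
down-regulated genes and pairwise Mann-Whitney U p-values.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import EnhancerRegion, ExpressionRecord, GeneModel
from .stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "filter_expressed",
    "log2_fold_change",
    "associate_genes",
    "fraction_decreased",
    "GroupContrast",
    "group_contrast",
]

GROUPS = ("SE", "TE", "other")


def filter_expressed(
    records: Sequence[ExpressionRecord], threshold_tpm: float = 1.0
) -> list[ExpressionRecord]:
    """Keep genes whose control tpm meets the expressed threshold
    (boundary inclusive)."""
    return [r for r in records if r.tpm_control >= threshold_tpm]


def log2_fold_change(record: ExpressionRecord, epsilon: float = 0.0) -> float:
    """log2((tpm_kd + eps) / (tpm_ctrl + eps)).

    With the default eps = 0 a knockdown tpm of exactly zero returns -inf
    (logged) rather than being silently pseudocounted.
    """
    num = record.tpm_knockdown + epsilon
    den = record.tpm_control + epsilon
    if den == 0:
        raise ValueError(f"gene {record.gene_id}: undefined fold change (control tpm 0)")
    if num == 0:
        logger.warning("gene %s: knockdown tpm 0, log2fc = -inf", record.gene_id)
        return -math.inf
    return math.log2(num / den)


def _tss_to_region_distance(tss: int, region: EnhancerRegion) -> int:
    """0 when the TSS lies inside the region, else distance to nearest edge."""
    iv = region.interval
    if iv.start <= tss < iv.end:
        return 0
    if tss < iv.start:
        return iv.start - tss
    return tss - (iv.end - 1)


def associate_genes(
    genes: Sequence[GeneModel],
    enhancers: Sequence[EnhancerRegion],
    max_distance_bp: int = 100_000,
) -> dict[str, str]:
    """Assign each gene to SE, TE, or 'other' by its nearest enhancer.

    The nearest enhancer within ``max_distance_bp`` (TSS-to-region-edge
    distance, 0 inside) determines the group; when an SE and a TE are
    equally near, SE wins. Genes with no enhancer in range are 'other'.
    """
    by_chrom: dict[str, list[EnhancerRegion]] = {}
    for e in enhancers:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    starts: dict[str, list[int]] = {}
    for chrom, es in by_chrom.items():
        es.sort(key=lambda e: (e.interval.start, e.interval.end))
        starts[chrom] = [e.interval.start for e in es]

    out: dict[str, str] = {}
    for gene in genes:
        es = by_chrom.get(gene.chrom)
        if not es:
            out[gene.gene_id] = "other"
            continue
        # candidates whose start is within range of the TSS, plus neighbors
        lo = bisect.bisect_left(starts[gene.chrom], gene.tss - max_distance_bp - max(
            e.interval.length for e in es
        ))
        hi = bisect.bisect_right(starts[gene.chrom], gene.tss + max_distance_bp)
        best_class, best_d = "other", None
        for e in es[lo:hi]:
            d = _tss_to_region_distance(gene.tss, e)
            if d > max_distance_bp:
                continue
            rank = (d, 0 if e.enh_class == "SE" else 1)
            if best_d is None or rank < best_d:
                best_d, best_class = rank, e.enh_class
        out[gene.gene_id] = best_class
    return out


def fraction_decreased(log2fcs: Sequence[float]) -> float:
    """Percentage of genes with log2 fold change below zero."""
    arr = np.asarray(log2fcs, dtype=float)
    if len(arr) == 0:
        raise ValueError("empty group")
    return float(100.0 * np.count_nonzero(arr < 0) / len(arr))


@dataclass(frozen=True)
class GroupContrast:
    n: dict[str, int]
    median_log2fc: dict[str, float]
    fraction_decreased: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]


def group_contrast(log2fcs_by_group: Mapping[str, Sequence[float]]) -> GroupContrast:
    """Per-group summaries plus pairwise two-sided Mann-Whitney U tests.

    Pairs involving an empty group are skipped with a warning rather than
    raising.
    """
    n: dict[str, int] = {}
    med: dict[str, float] = {}
    frac: dict[str, float] = {}
    for g, values in log2fcs_by_group.items():
        arr = np.asarray(values, dtype=float)
        n[g] = len(arr)
        med[g] = float(np.median(arr)) if len(arr) else math.nan
        frac[g] = fraction_decreased(arr) if len(arr) else math.nan
    pairwise: dict[tuple[str, str], float] = {}
    groups = list(log2fcs_by_group)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            if n[ga] == 0 or n[gb] == 0:
                logger.warning("skipping contrast %s vs %s: empty group", ga, gb)
                continue
            pairwise[(ga, gb)] = rank_sum_test(
                log2fcs_by_group[ga], log2fcs_by_group[gb]
            )
    return GroupContrast(n=n, median_log2fc=med, fraction_decreased=frac, pairwise_p=pairwise)
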