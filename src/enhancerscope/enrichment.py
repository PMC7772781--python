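"""Per-region occupancy density, SE-vs-TE class contrasts, length-matched
shuffled controls, and knockdown occupancy fold changes.

Two distinct fold estimators are exposed on purpose: density contrasts
between enhancer classes use class means (with a Wilcoxon rank-sum p-value),
while control-vs-knockdown occupancy changes use per-class medians of
region read counts. Both operate on rpm-normalized coverage tracks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import EnhancerRegion, GenomicInterval, SignalTrack
from .signal import interval_mass
from .stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "DensityRecord",
    "region_density",
    "ClassContrast",
    "compare_classes",
    "shuffle_intervals",
    "occupancy_fold_change",
]


@dataclass(frozen=True)
class DensityRecord:
    """Signal density of one factor over one region (mass per bp)."""

    region_id: str
    enh_class: str
    factor: str
    density: float
    mass: float
    length: int


def region_density(
    track: SignalTrack,
    regions: Sequence[EnhancerRegion],
    factor: str = "signal",
) -> list[DensityRecord]:
    """Per-region track mass divided by region length (length-weighted at
    partial bins). Regions on chromosomes absent from the track get density
    zero with a warning."""
    out: list[DensityRecord] = []
    for r in regions:
        iv = r.interval
        if iv.chrom not in track.data:
            logger.warning("region %s on %s absent from track; density 0", r.enh_id, iv.chrom)
            mass = 0.0
        else:
            mass = interval_mass(track, iv.chrom, iv.start, iv.end)
        out.append(
            DensityRecord(r.enh_id, r.enh_class, factor, mass / iv.length, mass, iv.length)
        )
    return out


@dataclass(frozen=True)
class ClassContrast:
    class_a: str
    class_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    fold: float | None  # mean_a / mean_b; None when mean_b == 0
    p_value: float


def compare_classes(
    densities: Sequence[DensityRecord],
    class_a: str = "SE",
    class_b: str = "TE",
) -> ClassContrast:
    """Mean-density fold (class_a over class_b) with a two-sided Wilcoxon
    rank-sum p-value for the density distributions."""
    a = np.array([d.density for d in densities if d.enh_class == class_a])
    b = np.array([d.density for d in densities if d.enh_class == class_b])
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"both classes must be non-empty ({class_a}: {len(a)}, {class_b}: {len(b)})")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_a / mean_b if mean_b != 0 else None
    p = rank_sum_test(a, b)
    return ClassContrast(class_a, class_b, len(a), len(b), mean_a, mean_b, fold, p)


def shuffle_intervals(
    regions: Sequence[EnhancerRegion],
    genome: Mapping[str, int],
    seed: int,
) -> list[GenomicInterval]:
    """Length-matched randomized control intervals.

    Emits exactly one interval per input region of identical length, placed
    uniformly on a uniformly chosen chromosome that can host the length.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    sizes = np.array([genome[c] for c in chroms])
    out: list[GenomicInterval] = []
    for r in regions:
        length = r.interval.length
        eligible = [i for i, s in enumerate(sizes) if s >= length]
        if not eligible:
            raise ValueError(
                f"region {r.enh_id} (length {length}) exceeds every chromosome"
            )
        ci = eligible[int(rng.integers(len(eligible)))]
        start = int(rng.integers(sizes[ci] - length + 1))
        out.append(GenomicInterval(chroms[ci], start, start + length))
    return out


def occupancy_fold_change(
    track_control: SignalTrack,
    track_knockdown: SignalTrack,
    regions_by_class: Mapping[str, Sequence[EnhancerRegion]],
) -> dict[str, dict[str, float | None]]:
    """Median per-region read count in each condition, per enhancer class,
    and the control/knockdown fold.

    Read count means track mass (rpm x bp) over the region. A zero
    knockdown median yields fold = None.
    """
    out: dict[str, dict[str, float | None]] = {}
    for cls, regions in regions_by_class.items():
        ctrl = np.array(
            [interval_mass(track_control, r.interval.chrom, r.interval.start, r.interval.end) for r in regions]
        )
        kd = np.array(
            [interval_mass(track_knockdown, r.interval.chrom, r.interval.start, r.interval.end) for r in regions]
        )
        med_c = float(np.median(ctrl)) if len(ctrl) else math.nan
        med_k = float(np.median(kd)) if len(kd) else math.nan
        fold = med_c / med_k if med_k else None
        out[cls] = {"median_control": med_c, "median_kd": med_k, "fold": fold, "n": len(regions)}
    return out
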