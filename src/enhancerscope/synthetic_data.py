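"""Synthetic genomes, peak sets, coverage tracks, and expression tables with
planted, recoverable structure.

The generator emulates the statistical features the downstream analyses
measure: promoter-proximal factor summits at characteristic offsets
downstream of TSSs (NELFA closest, then RNAPII Ser5p, then Ctr9),
class-dependent enhancer occupancy (super enhancers far more often
Ctr9-bound than typical enhancers), NELFA-to-Ctr9 summit distances that are
larger on SEs than on gene promoters, a planted SE:TE Ctr9 density ratio,
containment constraints (Ser2p and eRNA only on Ctr9-bound enhancers), and
a knockdown effect model for both expression (per-group down-regulation
fractions) and Ser2p occupancy (per-class divisors).

Where the calibration plants a population fraction, membership is drawn as
an exact-count random subset (round(n*p) regions chosen without
replacement) rather than independent Bernoulli trials, so the planted
fraction itself is recoverable and only the choice of members is random.

Layout is block-based: each enhancer sits in its own block, optionally with
its target gene a few kb away; blocks are separated by spacers large enough
that every gene's nearest enhancer is its own, and genes without enhancer
association live on a dedicated chromosome. The plant map records every
planted quantity so any downstream statistic can be recomputed without
re-simulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic_io import (
    EnhancerRegion,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_enhancers,
    write_expression,
    write_gene_table,
    write_narrowpeak,
)

__all__ = [
    "OffsetSpec",
    "CalibrationProfile",
    "SyntheticDataset",
    "default_profile",
    "simulate",
    "simulate_expression",
    "write_dataset",
]

PROFILE_NAMES = ("paper2020", "minimal")
ENHANCER_FACTORS = ("Ctr9", "NELFA", "Ser5p", "Ser2p", "H3K27ac", "H3K4me1")


@dataclass(frozen=True)
class OffsetSpec:
    mean: float
    sd: float


@dataclass
class CalibrationProfile:
    """Every number the generator plants, in one auditable place."""

    name: str
    # genome layout
    n_chromosomes: int
    n_se: int
    n_te: int
    n_genes_se: int
    n_genes_te: int
    n_genes_other: int
    se_width: int
    te_width: int
    gene_length_range: tuple[int, int]
    enhancer_gene_gap: tuple[int, int]
    gene_block_spacer: int
    lone_te_gap: int
    other_gene_gap: tuple[int, int]
    chrom_margin: int
    # promoter-proximal positioning (bp downstream of TSS)
    promoter_offsets: dict[str, OffsetSpec]
    # enhancer NELFA-Ctr9 summit distances per class
    pair_distance: dict[str, OffsetSpec]
    bilateral_fraction: float
    # per-class occupancy probabilities
    occupancy: dict[str, dict[str, float]]
    ser5p_given_ctr9: dict[str, float]
    ser5p_given_no_ctr9: dict[str, float]
    ser2p_given_ctr9: dict[str, float]
    erna_given_ctr9: dict[str, float]
    # coverage calibration
    density_ratio_se_te: float
    ctr9_te_height: float
    nelfa_height: float
    ser5p_height: float
    ser2p_enh_height: dict[str, float]
    ser2p_body_coverage: float
    promoter_height: dict[str, float]
    # knockdown effect model
    knockdown_down_fraction: dict[str, float]
    down_effect: tuple[float, float]
    up_effect: tuple[float, float]
    ser2p_kd_divisor: dict[str, float]
    # expression model
    stratum_fractions: dict[str, float]
    tpm_ranges: dict[str, tuple[float, float]]
    expressed_threshold: float
    # track geometry
    kernel_half_width: int
    peak_half_width: int
    bin_width: int
    noise_rate: float
    track_factors: tuple[str, ...]

    @property
    def total_enhancers(self) -> int:
        return self.n_se + self.n_te

    @property
    def total_genes(self) -> int:
        return self.n_genes_se + self.n_genes_te + self.n_genes_other

    def validate(self) -> None:
        for cls, factors in self.occupancy.items():
            for f, p in factors.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"occupancy[{cls}][{f}] = {p} outside [0, 1]")
        for spec in list(self.promoter_offsets.values()) + list(self.pair_distance.values()):
            if spec.sd < 0:
                raise ValueError("offset sd must be >= 0")
        if min(self.n_se, self.n_te, self.n_genes_other) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_genes_se > self.n_se or self.n_genes_te > self.n_te:
            raise ValueError("cannot attach more target genes than enhancers")


def default_profile(name: str) -> CalibrationProfile:
    """Named calibration profiles.

    ``paper2020`` is the study-scale calibration: 231 SEs vs 8,563 TEs,
    promoter summit offsets 21/39/184 bp for NELFA/Ser5p/Ctr9, NELFA-Ctr9
    distances 465 bp (SE) and 163 bp (TE, the gene-promoter value reused
    since no separate TE figure is stated in text), Ctr9 occupancy 72% of
    SEs and 7% of TEs, H3K4me1/H3K27ac on 90%/88% of SEs and 83%/31% of
    TEs, a 2.7-fold SE:TE Ctr9 density ratio, knockdown down-regulation
    fractions 73.5/63.8/53.7% for SE/TE/other gene groups, and Ser2p
    knockdown occupancy divisors 1.5 (SE) and 1.3 (TE). ``minimal`` is a
    2-chromosome, 20-gene, 10-enhancer profile for unit tests.
    """
    if name == "paper2020":
        profile = CalibrationProfile(
            name="paper2020",
            n_chromosomes=5,
            n_se=231,
            n_te=8563,
            n_genes_se=231,
            n_genes_te=700,
            n_genes_other=1069,
            se_width=10_000,
            te_width=1_000,
            gene_length_range=(4_000, 15_000),
            enhancer_gene_gap=(3_500, 8_000),
            gene_block_spacer=40_000,
            lone_te_gap=2_000,
            other_gene_gap=(2_000, 5_000),
            chrom_margin=10_000,
            promoter_offsets={
                "NELFA": OffsetSpec(21.0, 5.0),
                "Ser5p": OffsetSpec(39.0, 5.0),
                "Ctr9": OffsetSpec(184.0, 5.0),
            },
            pair_distance={"SE": OffsetSpec(465.0, 50.0), "TE": OffsetSpec(163.0, 50.0)},
            bilateral_fraction=0.1,
            occupancy={
                "SE": {"Ctr9": 0.72, "H3K27ac": 0.88, "H3K4me1": 0.90, "NELFA": 0.80},
                "TE": {"Ctr9": 0.07, "H3K27ac": 0.31, "H3K4me1": 0.83, "NELFA": 0.30},
            },
            ser5p_given_ctr9={"SE": 0.97, "TE": 0.60},
            ser5p_given_no_ctr9={"SE": 0.30, "TE": 0.10},
            # 146 of the 166 Ctr9-bound SEs carry Ser2p
            ser2p_given_ctr9={"SE": 146 / 166, "TE": 0.50},
            # 126 of the 166 Ctr9-bound SEs express an eRNA
            erna_given_ctr9={"SE": 126 / 166, "TE": 0.0},
            density_ratio_se_te=2.7,
            ctr9_te_height=6.0,
            nelfa_height=8.0,
            ser5p_height=8.0,
            ser2p_enh_height={"SE": 20.0, "TE": 6.0},
            ser2p_body_coverage=2.0,
            promoter_height={"low": 3.0, "medium": 6.0, "high": 12.0},
            knockdown_down_fraction={"SE": 0.735, "TE": 0.638, "other": 0.537},
            down_effect=(1.0, 0.4),
            up_effect=(0.5, 0.3),
            ser2p_kd_divisor={"SE": 1.5, "TE": 1.3},
            stratum_fractions={"silent": 0.25, "low": 0.1875, "medium": 0.375, "high": 0.1875},
            tpm_ranges={
                "silent": (0.0, 0.9),
                "low": (1.0, 3.0),
                "medium": (3.0, 30.0),
                "high": (30.0, 300.0),
            },
            expressed_threshold=1.0,
            kernel_half_width=150,
            peak_half_width=150,
            bin_width=10,
            noise_rate=0.05,
            track_factors=("Ctr9", "NELFA", "Ser5p", "Ser2p"),
        )
    elif name == "minimal":
        profile = default_profile("paper2020")
        profile.name = "minimal"
        profile.n_chromosomes = 2
        profile.n_se = 3
        profile.n_te = 7
        profile.n_genes_se = 3
        profile.n_genes_te = 3
        profile.n_genes_other = 14
        profile.se_width = 2_000
        profile.te_width = 1_000
        profile.gene_length_range = (1_000, 3_000)
        profile.enhancer_gene_gap = (3_500, 5_000)
        profile.gene_block_spacer = 20_000
        profile.other_gene_gap = (2_000, 4_000)
        profile.chrom_margin = 5_000
    else:
        raise ValueError(
            f"unknown profile {name!r}; available profiles: {', '.join(PROFILE_NAMES)}"
        )
    profile.validate()
    return profile


@dataclass
class SyntheticDataset:
    """A simulated study: inputs for every pipeline stage plus the plant map
    (the ground truth sufficient to recompute every expected summary)."""

    profile: CalibrationProfile
    seed: int
    genome: dict[str, int]
    genes: list[GeneModel]
    enhancers: list[EnhancerRegion]
    peaks: dict[str, list[Peak]]
    tracks: dict[str, SignalTrack]
    expression: list[ExpressionRecord]
    ernas: list[GenomicInterval]
    plant_map: dict


# ---------------------------------------------------------------------------
# internal draws
# ---------------------------------------------------------------------------

def _exact_subset(rng: np.random.Generator, items: Sequence[int], p: float) -> set[int]:
    """Random subset of exactly round(len * p) members."""
    k = int(round(len(items) * p))
    if k <= 0:
        return set()
    if k >= len(items):
        return set(items)
    chosen = rng.choice(len(items), size=k, replace=False)
    return {items[i] for i in chosen}


def _round_up(x: int, step: int) -> int:
    return -(-x // step) * step


def _ctr9_se_height(profile: CalibrationProfile) -> float:
    """Solve the SE Ctr9 kernel height that plants the target SE:TE mean
    density ratio, given the TE height, occupancy rates, expected kernels
    per bound region, and the noise floor."""
    hw = profile.kernel_half_width
    # Poisson bin values are per-bp depths, so the noise floor density is the
    # Poisson mean itself
    noise_per_bp = profile.noise_rate

    def mean_density(cls: str, n: int, width: int, height: float) -> float:
        p_ctr9 = round(n * profile.occupancy[cls]["Ctr9"]) / n
        p_nelfa = round(n * profile.occupancy[cls]["NELFA"]) / n
        kernels = 1.0 + p_nelfa * profile.bilateral_fraction
        return p_ctr9 * kernels * height * hw / width + noise_per_bp

    target = profile.density_ratio_se_te * mean_density(
        "TE", profile.n_te, profile.te_width, profile.ctr9_te_height
    )
    p_ctr9_se = round(profile.n_se * profile.occupancy["SE"]["Ctr9"]) / profile.n_se
    p_nelfa_se = round(profile.n_se * profile.occupancy["SE"]["NELFA"]) / profile.n_se
    kernels_se = 1.0 + p_nelfa_se * profile.bilateral_fraction
    return (target - noise_per_bp) * profile.se_width / (p_ctr9_se * kernels_se * hw)


def _draw_expression(
    rng: np.random.Generator,
    profile: CalibrationProfile,
    gene_groups: Sequence[tuple[str, str]],
) -> tuple[list[ExpressionRecord], dict[str, dict]]:
    """Control/knockdown tpm per gene with planted per-group down fractions.

    Strata (silent/low/medium/high) are drawn per gene; the exact-count set
    of down-regulated genes is chosen among the genes that pass the
    expressed filter, so the planted fraction is the recoverable one.
    """
    strata = list(profile.stratum_fractions)
    probs = np.array([profile.stratum_fractions[s] for s in strata])
    probs = probs / probs.sum()
    n = len(gene_groups)
    stratum_idx = rng.choice(len(strata), size=n, p=probs)
    tpm_ctrl = np.empty(n)
    for i, si in enumerate(stratum_idx):
        lo, hi = profile.tpm_ranges[strata[si]]
        tpm_ctrl[i] = rng.uniform(lo, hi)

    expressed = tpm_ctrl >= profile.expressed_threshold
    down = np.zeros(n, dtype=bool)
    for group in ("SE", "TE", "other"):
        idx = [i for i, (_, g) in enumerate(gene_groups) if g == group and expressed[i]]
        chosen = _exact_subset(rng, idx, profile.knockdown_down_fraction[group])
        for i in chosen:
            down[i] = True

    dm, ds = profile.down_effect
    um, us = profile.up_effect
    lfc = np.zeros(n)
    for i in range(n):
        if not expressed[i]:
            continue
        if down[i]:
            lfc[i] = -max(0.05, abs(rng.normal(dm, ds)))
        else:
            lfc[i] = max(0.05, abs(rng.normal(um, us)))
    tpm_kd = tpm_ctrl * np.exp2(lfc)

    records = []
    truth: dict[str, dict] = {}
    for i, (gene_id, group) in enumerate(gene_groups):
        records.append(
            ExpressionRecord(gene_id, float(tpm_ctrl[i]), float(tpm_kd[i]), None, group)
        )
        truth[gene_id] = {
            "group": group,
            "stratum": strata[stratum_idx[i]],
            "expressed": bool(expressed[i]),
            "down": bool(down[i]) if expressed[i] else None,
            "planted_log2fc": float(lfc[i]) if expressed[i] else None,
        }
    return records, truth


def simulate_expression(
    profile: CalibrationProfile, n_per_group: int, seed: int
) -> list[ExpressionRecord]:
    """Standalone expression simulation with ``n_per_group`` genes in each
    of the SE / TE / other association groups."""
    rng = np.random.default_rng(seed)
    gene_groups = [
        (f"G_{group}_{i:05d}", group)
        for group in ("SE", "TE", "other")
        for i in range(n_per_group)
    ]
    records, _ = _draw_expression(rng, profile, gene_groups)
    return records


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate(
    profile: CalibrationProfile,
    seed: int,
    with_tracks: bool = True,
    track_factors: Sequence[str] | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic dataset under ``profile``, deterministically
    for a fixed (profile, seed).

    ``with_tracks=False`` skips coverage-track construction (the expensive
    part) for analyses that only need peaks, genes, and expression.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    bw = profile.bin_width

    # ---- layout ----------------------------------------------------------
    blocks: list[tuple[str, bool]] = (
        [("SE", True)] * profile.n_genes_se
        + [("SE", False)] * (profile.n_se - profile.n_genes_se)
        + [("TE", True)] * profile.n_genes_te
        + [("TE", False)] * (profile.n_te - profile.n_genes_te)
    )
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    n_enh_chroms = max(1, profile.n_chromosomes - 1)
    per_chrom = -(-len(blocks) // n_enh_chroms)
    chrom_names = [f"chr{i + 1}" for i in range(profile.n_chromosomes)]

    genes: list[GeneModel] = []
    enhancers: list[EnhancerRegion] = []
    gene_group: dict[str, str] = {}
    enh_target: dict[str, str | None] = {}
    genome: dict[str, int] = {}
    se_i = te_i = gene_i = 0

    for ci in range(n_enh_chroms):
        chrom = chrom_names[ci]
        cursor = profile.chrom_margin
        for cls, has_gene in blocks[ci * per_chrom:(ci + 1) * per_chrom]:
            width = profile.se_width if cls == "SE" else profile.te_width
            start = _round_up(cursor, bw)
            if cls == "SE":
                enh_id = f"SE_{se_i:05d}"
                se_i += 1
            else:
                enh_id = f"TE_{te_i:05d}"
                te_i += 1
            target: str | None = None
            cursor = start + width
            if has_gene:
                gap = int(rng.integers(*profile.enhancer_gene_gap))
                glen = int(rng.integers(*profile.gene_length_range))
                gstart = cursor + gap
                gend = gstart + glen
                strand = "+" if rng.integers(2) == 0 else "-"
                gene_id = f"G_{gene_i:05d}"
                gene_i += 1
                tss, tes = (gstart, gend - 1) if strand == "+" else (gend - 1, gstart)
                genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
                gene_group[gene_id] = cls
                target = gene_id
                cursor = gend + profile.gene_block_spacer
            else:
                cursor += profile.lone_te_gap
            enhancers.append(
                EnhancerRegion(
                    GenomicInterval(chrom, start, start + width),
                    cls,
                    enh_id,
                    (target,) if target else (),
                )
            )
            enh_target[enh_id] = target
        genome[chrom] = _round_up(cursor + profile.chrom_margin, bw)

    # dedicated chromosome for genes with no enhancer within reach
    other_chrom = chrom_names[-1]
    cursor = profile.chrom_margin
    for _ in range(profile.n_genes_other):
        gap = int(rng.integers(*profile.other_gene_gap))
        glen = int(rng.integers(*profile.gene_length_range))
        gstart = cursor + gap
        gend = gstart + glen
        strand = "+" if rng.integers(2) == 0 else "-"
        gene_id = f"G_{gene_i:05d}"
        gene_i += 1
        tss, tes = (gstart, gend - 1) if strand == "+" else (gend - 1, gstart)
        genes.append(GeneModel(gene_id, other_chrom, strand, tss, tes))
        gene_group[gene_id] = "other"
        cursor = gend
    genome[other_chrom] = _round_up(cursor + profile.chrom_margin, bw)

    # ---- expression and knockdown ----------------------------------------
    gene_groups = [(g.gene_id, gene_group[g.gene_id]) for g in genes]
    expression, expr_truth = _draw_expression(rng, profile, gene_groups)
    expressed_ids = {r.gene_id for r in expression if r.tpm_control >= profile.expressed_threshold}

    # ---- enhancer factor membership (exact counts) -----------------------
    idx_by_class = {
        cls: [i for i, e in enumerate(enhancers) if e.enh_class == cls]
        for cls in ("SE", "TE")
    }
    member: dict[str, set[int]] = {f: set() for f in ENHANCER_FACTORS}
    erna_set: set[int] = set()
    for cls, idx in idx_by_class.items():
        if not idx:
            continue
        occ = profile.occupancy[cls]
        ctr9 = _exact_subset(rng, idx, occ["Ctr9"])
        member["Ctr9"] |= ctr9
        member["H3K27ac"] |= _exact_subset(rng, idx, occ["H3K27ac"])
        member["H3K4me1"] |= _exact_subset(rng, idx, occ["H3K4me1"])
        member["NELFA"] |= _exact_subset(rng, idx, occ["NELFA"])
        ctr9_list = sorted(ctr9)
        no_ctr9 = sorted(set(idx) - ctr9)
        member["Ser5p"] |= _exact_subset(rng, ctr9_list, profile.ser5p_given_ctr9[cls])
        member["Ser5p"] |= _exact_subset(rng, no_ctr9, profile.ser5p_given_no_ctr9[cls])
        # eRNA-producing enhancers are drawn first and folded into the Ser2p
        # set: transcribing enhancers carry the elongation mark
        erna_cls = _exact_subset(rng, ctr9_list, profile.erna_given_ctr9[cls])
        erna_set |= erna_cls
        n_ser2p = int(round(len(ctr9_list) * profile.ser2p_given_ctr9[cls]))
        ser2p_cls = set(erna_cls)
        remaining = sorted(set(ctr9_list) - erna_cls)
        if n_ser2p > len(ser2p_cls) and remaining:
            extra = (n_ser2p - len(ser2p_cls)) / len(remaining)
            ser2p_cls |= _exact_subset(rng, remaining, min(1.0, extra))
        member["Ser2p"] |= ser2p_cls
    # NELFA+Ctr9+ enhancers with symmetric flanking Ctr9 peaks (exact count)
    bilateral_set: set[int] = set()
    for cls, idx in idx_by_class.items():
        paired = sorted(set(idx) & member["NELFA"] & member["Ctr9"])
        bilateral_set |= _exact_subset(rng, paired, profile.bilateral_fraction)

    # ---- enhancer peak planting ------------------------------------------
    h_se = _ctr9_se_height(profile)
    ctr9_height = {"SE": h_se, "TE": profile.ctr9_te_height}
    phw = profile.peak_half_width
    peaks: dict[str, list[Peak]] = {f: [] for f in ENHANCER_FACTORS}
    enh_truth: dict[str, dict] = {}
    ernas: list[GenomicInterval] = []

    def _point_peak(factor: str, chrom: str, summit: int, score: float, name: str) -> Peak:
        iv = GenomicInterval(chrom, max(0, summit - phw), summit + phw + 1)
        return Peak(iv, summit, score, name, factor)

    for i, enh in enumerate(enhancers):
        cls = enh.enh_class
        iv = enh.interval
        center = (iv.start + iv.end) // 2
        width = iv.length
        cap = width // 2 - profile.kernel_half_width - 60
        truth: dict = {
            "class": cls,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "factors": sorted(f for f in ENHANCER_FACTORS if i in member[f]),
            "target_gene": enh_target[enh.enh_id],
            "nelfa_summit": None,
            "ctr9_summits": [],
            "nearest_distance": None,
            "laterality": "none",
            "erna": i in erna_set,
            "erna_interval": None,
        }
        nelfa_summit: int | None = None
        if i in member["NELFA"]:
            nelfa_summit = center + int(rng.integers(-50, 51))
            peaks["NELFA"].append(
                _point_peak("NELFA", iv.chrom, nelfa_summit, profile.nelfa_height, f"NELFA_{enh.enh_id}")
            )
            truth["nelfa_summit"] = nelfa_summit
        ctr9_summits: list[int] = []
        if i in member["Ctr9"]:
            if nelfa_summit is not None:
                spec = profile.pair_distance[cls]
                d = float(np.clip(rng.normal(spec.mean, spec.sd), 10, cap))
                side = 1 if rng.integers(2) == 0 else -1
                ctr9_summits.append(nelfa_summit + side * int(round(d)))
                bilateral = i in bilateral_set and cap - d > 50
                if bilateral:
                    d2 = d + rng.uniform(50, cap - d)
                    ctr9_summits.append(nelfa_summit - side * int(round(d2)))
                    truth["laterality"] = "bilateral"
                else:
                    truth["laterality"] = "unilateral"
                truth["nearest_distance"] = int(round(d))
            else:
                lo = -(width // 4)
                ctr9_summits.append(center + int(rng.integers(lo, -lo + 1)))
            for k, s in enumerate(ctr9_summits):
                peaks["Ctr9"].append(
                    _point_peak("Ctr9", iv.chrom, s, ctr9_height[cls], f"Ctr9_{enh.enh_id}_{k}")
                )
            truth["ctr9_summits"] = list(ctr9_summits)
        if i in member["Ser5p"]:
            lo = -(width // 4)
            s = center + int(rng.integers(lo, -lo + 1))
            peaks["Ser5p"].append(
                _point_peak("Ser5p", iv.chrom, s, profile.ser5p_height, f"Ser5p_{enh.enh_id}")
            )
        if i in member["Ser2p"]:
            anchor = ctr9_summits[0] if ctr9_summits else center
            s = int(np.clip(anchor + round(rng.normal(0, 50)), iv.start, iv.end - 1))
            peaks["Ser2p"].append(
                _point_peak("Ser2p", iv.chrom, s, profile.ser2p_enh_height[cls], f"Ser2p_{enh.enh_id}")
            )
        for mark in ("H3K27ac", "H3K4me1"):
            if i in member[mark]:
                peaks[mark].append(
                    Peak(iv, center, 4.0, f"{mark}_{enh.enh_id}", mark)
                )
        if i in erna_set:
            anchor = nelfa_summit if nelfa_summit is not None else center
            if ctr9_summits:
                direction = 1 if ctr9_summits[0] >= anchor else -1
            else:
                direction = 1 if rng.integers(2) == 0 else -1
            length = int(rng.integers(500, 2001))
            if direction > 0:
                erna_iv = GenomicInterval(iv.chrom, anchor, anchor + length)
            else:
                erna_iv = GenomicInterval(iv.chrom, max(0, anchor - length), anchor)
            ernas.append(erna_iv)
            truth["erna_interval"] = [erna_iv.start, erna_iv.end]
        enh_truth[enh.enh_id] = truth

    # ---- promoter peaks ---------------------------------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    for gene_id, info in expr_truth.items():
        if not info["expressed"]:
            info["promoter_offsets"] = {}
            continue
        gene = gene_by_id[gene_id]
        stratum = info["stratum"]
        height = profile.promoter_height[stratum]
        offsets: dict[str, int] = {}
        for factor, spec in profile.promoter_offsets.items():
            off = int(round(rng.normal(spec.mean, spec.sd)))
            summit = gene.tss + off if gene.strand == "+" else gene.tss - off
            peaks[factor].append(
                _point_peak(factor, gene.chrom, summit, height, f"{factor}_{gene_id}")
            )
            offsets[factor] = off
        info["promoter_offsets"] = offsets

    # promoter H3K27ac at active (expressed) genes: removed by the promoter
    # filter of the active-enhancer prediction rule
    for gene_id in sorted(expressed_ids):
        gene = gene_by_id[gene_id]
        lo = max(0, gene.tss - 1000)
        iv = GenomicInterval(gene.chrom, lo, gene.tss + 1001)
        peaks["H3K27ac"].append(Peak(iv, gene.tss, 4.0, f"H3K27ac_{gene_id}", "H3K27ac"))

    # ---- coverage tracks --------------------------------------------------
    tracks: dict[str, SignalTrack] = {}
    if with_tracks:
        factors = tuple(track_factors) if track_factors is not None else profile.track_factors
        for factor in factors:
            data = {c: np.zeros(genome[c] // bw) for c in chrom_names}
            for p in peaks[factor]:
                _stamp_triangle(data[p.chrom], bw, p.summit, p.score, profile.kernel_half_width)
            if factor == "Ser2p":
                for gene_id in sorted(expressed_ids):
                    g = gene_by_id[gene_id]
                    lo = min(g.tss, g.tes) // bw
                    hi = (max(g.tss, g.tes) + 1) // bw
                    data[g.chrom][lo:hi] += profile.ser2p_body_coverage
            if profile.noise_rate > 0:
                for c in chrom_names:
                    data[c] += rng.poisson(profile.noise_rate, len(data[c]))
            mass = float(sum(a.sum() for a in data.values()) * bw)
            tracks[factor] = SignalTrack(data=data, bin_width=bw, total_mass=mass, norm="raw")
            if factor == "Ser2p":
                tracks["Ser2p_kd"] = _knockdown_track(tracks["Ser2p"], enhancers, profile)

    plant_map = {
        "profile": profile.name,
        "seed": seed,
        "genome": genome,
        "params": {"ctr9_se_height": h_se},
        "genes": {
            g.gene_id: {
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "tes": g.tes,
                **expr_truth[g.gene_id],
            }
            for g in genes
        },
        "enhancers": enh_truth,
    }
    return SyntheticDataset(
        profile=profile,
        seed=seed,
        genome=genome,
        genes=genes,
        enhancers=enhancers,
        peaks=peaks,
        tracks=tracks,
        expression=expression,
        ernas=ernas,
        plant_map=plant_map,
    )


def _stamp_triangle(arr: np.ndarray, bin_width: int, summit: int, height: float, half_width: int) -> None:
    lo = max(0, (summit - half_width) // bin_width)
    hi = min(len(arr), (summit + half_width) // bin_width + 1)
    if hi <= lo:
        return
    x = (np.arange(lo, hi) + 0.5) * bin_width
    arr[lo:hi] += height * np.maximum(0.0, 1.0 - np.abs(x - summit) / half_width)


def _knockdown_track(
    control: SignalTrack,
    enhancers: Sequence[EnhancerRegion],
    profile: CalibrationProfile,
) -> SignalTrack:
    """Ser2p after knockdown: enhancer-local signal divided by the class
    divisor, everything else unchanged."""
    data = {c: a.copy() for c, a in control.data.items()}
    bw = control.bin_width
    for e in enhancers:
        div = profile.ser2p_kd_divisor[e.enh_class]
        lo = e.interval.start // bw
        hi = -(-e.interval.end // bw)
        arr = data.get(e.interval.chrom)
        if arr is not None:
            arr[lo:hi] /= div
    mass = float(sum(a.sum() for a in data.values()) * bw)
    return SignalTrack(data=data, bin_width=bw, total_mass=mass, norm="raw")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir: str | Path, write_tracks: bool = True) -> dict[str, str]:
    """Write the dataset in the formats the readers consume; returns a map
    of logical name to file path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for factor, plist in ds.peaks.items():
        p = outdir / f"peaks_{factor}.narrowPeak"
        write_narrowpeak(plist, p)
        paths[f"peaks_{factor}"] = str(p)
    write_gene_table(ds.genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    write_enhancers(ds.enhancers, outdir / "enhancers.bed")
    paths["enhancers"] = str(outdir / "enhancers.bed")
    write_expression(ds.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    write_bed(ds.ernas, outdir / "ernas.bed")
    paths["ernas"] = str(outdir / "ernas.bed")
    if write_tracks:
        for name, track in ds.tracks.items():
            p = outdir / f"track_{name}.bedGraph"
            write_bedgraph(track, p)
            paths[f"track_{name}"] = str(p)
    with open(outdir / "genome.json", "w") as fh:
        json.dump(ds.genome, fh, sort_keys=True, indent=1)
    paths["genome"] = str(outdir / "genome.json")
    with open(outdir / "plant_map.json", "w") as fh:
        json.dump(ds.plant_map, fh, sort_keys=True, indent=1)
    paths["plant_map"] = str(outdir / "plant_map.json")
    return paths
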