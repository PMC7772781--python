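"""Expression-stratified metagene profiles, TSS-window profiles, and
anchor-centered oriented heatmap matrices with quantile normalization.

Gene bodies are rescaled to a fixed number of bins by length-weighted
averaging (mass conserving); flanks keep fixed bp widths. Minus-strand genes
are profiled on their own 5'->3' axis, so "downstream" always means in the
direction of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genomic_io import ExpressionRecord, GeneModel, SignalTrack
from .positional import PairDistance
from .signal import resample, window_values

logger = logging.getLogger(__name__)

__all__ = [
    "expression_strata",
    "MetageneProfile",
    "scaled_gene_profile",
    "tss_window_profile",
    "HeatmapMatrix",
    "anchored_heatmap",
    "quantile_normalize",
]


def expression_strata(
    expression: Sequence[ExpressionRecord],
    expressed_threshold: float = 1.0,
) -> dict[str, list[str]]:
    """Partition genes into high / medium / low / silent expression strata.

    Genes below the expressed threshold (control tpm < 1 by default) are
    silent. The remaining genes are ranked by control tpm (ties broken by
    gene id); the top quarter is 'high', the bottom quarter 'low', and the
    middle half 'medium'.
    """
    if not expression:
        raise ValueError("empty expression table")
    silent = [r.gene_id for r in expression if r.tpm_control < expressed_threshold]
    expressed = sorted(
        (r for r in expression if r.tpm_control >= expressed_threshold),
        key=lambda r: (-r.tpm_control, r.gene_id),
    )
    n = len(expressed)
    n_high = int(round(n * 0.25))
    n_low = int(round(n * 0.25))
    high = [r.gene_id for r in expressed[:n_high]]
    low = [r.gene_id for r in expressed[n - n_low:]] if n_low else []
    medium = [r.gene_id for r in expressed[n_high:n - n_low]]
    return {"high": high, "medium": medium, "low": low, "silent": sorted(silent)}


@dataclass
class MetageneProfile:
    """Mean signal over a gene set on the flank / scaled-body / flank grid."""

    values: np.ndarray
    n_genes: int
    flank_bp: int
    body_bins: int
    flank_bins: int
    skipped: tuple[str, ...] = ()

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def _gene_axis_windows(gene: GeneModel) -> tuple[int, int]:
    """Body interval [lo, hi) covering TSS..TES inclusive."""
    lo = min(gene.tss, gene.tes)
    hi = max(gene.tss, gene.tes) + 1
    return lo, hi


def scaled_gene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    body_bins: int = 60,
    flank_bins: int = 20,
    scale_to_reads: float | None = None,
) -> MetageneProfile:
    """Average signal over genes after rescaling each body to ``body_bins``.

    Flanks are ``flank_bp`` wide at fixed bin size; the body is resampled by
    length-weighted averaging, which conserves mass per gene up to float
    rounding. Genes shorter than ``body_bins`` bp are skipped with a warning.
    When ``scale_to_reads`` is given and the track is rpm-normalized, values
    are rescaled so the track total corresponds to that many reads (e.g.
    1e7 for a 10-million-read scale).
    """
    rows: list[np.ndarray] = []
    skipped: list[str] = []
    for gene in genes:
        lo, hi = _gene_axis_windows(gene)
        if hi - lo < body_bins:
            logger.warning("gene %s shorter than %d bp; skipped", gene.gene_id, body_bins)
            skipped.append(gene.gene_id)
            continue
        up = resample(track, gene.chrom, lo - flank_bp, lo, flank_bins)
        body = resample(track, gene.chrom, lo, hi, body_bins)
        down = resample(track, gene.chrom, hi, hi + flank_bp, flank_bins)
        row = np.concatenate([up, body, down])
        if gene.strand == "-":
            row = row[::-1]
        rows.append(row)
    n = len(rows)
    n_bins = 2 * flank_bins + body_bins
    values = np.mean(rows, axis=0) if rows else np.zeros(n_bins)
    if scale_to_reads is not None and track.norm == "rpm":
        values = values * (scale_to_reads / 1e6)
    return MetageneProfile(
        values=values,
        n_genes=n,
        flank_bp=flank_bp,
        body_bins=body_bins,
        flank_bins=flank_bins,
        skipped=tuple(skipped),
    )


def tss_window_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    window_bp: int = 4000,
) -> np.ndarray:
    """Mean coverage across a strand-corrected fixed window centered on the
    TSS of every gene, at track bin resolution."""
    rows = []
    for gene in genes:
        row = window_values(track, gene.chrom, gene.tss + 0.5, window_bp)
        if gene.strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        return np.zeros(max(1, window_bp // track.bin_width))
    return np.mean(rows, axis=0)


@dataclass
class HeatmapMatrix:
    """Anchor-centered signal matrix: one row per anchored region."""

    matrix: np.ndarray
    row_ids: tuple[str, ...]
    flipped: tuple[bool, ...]
    padded: tuple[bool, ...]
    window_bp: int


def anchored_heatmap(
    tracks: Mapping[str, SignalTrack],
    anchors: Sequence[PairDistance],
    window_bp: int = 2000,
) -> dict[str, HeatmapMatrix]:
    """Per-factor matrices of windows centered on NELFA summits, oriented so
    the nearest Ctr9 summit always lies to the right.

    Rows whose nearest Ctr9 summit has a lower coordinate than the anchor
    are reversed. Windows running past a chromosome end read as zero and the
    row is flagged padded.
    """
    out: dict[str, HeatmapMatrix] = {}
    usable = [a for a in anchors]
    for factor, track in tracks.items():
        rows, ids, flips, pads = [], [], [], []
        for a in usable:
            row = window_values(track, a.chrom, a.nelfa_summit + 0.5, window_bp)
            half = window_bp / 2.0
            pad = (
                a.nelfa_summit + 0.5 - half < 0
                or a.nelfa_summit + 0.5 + half > track.chrom_size(a.chrom)
            )
            flip = a.nearest_ctr9 is not None and a.nearest_ctr9 < a.nelfa_summit
            if flip:
                row = row[::-1]
            rows.append(row)
            ids.append(a.region_id)
            flips.append(flip)
            pads.append(pad)
        matrix = np.vstack(rows) if rows else np.zeros((0, max(1, window_bp // track.bin_width)))
        out[factor] = HeatmapMatrix(
            matrix=matrix,
            row_ids=tuple(ids),
            flipped=tuple(flips),
            padded=tuple(pads),
            window_bp=window_bp,
        )
    return out


def quantile_normalize(matrices: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Quantile-normalize a set of equally sized matrices against the mean
    order-statistic distribution across them.

    All values of each matrix are pooled, ranked (ties averaged), and mapped
    onto the reference distribution; the mapping is monotone, so within-row
    rank order is preserved.
    """
    keys = list(matrices)
    if not keys:
        return {}
    shapes = {matrices[k].shape for k in keys}
    if len(shapes) != 1:
        raise ValueError(f"matrices differ in shape: {sorted(shapes)}")
    flats = {k: np.asarray(matrices[k], dtype=float).ravel() for k in keys}
    n = len(next(iter(flats.values())))
    if n == 0:
        return {k: matrices[k].copy() for k in keys}
    reference = np.mean([np.sort(v) for v in flats.values()], axis=0)
    out: dict[str, np.ndarray] = {}
    positions = np.arange(1, n + 1, dtype=float)
    for k in keys:
        ranks = sps.rankdata(flats[k])  # average ties
        mapped = np.interp(ranks, positions, reference)
        out[k] = mapped.reshape(matrices[k].shape)
    return out
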