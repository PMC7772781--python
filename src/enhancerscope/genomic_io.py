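"""Core genomic record types and text-format readers/writers.

Every coordinate inside the package is 0-based half-open (BED convention).
The one deliberately 1-based surface is the gene table on disk, whose TSS and
TES columns follow the 1-based convention of common annotation exports; the
reader converts to 0-based point coordinates and the writer converts back.

Chromosome names are compared by exact string match: ``chr1`` and ``1`` are
different sequences as far as this package is concerned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")
ENHANCER_CLASSES = ("SE", "TE")

__all__ = [
    "FormatError",
    "ValidationError",
    "DegenerateTrackError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "EnhancerRegion",
    "SignalTrack",
    "ExpressionRecord",
    "parse_narrowpeak",
    "write_narrowpeak",
    "parse_bed",
    "write_bed",
    "parse_enhancers",
    "write_enhancers",
    "parse_gene_table",
    "write_gene_table",
    "parse_expression",
    "write_expression",
    "parse_bedgraph",
    "write_bedgraph",
    "to_rpm",
]


class FormatError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class DegenerateTrackError(ValueError):
    """A signal track with zero total mass cannot be normalized."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic region, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """Called peak: an interval with the summit (max pileup position) inside it."""

    interval: GenomicInterval
    summit: int
    score: float
    name: str
    factor: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end} for peak {self.name}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """Gene anchors: TSS and TES as 0-based point coordinates.

    On the plus strand ``tss < tes``; on the minus strand ``tss > tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValidationError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValidationError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def span(self) -> GenomicInterval:
        """Interval covering the gene body (both anchors inclusive)."""
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand)


@dataclass(frozen=True)
class EnhancerRegion:
    """Annotated enhancer with its class (SE = super enhancer, TE = typical)."""

    interval: GenomicInterval
    enh_class: str
    enh_id: str
    target_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.enh_class not in ENHANCER_CLASSES:
            raise ValidationError(
                f"enhancer {self.enh_id}: class {self.enh_class!r} not in "
                f"{ENHANCER_CLASSES}"
            )


@dataclass
class SignalTrack:
    """Binned genome coverage. ``data`` maps chromosome to a per-bin array.

    ``total_mass`` is the integral of the raw track (value x bp); an rpm track
    keeps the raw total mass so normalization state is invertible.
    """

    data: dict[str, np.ndarray]
    bin_width: int
    total_mass: float
    norm: str = "raw"
    _cum: dict = field(default_factory=dict, repr=False, compare=False)

    def values(self, chrom: str) -> np.ndarray:
        arr = self.data.get(chrom)
        if arr is None:
            return np.zeros(0)
        return arr

    def cumulative(self, chrom: str) -> np.ndarray:
        """Cached cumulative mass at bin boundaries (length n_bins + 1).

        Invalidated only by constructing a new track; callers must not
        mutate ``data`` after the first query.
        """
        cum = self._cum.get(chrom)
        if cum is None:
            arr = self.values(chrom)
            cum = np.concatenate(([0.0], np.cumsum(arr, dtype=float) * self.bin_width))
            self._cum[chrom] = cum
        return cum

    def chrom_size(self, chrom: str) -> int:
        return len(self.values(chrom)) * self.bin_width

    def mass(self) -> float:
        """Integral of the stored values (equals total_mass for raw tracks)."""
        return float(
            sum(float(a.sum()) for a in self.data.values()) * self.bin_width
        )


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression in control and knockdown, with derived fields."""

    gene_id: str
    tpm_control: float
    tpm_knockdown: float
    log2fc: float | None = None
    group: str = "other"

    def __post_init__(self) -> None:
        if self.tpm_control < 0 or self.tpm_knockdown < 0:
            raise ValidationError(f"gene {self.gene_id}: negative tpm")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def parse_narrowpeak(path: str | Path, factor: str) -> list[Peak]:
    """Read a 10-column narrowPeak file into :class:`Peak` records.

    Column 10 is the summit offset from the interval start; ``-1`` means the
    caller did not report a summit, in which case the interval midpoint
    (floored) is used.
    """
    peaks: list[Peak] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) != 10:
            raise FormatError(
                f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
            )
        try:
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            score = float(fields[6])
            offset = int(fields[9])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        interval = GenomicInterval(chrom, start, end, strand if strand in VALID_STRANDS else ".")
        if offset >= interval.length:
            raise ValidationError(
                f"{path}:{lineno}: summit offset {offset} >= length {interval.length}"
            )
        summit = start + offset if offset >= 0 else start + interval.length // 2
        peaks.append(Peak(interval, summit, score, name, factor))
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        "0",
                        p.interval.strand,
                        _fmt(p.score),
                        "-1",
                        "-1",
                        str(p.summit - p.interval.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / enhancers
# ---------------------------------------------------------------------------

def parse_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals; column 6 (if present) is the strand."""
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
        try:
            out.append(GenomicInterval(chrom, start, end, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def parse_enhancers(path: str | Path) -> list[EnhancerRegion]:
    """Read an enhancer BED: chrom, start, end, class, id[, target genes].

    Target genes (column 6) are comma-separated; the column may be absent or
    '.' for enhancers without assigned targets.
    """
    out: list[EnhancerRegion] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: expected >= 5 enhancer columns")
        try:
            interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        enh_class, enh_id = fields[3], fields[4]
        targets: tuple[str, ...] = ()
        if len(fields) >= 6 and fields[5] not in (".", ""):
            targets = tuple(fields[5].split(","))
        try:
            out.append(EnhancerRegion(interval, enh_class, enh_id, targets))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_enhancers(regions: Sequence[EnhancerRegion], path: str | Path) -> None:
    rows = sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    with open(path, "w") as fh:
        for r in rows:
            targets = ",".join(r.target_genes) if r.target_genes else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.enh_class}\t{r.enh_id}\t{targets}\n"
            )


# ---------------------------------------------------------------------------
# gene table (TSV, 1-based on disk)
# ---------------------------------------------------------------------------

_GENE_HEADER = ["gene_id", "chrom", "strand", "tss", "tes"]


def parse_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the gene TSV (header: gene_id, chrom, strand, tss, tes; 1-based)."""
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != _GENE_HEADER:
        raise FormatError(f"{path}: expected header {_GENE_HEADER}")
    out: list[GeneModel] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        try:
            out.append(
                GeneModel(fields[0], fields[1], fields[2], int(fields[3]) - 1, int(fields[4]) - 1)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, min(g.tss, g.tes), g.gene_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in rows:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss + 1}\t{g.tes + 1}\n")


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

_EXPR_HEADER = ["gene_id", "tpm_control", "tpm_knockdown", "group"]


def parse_expression(path: str | Path, collapse_transcripts: bool = True) -> list[ExpressionRecord]:
    """Read the expression TSV.

    If the same gene id occurs on several rows (a transcript-level table),
    the row with the highest control tpm is kept as the gene's representative
    when ``collapse_transcripts`` is true.
    """
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != _EXPR_HEADER:
        raise FormatError(f"{path}: expected header {_EXPR_HEADER}")
    best: dict[str, ExpressionRecord] = {}
    order: list[str] = []
    out: list[ExpressionRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        try:
            rec = ExpressionRecord(fields[0], float(fields[1]), float(fields[2]), None, fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if not collapse_transcripts:
            out.append(rec)
            continue
        prev = best.get(rec.gene_id)
        if prev is None:
            order.append(rec.gene_id)
            best[rec.gene_id] = rec
        elif rec.tpm_control > prev.tpm_control:
            best[rec.gene_id] = rec
    if collapse_transcripts:
        return [best[g] for g in order]
    return out


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    rows = sorted(records, key=lambda r: r.gene_id)
    with open(path, "w") as fh:
        fh.write("\t".join(_EXPR_HEADER) + "\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{_fmt(r.tpm_control)}\t{_fmt(r.tpm_knockdown)}\t{r.group}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / SignalTrack
# ---------------------------------------------------------------------------

def parse_bedgraph(
    path: str | Path,
    bin_width: int,
    chrom_sizes: dict[str, int] | None = None,
) -> SignalTrack:
    """Read a bedGraph into a binned track.

    Interval values are length-weighted into bins, so interval boundaries do
    not need to align with the bin grid. ``chrom_sizes`` (bp) fixes array
    lengths; otherwise each chromosome extends to its last covered base.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    total_mass = 0.0
    for lineno, line in enumerate(_read_lines(path), start=1):
        if line.startswith(("track", "#")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if end <= start:
            raise ValidationError(f"{path}:{lineno}: end <= start")
        per_chrom.setdefault(chrom, []).append((start, end, value))
        total_mass += value * (end - start)

    data: dict[str, np.ndarray] = {}
    sizes = dict(chrom_sizes or {})
    for chrom, ivs in per_chrom.items():
        size = sizes.get(chrom, max(end for _, end, _ in ivs))
        n_bins = -(-size // bin_width)
        arr = np.zeros(n_bins)
        for start, end, value in ivs:
            lo, hi = start // bin_width, -(-end // bin_width)
            for b in range(lo, min(hi, n_bins)):
                b0, b1 = b * bin_width, (b + 1) * bin_width
                overlap = min(end, b1) - max(start, b0)
                arr[b] += value * overlap / bin_width
        data[chrom] = arr
    for chrom, size in sizes.items():
        if chrom not in data:
            data[chrom] = np.zeros(-(-size // bin_width))
    return SignalTrack(data=data, bin_width=bin_width, total_mass=total_mass, norm="raw")


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length merging equal adjacent bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(arr)]))
            w = track.bin_width
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * w}\t{e * w}\t{_fmt(float(v))}\n")


def to_rpm(track: SignalTrack) -> SignalTrack:
    """Scale a raw track to reads per million: value x 1e6 / total mass."""
    if track.norm == "rpm":
        return track
    if track.total_mass <= 0:
        raise DegenerateTrackError("cannot rpm-normalize a track with zero total mass")
    factor = 1e6 / track.total_mass
    data = {c: a * factor for c, a in track.data.items()}
    return SignalTrack(data=data, bin_width=track.bin_width, total_mass=track.total_mass, norm="rpm")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _fmt(x: float) -> str:
    """Canonical numeric formatting shared by all writers (round-trip stable)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))
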