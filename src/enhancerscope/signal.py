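"""Exact extraction of mass and resampled values from binned coverage tracks.

A :class:`~enhancerscope.genomic_io.SignalTrack` is piecewise constant: bin
``i`` has value ``arr[i]`` (coverage depth per bp) on ``[i*w, (i+1)*w)``.
All helpers here integrate that step function exactly, so downstream profile
and density computations are length-weighted at bin edges rather than
nearest-bin approximations. Positions outside the stored array contribute
zero mass. Per-chromosome cumulative sums are cached on the track, so
repeated region queries cost O(query) rather than O(chromosome).
"""

from __future__ import annotations

import numpy as np

from .genomic_io import SignalTrack


def cumulative_mass_at(track: SignalTrack, chrom: str, xs) -> np.ndarray:
    """Integral of the track's step function from 0 to each position in ``xs``."""
    arr = track.values(chrom)
    w = track.bin_width
    n = len(arr)
    xs = np.clip(np.asarray(xs, dtype=float), 0.0, n * w)
    k = np.minimum((xs // w).astype(int), n)
    cum = track.cumulative(chrom)
    if n == 0:
        return np.zeros_like(xs)
    vals = np.asarray(arr, dtype=float)[np.minimum(k, n - 1)]
    part = np.where(k < n, vals * (xs - k * w), 0.0)
    return cum[k] + part


def interval_mass(track: SignalTrack, chrom: str, start: float, end: float) -> float:
    """Track mass (value x bp) over [start, end)."""
    lo, hi = cumulative_mass_at(track, chrom, np.array([start, end]))
    return float(hi - lo)


def resample(
    track: SignalTrack, chrom: str, start: float, end: float, n_bins: int
) -> np.ndarray:
    """Length-weighted mean values over ``n_bins`` equal sub-intervals of
    [start, end). Regions outside the chromosome read as zero."""
    if end <= start:
        raise ValueError("end must exceed start")
    edges = np.linspace(start, end, n_bins + 1)
    masses = np.diff(cumulative_mass_at(track, chrom, edges))
    widths = np.diff(edges)
    return masses / widths


def window_values(
    track: SignalTrack, chrom: str, center: float, window_bp: int
) -> np.ndarray:
    """Values across a window centered on ``center`` at track bin resolution."""
    n_bins = max(1, int(round(window_bp / track.bin_width)))
    half = window_bp / 2.0
    return resample(track, chrom, center - half, center + half, n_bins)
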