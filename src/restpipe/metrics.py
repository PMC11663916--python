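"""Local resting-state activity metrics: ALFF, fALFF and ReHo.

ALFF is the mean one-sided amplitude spectrum of a voxel's series inside the
low-frequency band (0.01-0.10 Hz by convention). fALFF is the in-band
amplitude sum divided by the full-band sum, computed on the *unfiltered*
(post-regression) series since the denominator is the whole spectrum by
definition. ReHo is Kendall's coefficient of concordance (W) between a
voxel's time-series ranks and those of its neighbors.

Amplitude convention: a(f) = 2|DFT(x)|/T at interior positive frequencies,
|DFT(x)|/T at DC and Nyquist (one-sided spectrum). Any consistent convention
cancels in fALFF and in standardized group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .core_io import BoldRun, BrainMask, GridError, StatMap
from .preprocess import BandDefinition, BandError

__all__ = [
    "NeighborhoodSpec",
    "amplitude_spectrum",
    "alff",
    "falff",
    "reho",
    "kendall_w",
    "standardize_map",
    "DegenerateMapError",
]


class DegenerateMapError(ValueError):
    """Map has no variance inside the mask; standardization undefined."""


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Cubic voxel neighborhood: 7 (faces), 19 (faces+edges) or 27 (full)."""

    n_voxels: int = 27

    def __post_init__(self) -> None:
        if self.n_voxels not in (7, 19, 27):
            raise ValueError(f"neighborhood must be 7, 19 or 27, got {self.n_voxels}")

    def kernel(self) -> np.ndarray:
        """3x3x3 boolean stencil (center included)."""
        offsets = np.abs(np.indices((3, 3, 3)) - 1)  # per-axis |offset|
        nonzero = (offsets > 0).sum(axis=0)
        if self.n_voxels == 7:
            return nonzero <= 1
        if self.n_voxels == 19:
            return nonzero <= 2
        return np.ones((3, 3, 3), dtype=bool)


def _check_grids(run: BoldRun, mask: BrainMask) -> None:
    if not run.grid.matches(mask.grid):
        raise GridError("run and mask grids differ")


def amplitude_spectrum(data: np.ndarray, tr_s: float):
    """One-sided amplitude spectrum along the last axis.

    Returns ``(freqs, amps)`` with the 2/T doubling applied to interior bins
    only, so that the sum of squared amplitudes over nonzero bins equals
    (2/T) x signal energy for zero-mean, Nyquist-free series (Parseval).
    """
    T = data.shape[-1]
    spectrum = np.abs(np.fft.rfft(data, axis=-1)) / T
    freqs = np.fft.rfftfreq(T, d=tr_s)
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if T % 2 == 0:  # Nyquist bin is unpaired
        scale[-1] = 1.0
    return freqs, spectrum * scale


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    bins = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not bins.any():
        raise BandError(
            f"no frequency bin falls inside [{band.low_hz}, {band.high_hz}] Hz"
        )
    return bins


def alff(run: BoldRun, band: BandDefinition, mask: BrainMask) -> StatMap:
    """Mean in-band amplitude per voxel; out-of-mask voxels set to 0."""
    _check_grids(run, mask)
    freqs, amps = amplitude_spectrum(run.data, run.tr_s)
    bins = _band_bins(freqs, band)
    values = amps[..., bins].mean(axis=-1)
    values[~mask.include] = 0.0
    return StatMap(values, run.grid, kind="alff")


def falff(run_fullband: BoldRun, band: BandDefinition, mask: BrainMask) -> StatMap:
    """In-band amplitude sum over full-band (0 < f <= Nyquist) amplitude sum.

    Expects the NOT band-passed (post-regression) series; voxels whose total
    amplitude is zero get fALFF 0.
    """
    _check_grids(run_fullband, mask)
    freqs, amps = amplitude_spectrum(run_fullband.data, run_fullband.tr_s)
    bins = _band_bins(freqs, band)
    numer = amps[..., bins].sum(axis=-1)
    denom = amps[..., freqs > 0].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    values[~mask.include] = 0.0
    return StatMap(values, run_fullband.grid, kind="falff")


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K series of length T.

    Ranks each series over time (average ranks on ties, no tie correction)
    and applies W = 12 S / (K^2 (T^3 - T)) where S is the sum of squared
    deviations of the per-timepoint rank sums from their mean.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected K x T array")
    K, T = series.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    if K < 2:
        return 0.0
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    S = ((rank_sums - rank_sums.mean()) ** 2).sum()
    return float(12.0 * S / (K**2 * (T**3 - T)))


def reho(
    run: BoldRun,
    mask: BrainMask,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(27),
) -> StatMap:
    """ReHo map: Kendall's W of each in-mask voxel with its in-mask neighbors.

    At mask edges the neighborhood shrinks to the available in-mask voxels
    (no zero padding); voxels with fewer than 2 in-mask neighbors get 0.

    The vectorized form exploits that the mean rank sum is K(T+1)/2 exactly,
    so only the neighborhood rank sums and counts are needed.
    """
    _check_grids(run, mask)
    T = run.n_volumes
    if T < 3:
        raise ValueError("ReHo needs at least 3 time points")
    kernel = nbhd.kernel().astype(float)

    ranks = rankdata(run.data, axis=-1).astype(float)
    ranks[~mask.include] = 0.0

    K = ndimage.correlate(mask.include.astype(float), kernel, mode="constant", cval=0.0)
    K = np.rint(K)
    # rank sums per timepoint over the (in-mask) neighborhood
    kernel4 = kernel[..., None]
    rank_sums = ndimage.correlate(ranks, kernel4, mode="constant", cval=0.0)
    mean_rank_sum = K[..., None] * (T + 1) / 2.0
    S = ((rank_sums - mean_rank_sum) ** 2).sum(axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        W = 12.0 * S / (K**2 * (T**3 - T))
    W[K < 2] = 0.0
    W[~mask.include] = 0.0
    W = np.clip(W, 0.0, 1.0)
    return StatMap(W, run.grid, kind="reho")


def standardize_map(stat_map: StatMap, mask: BrainMask) -> StatMap:
    """Z-standardize within the mask: (v - mean) / sd, population sd.

    Out-of-mask voxels are zeroed. Used to make metric maps comparable across
    subjects (and sites) before group testing.
    """
    if not stat_map.grid.matches(mask.grid):
        raise GridError("map and mask grids differ")
    inside = stat_map.values[mask.include]
    if inside.size < 2:
        raise DegenerateMapError("need at least 2 in-mask voxels")
    sd = inside.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateMapError("map has zero variance inside the mask")
    values = np.zeros_like(stat_map.values)
    values[mask.include] = (inside - inside.mean()) / sd
    return StatMap(values, stat_map.grid, kind="zmap")
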