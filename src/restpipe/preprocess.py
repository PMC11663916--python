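"""BOLD preprocessing: volume discard, motion screening, nuisance regression,
band-pass filtering and Gaussian smoothing.

The pipeline order is fixed: discard initial volumes, regress nuisance
covariates (linear trend, CSF and white-matter mean signals, Friston-24 motion
expansion — deliberately no global signal), band-pass filter, smooth. Spatial
smoothing is applied to metric *maps* rather than to the series (see the
methods note for why ReHo forces that choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BoldRun, BrainMask, GridError, MotionTrace, StatMap

__all__ = [
    "BandDefinition",
    "NuisanceDesign",
    "BandError",
    "discard_initial_volumes",
    "motion_exclusion_flag",
    "friston24",
    "build_nuisance_design",
    "nuisance_regress",
    "bandpass",
    "smooth_gaussian",
    "FWHM_TO_SIGMA",
]

logger = logging.getLogger(__name__)

#: sigma = FWHM * this factor (1 / (2 sqrt(2 ln 2)))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class BandError(ValueError):
    """Frequency band incompatible with the sampling rate."""


@dataclass(frozen=True)
class BandDefinition:
    """A pass band in Hz; the study convention is 0.01-0.10 Hz."""

    low_hz: float = 0.01
    high_hz: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise BandError(f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})")

    def validate_for_tr(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if self.high_hz > nyquist:
            raise BandError(
                f"band upper edge {self.high_hz} Hz above Nyquist {nyquist:.4f} Hz"
            )


@dataclass
class NuisanceDesign:
    """T x K regressor matrix with named columns."""

    matrix: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != len(self.column_names):
            raise ValueError("design matrix / column-name mismatch")
        self.matrix = matrix

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def discard_initial_volumes(run: BoldRun, n_discard: int = 10) -> BoldRun:
    """Drop the first ``n_discard`` volumes (and matching motion rows)."""
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= run.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {run.n_volumes} volumes"
        )
    if n_discard == 0:
        return run
    motion = run.motion
    if motion is not None:
        motion = MotionTrace(motion.values[n_discard:])
    return run.with_data(run.data[..., n_discard:], motion=motion)


def motion_exclusion_flag(
    trace: MotionTrace, trans_mm: float = 3.0, rot_deg: float = 3.0
) -> bool:
    """True (exclude) iff any |translation| > trans_mm or |rotation| > rot_deg.

    Strict inequality: a run sitting exactly at the threshold is retained.
    """
    if trace.n_volumes == 0:
        raise ValueError("empty motion trace")
    max_trans = np.abs(trace.translations_mm).max()
    max_rot = np.abs(trace.rotations_deg).max()
    return bool(max_trans > trans_mm or max_rot > rot_deg)


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns: the 6 parameters, their one-volume lags (zero first row), the
    squares of both sets.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"expected T x 6 motion matrix, got {motion6.shape}")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    lagged = np.zeros_like(motion6)
    lagged[1:] = motion6[:-1]
    return np.hstack([motion6, lagged, motion6**2, lagged**2])


def build_nuisance_design(
    run: BoldRun, csf_mask: BrainMask, wm_mask: BrainMask
) -> NuisanceDesign:
    """Constant + centered linear trend + CSF mean + WM mean + Friston-24.

    Global signal regression is deliberately not part of the design.
    """
    for mask, name in ((csf_mask, "csf"), (wm_mask, "wm")):
        if not mask.grid.matches(run.grid):
            raise GridError(f"{name} mask grid differs from run grid")
    T = run.n_volumes
    columns = [np.ones(T)]
    names = ["constant"]
    trend = np.arange(T, dtype=float)
    columns.append(trend - trend.mean())
    names.append("linear_trend")
    columns.append(run.data[csf_mask.include].mean(axis=0))
    names.append("csf")
    columns.append(run.data[wm_mask.include].mean(axis=0))
    names.append("wm")
    if run.motion is None:
        raise ValueError("run has no motion trace; cannot build Friston-24 columns")
    if run.motion.n_volumes != T:
        raise ValueError("motion trace length does not match volume count")
    f24 = friston24(run.motion.values)
    for j in range(24):
        columns.append(f24[:, j])
        names.append(f"motion{j + 1}")
    return NuisanceDesign(np.column_stack(columns), names)


def nuisance_regress(run: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Per-voxel OLS residuals against the nuisance design.

    Uses the pseudo-inverse, so a rank-deficient design (warned about) still
    yields the minimum-norm projection; residuals are orthogonal to every
    design column either way.
    """
    X = design.matrix
    if X.shape[0] != run.n_volumes:
        raise ValueError("design rows do not match volume count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "nuisance design is rank deficient (%d < %d); using pseudo-inverse",
            rank,
            X.shape[1],
        )
    pinv = np.linalg.pinv(X)
    flat = run.data.reshape(-1, run.n_volumes)
    beta = flat @ pinv.T  # (V, K)
    resid = flat - beta @ X.T
    return run.with_data(resid.reshape(run.data.shape))


def _bandpass_series(series: np.ndarray, low_hz: float, high_hz: float, tr_s: float):
    """Ideal (boxcar) frequency-domain filter along the last axis."""
    T = series.shape[-1]
    spectrum = np.fft.rfft(series, axis=-1)
    freqs = np.fft.rfftfreq(T, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum[..., ~keep] = 0.0
    return np.fft.irfft(spectrum, n=T, axis=-1)


def bandpass(run: BoldRun, band: BandDefinition) -> BoldRun:
    """Ideal band-pass filter: DFT, zero out-of-band bins, inverse DFT.

    Band edges are kept (closed interval); the DC bin is always removed, so
    the output is zero-mean.
    """
    band.validate_for_tr(run.tr_s)
    freqs = np.fft.rfftfreq(run.n_volumes, d=run.tr_s)
    if not ((freqs >= band.low_hz) & (freqs <= band.high_hz)).any():
        raise BandError(
            f"no DFT bin falls inside [{band.low_hz}, {band.high_hz}] Hz "
            f"with {run.n_volumes} volumes at TR {run.tr_s}s"
        )
    filtered = _bandpass_series(run.data, band.low_hz, band.high_hz, run.tr_s)
    return run.with_data(filtered)


def smooth_gaussian(obj: StatMap | BoldRun, fwhm_mm) -> StatMap | BoldRun:
    """Separable Gaussian smoothing with FWHM given in mm (scalar or 3-vector).

    Reflect boundary handling; a 4D run is smoothed volume by volume.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if (fwhm < 0).any():
        raise ValueError("FWHM components must be >= 0")
    sigma_vox = fwhm * FWHM_TO_SIGMA / obj.grid.voxel_size_mm
    if isinstance(obj, BoldRun):
        sigma = tuple(sigma_vox) + (0.0,)
        smoothed = ndimage.gaussian_filter(obj.data, sigma=sigma, mode="reflect")
        return obj.with_data(smoothed)
    if isinstance(obj, StatMap):
        smoothed = ndimage.gaussian_filter(obj.values, sigma=tuple(sigma_vox), mode="reflect")
        return StatMap(smoothed, obj.grid, kind=obj.kind, df=obj.df)
    raise TypeError(f"cannot smooth object of type {type(obj)!r}")
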