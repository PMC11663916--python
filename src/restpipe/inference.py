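"""Voxelwise two-sample inference with cluster-level multiple-comparison
control.

Two corrections are provided, mirroring the usual robustness pairing in
resting-state studies:

* Gaussian random field (GRF) cluster-level correction at voxel p < 0.001 and
  cluster p < 0.05, two-tailed (alpha split across tails, tails analyzed
  independently), using the expected-Euler-characteristic cluster-size
  distribution for thresholded fields;
* voxelwise Benjamini-Hochberg FDR at q = 0.05 with a minimum cluster extent
  (50 voxels by convention).

Smoothness (FWHM, resels) is estimated from standardized residual maps via
the variance of their spatial first differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core_io import BrainMask, Cluster, ClusterTable, GridError, StatMap

__all__ = [
    "GrfSettings",
    "FdrSettings",
    "SmoothnessEstimate",
    "voxelwise_ttest",
    "group_residual_maps",
    "estimate_smoothness",
    "grf_cluster_correct",
    "fdr_correct",
    "extract_clusters",
    "connectivity_structure",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrfSettings:
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p < 1 or not 0 < self.cluster_p < 1:
            raise ValueError("voxel_p and cluster_p must lie in (0, 1)")


@dataclass(frozen=True)
class FdrSettings:
    q: float = 0.05
    min_extent_voxels: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.min_extent_voxels < 0:
            raise ValueError("min_extent_voxels must be >= 0")


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Per-axis FWHM in mm and the resel count of the analysis mask."""

    fwhm_mm: tuple[float, float, float]
    resels: float

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_mm) or self.resels <= 0:
            raise ValueError("FWHM components and resels must be positive")


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for 6-, 18- or 26-connected components."""
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order)


def _stack(maps: list[StatMap], mask: BrainMask) -> np.ndarray:
    grids = [m.grid for m in maps]
    for g in grids:
        if not g.matches(mask.grid):
            raise GridError("map grid differs from mask grid")
    return np.stack([m.values for m in maps], axis=0)


def voxelwise_ttest(
    maps_a: list[StatMap], maps_b: list[StatMap], mask: BrainMask, welch: bool = False
) -> StatMap:
    """Two-sample t map (group a minus group b), pooled variance by default.

    Pooled (Student) t is the SPM-family convention; ``welch`` switches to
    unequal-variance standard errors with Welch-Satterthwaite df (rounded
    down). Zero-variance voxels get t = 0 (count logged).
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    a = _stack(maps_a, mask)
    b = _stack(maps_b, mask)
    na, nb = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss_a = ((a - mean_a) ** 2).sum(axis=0)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    if welch:
        va = ss_a / (na - 1) / na
        vb = ss_b / (nb - 1) / nb
        se = np.sqrt(va + vb)
        with np.errstate(invalid="ignore", divide="ignore"):
            df_map = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        df = int(np.floor(np.nanmedian(df_map[mask.include & (se > 0)])))
        df = max(df, 2)
    else:
        df = na + nb - 2
        pooled_var = (ss_a + ss_b) / df
        se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1.0), 0.0)
    t[~mask.include] = 0.0
    n_flat = int(((se == 0) & mask.include).sum())
    if n_flat:
        logger.info("voxelwise_ttest: %d zero-variance in-mask voxels set to t=0", n_flat)
    return StatMap(t, mask.grid, kind="tmap", df=df)


def group_residual_maps(
    maps_a: list[StatMap], maps_b: list[StatMap], mask: BrainMask
) -> list[StatMap]:
    """Within-group demeaned maps — the residuals of the two-sample model."""
    out = []
    for group in (maps_a, maps_b):
        stack = _stack(group, mask)
        resid = stack - stack.mean(axis=0)
        for r in resid:
            out.append(StatMap(r, mask.grid, kind="zmap"))
    return out


def estimate_smoothness(
    residual_maps: list[StatMap], mask: BrainMask
) -> SmoothnessEstimate:
    """Estimate map smoothness from standardized residuals.

    Each residual map is standardized by its in-mask mean and sd (map-level,
    not voxel-level: voxelwise normalization with few maps injects sampling
    noise that biases the estimate rough). For each axis the pooled variance
    of first differences between in-mask neighbor pairs gives Lambda_i;
    FWHM_i = sqrt(4 ln 2 / Lambda_i) voxels. Resels = in-mask voxel count
    divided by the product of the FWHMs in voxel units. Assumes approximate
    stationarity of the residual field.
    """
    if len(residual_maps) < 2:
        raise ValueError("need at least 2 residual maps")
    resid = _stack(residual_maps, mask)
    inside = resid[:, mask.include]
    sd = inside.std(axis=1, ddof=0)
    if not (sd > 0).all() or not np.isfinite(sd).all():
        raise ValueError("a residual map is flat inside the mask; smoothness undefined")
    z = (resid - inside.mean(axis=1)[:, None, None, None]) / sd[:, None, None, None]
    z = np.where(mask.include, z, np.nan)

    voxel_mm = mask.grid.voxel_size_mm
    fwhm_mm = []
    fwhm_vox = []
    for axis in range(3):
        d = np.diff(z, axis=axis + 1)
        pair_ok = ~np.isnan(d)
        if pair_ok.sum() == 0:
            raise ValueError(f"no neighbor pairs along axis {axis}")
        lam = np.nanmean(d**2)
        if lam <= 0:
            raise ValueError("degenerate smoothness: zero derivative variance")
        f_vox = float(np.sqrt(4.0 * np.log(2.0) / lam))
        fwhm_vox.append(f_vox)
        fwhm_mm.append(f_vox * float(voxel_mm[axis]))
    resels = float(mask.n_voxels / np.prod(fwhm_vox))
    return SmoothnessEstimate(tuple(fwhm_mm), resels)


def _ec_density_3d_t(u: float, df: int) -> float:
    """3D Euler-characteristic density of a unit-variance t field at height u."""
    return (
        (4.0 * np.log(2.0)) ** 1.5
        / (2.0 * np.pi) ** 2
        * ((df - 1.0) / df * u**2 - 1.0)
        * (1.0 + u**2 / df) ** (-(df - 1.0) / 2.0)
    )


def grf_cluster_p(
    extent_voxels: int,
    t_threshold: float,
    df: int,
    n_mask_voxels: int,
    resels: float,
) -> float:
    """Corrected cluster-level p for a cluster of given extent in a t field.

    Standard random-field results at cluster-forming height u: expected
    cluster count E[m] = resels x t-field EC density; expected suprathreshold
    volume = mask size x P(T_df > u); cluster sizes follow
    P(n >= k) = exp(-beta k^(2/3)) with beta = (Gamma(5/2) / nbar)^(2/3)
    where nbar = E[volume] / E[m]; corrected p = 1 - exp(-E[m] P(n >= k)).
    """
    p_height = float(stats.t.sf(t_threshold, df))
    expected_clusters = max(resels * _ec_density_3d_t(t_threshold, df), 1e-12)
    expected_voxels = n_mask_voxels * p_height
    nbar = max(expected_voxels / expected_clusters, 1e-12)
    beta = (math.gamma(2.5) / nbar) ** (2.0 / 3.0)
    p_extent = np.exp(-beta * extent_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-expected_clusters * p_extent))


def extract_clusters(
    binary_map: np.ndarray | StatMap | BrainMask,
    source_map: StatMap,
    connectivity: int = 26,
) -> ClusterTable:
    """Connected components of a suprathreshold set, with peak reporting.

    The peak of each component is the voxel maximizing the absolute source
    value; the reported intensity is signed. Ties break to the
    lexicographically smallest voxel index (np.argmax on C-ordered arrays).
    """
    if isinstance(binary_map, StatMap):
        binary = binary_map.values != 0
    elif isinstance(binary_map, BrainMask):
        binary = binary_map.include
    else:
        binary = np.asarray(binary_map).astype(bool)
    if binary.shape != source_map.values.shape:
        raise GridError("binary map and source map shapes differ")
    labels, n = ndimage.label(binary, structure=connectivity_structure(connectivity))
    clusters = []
    grid = source_map.grid
    for lab in range(1, n + 1):
        component = labels == lab
        voxels = np.argwhere(component)
        absvals = np.abs(source_map.values[component])
        peak_local = int(np.argmax(absvals))
        peak_ijk = tuple(int(v) for v in voxels[peak_local])
        clusters.append(
            Cluster(
                voxels=voxels,
                peak_ijk=peak_ijk,
                peak_mni_mm=tuple(grid.voxel_to_world(peak_ijk)),
                peak_intensity=float(source_map.values[peak_ijk]),
            )
        )
    return ClusterTable(clusters)


def grf_cluster_correct(
    tmap: StatMap,
    mask: BrainMask,
    smoothness: SmoothnessEstimate,
    settings: GrfSettings = GrfSettings(),
    connectivity: int = 26,
) -> ClusterTable:
    """GRF cluster-level correction of a t map.

    The voxel threshold is applied per tail (voxel_p/2 each when two-tailed);
    positive and negative clusters are extracted separately and each tail is
    tested at cluster_p/2 (two-tailed) so the family-wise alpha is preserved.
    """
    if tmap.df is None:
        raise ValueError("t map must carry degrees of freedom")
    if not tmap.grid.matches(mask.grid):
        raise GridError("t map and mask grids differ")
    p_tail = settings.voxel_p / 2.0 if settings.two_tailed else settings.voxel_p
    cluster_alpha = settings.cluster_p / 2.0 if settings.two_tailed else settings.cluster_p
    t_crit = float(stats.t.isf(p_tail, tmap.df))

    survivors: list[Cluster] = []
    masked_t = np.where(mask.include, tmap.values, 0.0)
    for sign in (+1, -1):
        supra = (sign * masked_t) > t_crit
        table = extract_clusters(supra, tmap, connectivity=connectivity)
        for cluster in table:
            p_corr = grf_cluster_p(
                cluster.size_voxels, t_crit, tmap.df, mask.n_voxels, smoothness.resels
            )
            if p_corr < cluster_alpha:
                survivors.append(cluster)
    return ClusterTable(survivors, source="grf").sorted_by_size()


def fdr_correct(
    tmap: StatMap,
    mask: BrainMask,
    settings: FdrSettings = FdrSettings(),
    connectivity: int = 26,
) -> ClusterTable:
    """Voxelwise BH-FDR on two-tailed t p-values plus an extent threshold."""
    if tmap.df is None:
        raise ValueError("t map must carry degrees of freedom")
    if not tmap.grid.matches(mask.grid):
        raise GridError("t map and mask grids differ")
    t_in = tmap.values[mask.include]
    p = 2.0 * stats.t.sf(np.abs(t_in), tmap.df)
    reject, _, _, _ = multipletests(p, alpha=settings.q, method="fdr_bh")
    supra = np.zeros(tmap.values.shape, dtype=bool)
    supra[mask.include] = reject
    table = extract_clusters(supra, tmap, connectivity=connectivity)
    kept = [c for c in table if c.size_voxels >= settings.min_extent_voxels]
    return ClusterTable(kept, source="fdr").sorted_by_size()


def signed_significance_map(clusters: ClusterTable, grid_shape) -> np.ndarray:
    """{-1, 0, +1} map marking surviving voxels by their cluster's peak sign."""
    out = np.zeros(grid_shape, dtype=int)
    for c in clusters:
        sign = 1 if c.peak_intensity >= 0 else -1
        out[tuple(c.voxels.T)] = sign
    return out
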