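"""Seed definition by triple-metric overlap, and seed-based connectivity.

Seeds are defined where ALFF, fALFF and ReHo all show a significant group
difference in the same direction: voxels positive (patients > controls) in
all three signed significance maps form the positive overlap set, negatives
likewise; each set is decomposed into connected components and components
smaller than 19 voxels are dropped (a 5 mm sphere covers 19 voxels on a 3 mm
grid, the conventional minimum ROI extent). Each surviving component becomes
a seed; its representative peak is the voxel with the highest absolute sum of
the three metrics' group-difference t values.

Seed-based analysis correlates every in-mask voxel's series with the seed's
mean series, Fisher-z transforms, and hands the per-subject z maps to the
group-inference machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import BoldRun, BrainMask, GridError, StatMap
from .inference import (
    FdrSettings,
    GrfSettings,
    SmoothnessEstimate,
    connectivity_structure,
    estimate_smoothness,
    fdr_correct,
    grf_cluster_correct,
    group_residual_maps,
    voxelwise_ttest,
)
from scipy import ndimage

__all__ = [
    "RoiRegion",
    "sphere_voxel_count",
    "sphere_mask",
    "overlap_rois",
    "roi_peak",
    "seed_timeseries",
    "fc_map",
    "sba_group_compare",
]

logger = logging.getLogger(__name__)

#: |r| is clipped here before the Fisher transform so z stays finite.
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class RoiRegion:
    """An overlap-derived seed region.

    ``direction`` is +1 where patients exceeded controls on all three metrics,
    -1 for the reverse.
    """

    voxels: np.ndarray  # (n, 3) int
    direction: int
    peak_ijk: tuple[int, int, int] | None = None
    peak_world_mm: tuple[float, float, float] | None = None
    label: str = "unlabeled"
    network: str = "unassigned"

    def __post_init__(self) -> None:
        voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if voxels.shape[1] != 3:
            raise ValueError("region voxels must be (n, 3)")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        self.voxels = voxels

    @property
    def size_voxels(self) -> int:
        return self.voxels.shape[0]

    def contains(self, ijk) -> bool:
        return bool(any((self.voxels == np.asarray(ijk, dtype=int)).all(axis=1)))


def rois_to_json(regions: list[RoiRegion], path) -> None:
    """Serialize seed regions (voxel lists, direction, peak, labels)."""
    import json
    from pathlib import Path

    records = []
    for r in regions:
        records.append(
            dict(
                voxels=r.voxels.tolist(),
                direction=r.direction,
                peak_ijk=list(r.peak_ijk) if r.peak_ijk is not None else None,
                peak_world_mm=list(r.peak_world_mm) if r.peak_world_mm is not None else None,
                label=r.label,
                network=r.network,
            )
        )
    Path(path).write_text(json.dumps({"rois": records}, indent=1))


def rois_from_json(path) -> list[RoiRegion]:
    """Read back regions written by :func:`rois_to_json`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    regions = []
    for rec in payload["rois"]:
        regions.append(
            RoiRegion(
                voxels=np.asarray(rec["voxels"], dtype=int),
                direction=rec["direction"],
                peak_ijk=tuple(rec["peak_ijk"]) if rec.get("peak_ijk") else None,
                peak_world_mm=tuple(rec["peak_world_mm"]) if rec.get("peak_world_mm") else None,
                label=rec.get("label", "unlabeled"),
                network=rec.get("network", "unassigned"),
            )
        )
    return regions


def sphere_voxel_count(radius_mm: float, voxel_mm: float) -> int:
    """Number of lattice voxels whose center lies within radius_mm.

    Counts integer offsets (i, j, k) with voxel_mm * ||(i,j,k)|| <= radius_mm.
    On a 3 mm grid a 5 mm sphere covers 19 voxels — the minimum seed extent.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    reach = int(np.floor(radius_mm / voxel_mm))
    offsets = np.mgrid[-reach : reach + 1, -reach : reach + 1, -reach : reach + 1]
    dist = voxel_mm * np.sqrt((offsets**2).sum(axis=0))
    return int((dist <= radius_mm).sum())


def sphere_mask(center_ijk, radius_mm: float, grid) -> np.ndarray:
    """Boolean mask of voxels within radius_mm of a center voxel's position."""
    idx = np.indices(grid.shape)
    center = np.asarray(center_ijk, dtype=float).reshape(3, 1, 1, 1)
    voxel_mm = grid.voxel_size_mm.reshape(3, 1, 1, 1)
    dist = np.sqrt((((idx - center) * voxel_mm) ** 2).sum(axis=0))
    return dist <= radius_mm


def _as_sign_array(m) -> np.ndarray:
    arr = m.values if isinstance(m, StatMap) else np.asarray(m)
    out = np.sign(arr).astype(int)
    return out


def overlap_rois(
    sig_alff,
    sig_falff,
    sig_reho,
    min_voxels: int = 19,
    connectivity: int = 26,
) -> list[RoiRegion]:
    """Triple-overlap seed regions from three signed significance maps.

    Inputs are {-1, 0, +1} maps (or StatMaps holding them). Positive and
    negative overlaps are handled separately; components below ``min_voxels``
    are excluded.
    """
    a, f, r = (_as_sign_array(m) for m in (sig_alff, sig_falff, sig_reho))
    if not (a.shape == f.shape == r.shape):
        raise GridError("significance maps are on different grids")
    structure = connectivity_structure(connectivity)
    regions: list[RoiRegion] = []
    for direction in (+1, -1):
        overlap = (a == direction) & (f == direction) & (r == direction)
        labels, n = ndimage.label(overlap, structure=structure)
        for lab in range(1, n + 1):
            voxels = np.argwhere(labels == lab)
            if voxels.shape[0] < min_voxels:
                continue
            regions.append(RoiRegion(voxels=voxels, direction=direction))
    # larger regions first, for stable reporting
    regions.sort(key=lambda reg: (-reg.size_voxels, reg.direction))
    return regions


def roi_peak(
    region: RoiRegion,
    tmap_alff: StatMap,
    tmap_falff: StatMap,
    tmap_reho: StatMap,
) -> tuple[int, int, int]:
    """Voxel with the highest absolute sum of the three metrics' t values.

    Ties break to the lexicographically smallest voxel index (np.argwhere
    emits voxels in C order and np.argmax returns the first maximum).
    """
    if region.size_voxels == 0:
        raise ValueError("empty region")
    idx = tuple(region.voxels.T)
    total = tmap_alff.values[idx] + tmap_falff.values[idx] + tmap_reho.values[idx]
    best = int(np.argmax(np.abs(total)))
    n_best = int((np.abs(total) == np.abs(total[best])).sum())
    if n_best > 1:
        logger.info("roi_peak: %d tied voxels; lexicographic tie-break applied", n_best)
    return tuple(int(v) for v in region.voxels[best])


def seed_timeseries(run: BoldRun, region: RoiRegion) -> np.ndarray:
    """Unweighted mean series over the region's voxels."""
    if region.size_voxels == 0:
        raise ValueError("empty region")
    for ijk in (region.voxels.min(axis=0), region.voxels.max(axis=0)):
        if not run.grid.in_bounds(ijk):
            raise GridError("region extends outside the run grid")
    return run.data[tuple(region.voxels.T)].mean(axis=0)


def fc_map(
    run: BoldRun,
    seed_series: np.ndarray,
    mask: BrainMask,
    seed: RoiRegion | None = None,
) -> StatMap:
    """Fisher-z seed connectivity map.

    Pearson r of every in-mask voxel with the seed series, then z = atanh(r)
    with |r| clipped to 1 - 1e-7 so perfectly correlated voxels (including
    those inside the seed itself, which are retained) stay finite.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    if seed_series.shape[0] != run.n_volumes:
        raise ValueError("seed series length does not match run")
    if not run.grid.matches(mask.grid):
        raise GridError("run and mask grids differ")
    s = seed_series - seed_series.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError("seed series has zero variance")
    data = run.data - run.data.mean(axis=-1, keepdims=True)
    v_norm = np.sqrt((data**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(v_norm > 0, (data @ s) / (np.where(v_norm > 0, v_norm, 1.0) * s_norm), 0.0)
    r = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    z = np.arctanh(r)
    z[~mask.include] = 0.0
    return StatMap(z, run.grid, kind="fcz")


def sba_group_compare(
    fc_maps_a: list[StatMap],
    fc_maps_b: list[StatMap],
    mask: BrainMask,
    settings: GrfSettings | FdrSettings = GrfSettings(),
    connectivity: int = 26,
    smoothness: SmoothnessEstimate | None = None,
):
    """Group comparison of per-subject Fisher-z seed maps.

    Delegates to the voxelwise t test plus the chosen correction; with GRF
    settings the smoothness is estimated from the group residual maps unless
    supplied.
    """
    tmap = voxelwise_ttest(fc_maps_a, fc_maps_b, mask)
    if isinstance(settings, GrfSettings):
        if smoothness is None:
            resid = group_residual_maps(fc_maps_a, fc_maps_b, mask)
            smoothness = estimate_smoothness(resid, mask)
        table = grf_cluster_correct(tmap, mask, smoothness, settings, connectivity)
    else:
        table = fdr_correct(tmap, mask, settings, connectivity)
    return table, tmap
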