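"""Anatomical labeling and winner-takes-all network assignment.

Peaks are named against an integer-labeled anatomical parcellation (AAL-style)
and each parcel is assigned to one of the canonical seven resting-state
networks (Yeo-style partition) by the winner-takes-all rule: the network with
which the parcel shares the most voxels. Real atlas files are optional user
inputs resampled to the analysis grid by nearest neighbor; the test suite and
the synthetic pipeline use toy atlases built here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BoundsError, Cluster, ClusterTable, GridError, VolumeGrid

__all__ = [
    "AtlasVolume",
    "NetworkMapping",
    "YEO7_NETWORKS",
    "winner_takes_all",
    "label_point",
    "annotate_clusters",
    "resample_labels_nearest",
    "make_toy_atlases",
]

logger = logging.getLogger(__name__)

#: Canonical seven-network names, indexed 1..7.
YEO7_NETWORKS = {
    1: "Visual network",
    2: "Sensorimotor network",
    3: "Dorsal attention",
    4: "Ventral attention",
    5: "Limbic",
    6: "Frontoparietal network",
    7: "Default mode network",
}


@dataclass
class AtlasVolume:
    """Integer-labeled volume (0 = background) with a label-name table."""

    labels: np.ndarray
    grid: VolumeGrid
    names: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if labels.shape != self.grid.shape:
            raise GridError("atlas labels shape does not match grid")
        labels = labels.astype(int)
        present = set(np.unique(labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        self.labels = labels


@dataclass
class NetworkMapping:
    """Parcel-name -> network-name assignment with the overlap counts."""

    assignment: dict[str, str]
    overlap_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __getitem__(self, parcel: str) -> str:
        return self.assignment.get(parcel, "unassigned")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for parcel, network in sorted(self.assignment.items()):
            row = {"parcel": parcel, "network": network}
            row.update(self.overlap_counts.get(parcel, {}))
            rows.append(row)
        return pd.DataFrame(rows)


def winner_takes_all(parcellation: AtlasVolume, networks: AtlasVolume) -> NetworkMapping:
    """Assign each parcel to the network it overlaps most.

    Background voxels of the network volume are excluded from the counts;
    parcels overlapping no network get "unassigned". Ties go to the lowest
    network index (logged).
    """
    if not parcellation.grid.matches(networks.grid):
        raise GridError("parcellation and network volumes on different grids")
    assignment: dict[str, str] = {}
    counts_out: dict[str, dict[str, int]] = {}
    net_ids = sorted(set(np.unique(networks.labels)) - {0})
    for parcel_id, parcel_name in sorted(parcellation.names.items()):
        inside = parcellation.labels == parcel_id
        if not inside.any():
            assignment[parcel_name] = "unassigned"
            continue
        overlaps = networks.labels[inside]
        counts = {nid: int((overlaps == nid).sum()) for nid in net_ids}
        counts_out[parcel_name] = {
            networks.names[nid]: c for nid, c in counts.items()
        }
        best = max(counts.values(), default=0)
        if best == 0:
            assignment[parcel_name] = "unassigned"
            continue
        winners = [nid for nid, c in counts.items() if c == best]
        if len(winners) > 1:
            logger.info(
                "winner_takes_all: parcel %s tied between networks %s; lowest index wins",
                parcel_name,
                winners,
            )
        assignment[parcel_name] = networks.names[min(winners)]
    return NetworkMapping(assignment, counts_out)


def label_point(world_mm, atlas: AtlasVolume, search_radius_mm: float = 6.0) -> str:
    """Parcel name at a world-mm point.

    A background point is assigned the nearest labeled voxel within
    ``search_radius_mm`` (6 mm default, logged); beyond that, "unlabeled".
    """
    ijk = atlas.grid.world_to_voxel(world_mm)
    if not atlas.grid.in_bounds(ijk):
        raise BoundsError(f"point {tuple(world_mm)} outside atlas volume")
    lab = int(atlas.labels[ijk])
    if lab != 0:
        return atlas.names[lab]
    labeled = np.argwhere(atlas.labels != 0)
    if labeled.size == 0:
        return "unlabeled"
    voxel_mm = atlas.grid.voxel_size_mm
    dist = np.sqrt((((labeled - np.asarray(ijk)) * voxel_mm) ** 2).sum(axis=1))
    nearest = int(np.argmin(dist))
    if dist[nearest] <= search_radius_mm:
        lab = int(atlas.labels[tuple(labeled[nearest])])
        logger.info(
            "label_point: background point assigned to %s at %.1f mm",
            atlas.names[lab],
            dist[nearest],
        )
        return atlas.names[lab]
    return "unlabeled"


def annotate_clusters(
    clusters: ClusterTable,
    atlas: AtlasVolume | None,
    mapping: NetworkMapping | None,
) -> ClusterTable:
    """Attach anatomical label and network name to each cluster's peak."""
    out = []
    for c in clusters:
        label = c.label
        network = c.network
        if atlas is not None:
            label = label_point(c.peak_mni_mm, atlas)
        if mapping is not None:
            network = mapping[label]
        out.append(
            Cluster(
                voxels=c.voxels,
                peak_ijk=c.peak_ijk,
                peak_mni_mm=c.peak_mni_mm,
                peak_intensity=c.peak_intensity,
                label=label,
                network=network,
            )
        )
    return ClusterTable(out, source=clusters.source)


def resample_labels_nearest(atlas: AtlasVolume, target_grid: VolumeGrid) -> AtlasVolume:
    """Nearest-neighbor resampling of a label volume onto another grid.

    Labels are categorical, so nearest neighbor is the only sane resampler.
    Target voxels falling outside the source volume become background.
    """
    idx = np.indices(target_grid.shape).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    world = target_grid.affine @ homog
    src = np.linalg.inv(atlas.grid.affine) @ world
    src_ijk = np.rint(src[:3]).astype(int)
    inside = np.all(
        (src_ijk >= 0) & (src_ijk < np.asarray(atlas.grid.shape)[:, None]), axis=0
    )
    out = np.zeros(idx.shape[1], dtype=int)
    out[inside] = atlas.labels[tuple(src_ijk[:, inside])]
    return AtlasVolume(out.reshape(target_grid.shape), target_grid, dict(atlas.names))


def make_toy_atlases(grid: VolumeGrid, n_parcels_per_axis: int = 3):
    """Synthetic toy parcellation + network partition on an analysis grid.

    The parcellation tiles the volume into ``n_parcels_per_axis**3`` blocks
    named ``Parcel_<i>``; the network partition slices the volume into seven
    slabs along the first axis, one per canonical network. Purely a stand-in
    for real anatomical/network atlases so that labeling is exercised without
    shipping atlas files.
    """
    shape = grid.shape
    labels = np.zeros(shape, dtype=int)
    edges = [np.linspace(0, s, n_parcels_per_axis + 1).astype(int) for s in shape]
    names = {}
    parcel_id = 0
    for i in range(n_parcels_per_axis):
        for j in range(n_parcels_per_axis):
            for k in range(n_parcels_per_axis):
                parcel_id += 1
                labels[
                    edges[0][i] : edges[0][i + 1],
                    edges[1][j] : edges[1][j + 1],
                    edges[2][k] : edges[2][k + 1],
                ] = parcel_id
                names[parcel_id] = f"Parcel_{parcel_id}"
    parcellation = AtlasVolume(labels, grid, names)

    net_labels = np.zeros(shape, dtype=int)
    slab_edges = np.linspace(0, shape[0], 8).astype(int)
    for net_id in range(1, 8):
        net_labels[slab_edges[net_id - 1] : slab_edges[net_id]] = net_id
    networks = AtlasVolume(net_labels, grid, dict(YEO7_NETWORKS))
    return parcellation, networks
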