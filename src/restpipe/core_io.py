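"""Volume data model, NIfTI I/O, voxel/world coordinates, and cluster tables.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` triples;
* reported coordinates are always world millimetres (MNI-style), obtained
  through the volume's affine;
* statistical maps are plain 3D arrays on a :class:`VolumeGrid`, tagged with a
  ``kind`` so downstream stages can check what they were handed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "BoldRun",
    "StatMap",
    "BrainMask",
    "Cluster",
    "ClusterTable",
    "DimensionalityError",
    "FormatError",
    "GridError",
    "BoundsError",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "write_cluster_table",
    "read_cluster_table",
]

STATMAP_KINDS = {"alff", "falff", "reho", "zmap", "tmap", "fcz"}


class FormatError(ValueError):
    """File is not a volume format this package reads."""


class DimensionalityError(ValueError):
    """Volume has the wrong number of dimensions for the requested type."""


class GridError(ValueError):
    """Two objects that must share a voxel grid do not."""


class BoundsError(IndexError):
    """Voxel index or world point outside the grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice with an affine mapping indices to world mm.

    ``affine`` is the usual 4x4 homogeneous matrix: world = A @ (i, j, k, 1).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Column norms of the 3x3 block: physical voxel edge lengths."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]

    def world_to_voxel(self, xyz: Sequence[float], round_to_int: bool = True):
        xyz = np.asarray(xyz, dtype=float)
        ijk = np.linalg.solve(self.affine[:3, :3], xyz - self.affine[:3, 3])
        if round_to_int:
            return tuple(int(v) for v in np.rint(ijk))
        return ijk

    def in_bounds(self, ijk: Sequence[int]) -> bool:
        return all(0 <= int(v) < s for v, s in zip(ijk, self.shape))

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def _require_same_grid(a: VolumeGrid, b: VolumeGrid, what: str) -> None:
    if not a.matches(b):
        raise GridError(f"{what}: grids differ (shape {a.shape} vs {b.shape})")


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (deg)."""

    values: np.ndarray  # (T, 6)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 6:
            raise ValueError("motion trace must be T x 6")
        self.values = values

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series.

    ``data`` is (x, y, z, t) in arbitrary units; ``tr_s`` is the repetition
    time in seconds. ``group`` is ``"patient"`` or ``"control"`` when the run
    belongs to a two-group cohort.
    """

    data: np.ndarray
    grid: VolumeGrid
    tr_s: float
    motion: MotionTrace | None = None
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise DimensionalityError(f"BOLD data must be 4D, got {data.ndim}D")
        if data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if data.shape[:3] != self.grid.shape:
            raise GridError("data shape does not match grid")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        self.data = data

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, **kwargs) -> "BoldRun":
        return replace(self, data=data, **kwargs)


@dataclass
class StatMap:
    """A 3D scalar map (metric, t, z or Fisher-z correlation) on a grid."""

    values: np.ndarray
    grid: VolumeGrid
    kind: str
    df: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise DimensionalityError(f"stat map must be 3D, got {values.ndim}D")
        if values.shape != self.grid.shape:
            raise GridError("values shape does not match grid")
        if self.kind not in STATMAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; one of {sorted(STATMAP_KINDS)}")
        self.values = values


@dataclass
class BrainMask:
    """Boolean inclusion mask on a grid (the analysis restriction)."""

    include: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        include = np.asarray(self.include).astype(bool)
        if include.ndim != 3:
            raise DimensionalityError("mask must be 3D")
        if include.shape != self.grid.shape:
            raise GridError("mask shape does not match grid")
        if not include.any():
            raise ValueError("mask includes no voxels")
        self.include = include

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class Cluster:
    """A contiguous suprathreshold region with its reported peak.

    ``peak_intensity`` is signed (t or FC-difference statistic); the peak is
    the cluster voxel maximizing the absolute source-map value.
    """

    voxels: np.ndarray  # (n, 3) int voxel indices
    peak_ijk: tuple[int, int, int]
    peak_mni_mm: tuple[float, float, float]
    peak_intensity: float
    label: str = "unlabeled"
    network: str = "unassigned"

    def __post_init__(self) -> None:
        voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if voxels.shape[1] != 3:
            raise ValueError("cluster voxels must be (n, 3)")
        self.voxels = voxels
        self.peak_ijk = tuple(int(v) for v in self.peak_ijk)
        self.peak_mni_mm = tuple(float(v) for v in self.peak_mni_mm)
        if not any((voxels == np.array(self.peak_ijk)).all(axis=1)):
            raise ValueError("peak voxel not contained in cluster")

    @property
    def size_voxels(self) -> int:
        return self.voxels.shape[0]

    def contains(self, ijk: Sequence[int]) -> bool:
        return bool(any((self.voxels == np.asarray(ijk, dtype=int)).all(axis=1)))


@dataclass
class ClusterTable:
    """Ordered collection of clusters from one statistical comparison."""

    clusters: list[Cluster] = field(default_factory=list)
    source: str = ""

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, i: int) -> Cluster:
        return self.clusters[i]

    def sorted_by_size(self) -> "ClusterTable":
        order = sorted(self.clusters, key=lambda c: -c.size_voxels)
        return ClusterTable(order, source=self.source)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.sorted_by_size(), start=1):
            x, y, z = c.peak_mni_mm
            rows.append(
                dict(
                    cluster_no=i,
                    peak_x=x,
                    peak_y=y,
                    peak_z=z,
                    peak_intensity=c.peak_intensity,
                    label=c.label,
                    network=c.network,
                    size_voxels=c.size_voxels,
                )
            )
        columns = [
            "cluster_no",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_intensity",
            "label",
            "network",
            "size_voxels",
        ]
        return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(
    path,
    kind: str | None = None,
    tr_s: float | None = None,
    subject_id: str = "",
    group: str = "",
):
    """Read a NIfTI file as a :class:`BoldRun` (4D) or :class:`StatMap` (3D).

    For 3D input ``kind`` must be supplied by the caller; for 4D input the
    repetition time is taken from the header's 4th zoom unless ``tr_s``
    overrides it.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except (nib.filebasedimages.ImageFileError, OSError) as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 4:
        grid = VolumeGrid(data.shape[:3], affine)
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else 0.0
        if tr_s <= 0:
            raise ValueError(f"{path}: no TR in header; pass tr_s explicitly")
        return BoldRun(data, grid, tr_s=tr_s, subject_id=subject_id, group=group)
    if data.ndim == 3:
        if kind is None:
            raise DimensionalityError(
                f"{path} is 3D; a map kind must be supplied to read it as a StatMap"
            )
        grid = VolumeGrid(data.shape, affine)
        return StatMap(data, grid, kind=kind)
    raise DimensionalityError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")


def write_volume(obj: BoldRun | StatMap | BrainMask, path) -> None:
    """Write a run, map or mask to NIfTI (float32 data, TR in the 4th zoom)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, BoldRun):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.grid.affine)
        zooms = tuple(obj.grid.voxel_size_mm) + (obj.tr_s,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, StatMap):
        img = nib.Nifti1Image(obj.values.astype(np.float32), obj.grid.affine)
    elif isinstance(obj, BrainMask):
        img = nib.Nifti1Image(obj.include.astype(np.uint8), obj.grid.affine)
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    nib.save(img, str(path))


def voxel_to_world(ijk: Sequence[int], grid: VolumeGrid) -> np.ndarray:
    """World mm coordinate of an in-bounds voxel index."""
    if not grid.in_bounds(ijk):
        raise BoundsError(f"voxel {tuple(ijk)} outside grid {grid.shape}")
    return grid.voxel_to_world(ijk)


def world_to_voxel(xyz: Sequence[float], grid: VolumeGrid) -> tuple[int, int, int]:
    """Nearest voxel index of a world mm coordinate (inverse of voxel_to_world)."""
    ijk = grid.world_to_voxel(xyz, round_to_int=True)
    if not grid.in_bounds(ijk):
        raise BoundsError(f"world point {tuple(xyz)} maps outside grid {grid.shape}")
    return ijk


# ---------------------------------------------------------------------------
# Cluster table serialization


def write_cluster_table(table: ClusterTable | Iterable[Cluster], path) -> None:
    """Write a cluster table as TSV plus a full-precision JSON twin.

    The TSV mirrors the layout of published peak tables (one row per cluster,
    descending size, peak intensity rounded to one decimal); the ``.json``
    twin next to it keeps full float precision and the voxel lists.
    """
    if not isinstance(table, ClusterTable):
        table = ClusterTable(list(table))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_dataframe()
    out = df.copy()
    if len(out):
        out["peak_intensity"] = out["peak_intensity"].map(lambda v: f"{v:.1f}")
        for col in ("peak_x", "peak_y", "peak_z"):
            out[col] = out[col].map(lambda v: f"{v:g}")
    out.to_csv(path, sep="\t", index=False)

    records = []
    for i, c in enumerate(table.sorted_by_size(), start=1):
        records.append(
            dict(
                cluster_no=i,
                peak_ijk=list(c.peak_ijk),
                peak_mni_mm=list(c.peak_mni_mm),
                peak_intensity=float(c.peak_intensity),
                label=c.label,
                network=c.network,
                size_voxels=c.size_voxels,
                voxels=c.voxels.tolist(),
            )
        )
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps({"source": table.source, "clusters": records}, indent=1))


def read_cluster_table(json_path) -> ClusterTable:
    """Read back the JSON twin written by :func:`write_cluster_table`."""
    payload = json.loads(Path(json_path).read_text())
    clusters = []
    for rec in payload["clusters"]:
        clusters.append(
            Cluster(
                voxels=np.asarray(rec["voxels"], dtype=int),
                peak_ijk=tuple(rec["peak_ijk"]),
                peak_mni_mm=tuple(rec["peak_mni_mm"]),
                peak_intensity=rec["peak_intensity"],
                label=rec["label"],
                network=rec["network"],
            )
        )
    return ClusterTable(clusters, source=payload.get("source", ""))
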