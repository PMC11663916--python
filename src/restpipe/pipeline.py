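"""End-to-end orchestration of the group analysis on a cohort.

Stages: motion screening -> preprocessing (discard, nuisance regression,
band-pass) -> local metrics (ALFF/fALFF/ReHo, smoothed, standardized) ->
voxelwise group inference per metric (GRF and FDR cluster correction) ->
triple-overlap seed definition -> seed-based connectivity group comparison
-> atlas annotation -> cognitive comparison and cognition-imaging
correlation. All tunable parameters live in :class:`PipelineConfig`, whose
defaults are the study conventions (discard 10; 3 mm / 3 deg motion limits;
0.01-0.10 Hz; 4 mm FWHM; voxel p 0.001; cluster p 0.05 two-tailed; FDR q
0.05 with 50-voxel extent; 19-voxel minimum seed size).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from .cognition import (
    ImagingMarkerVector,
    correlate_battery,
    correlation_frame,
    domain_group_ttest,
    extract_marker,
)
from .core_io import (
    BoldRun,
    BrainMask,
    ClusterTable,
    MotionTrace,
    StatMap,
    read_volume,
    write_cluster_table,
    write_volume,
)
from .inference import (
    FdrSettings,
    GrfSettings,
    estimate_smoothness,
    fdr_correct,
    grf_cluster_correct,
    group_residual_maps,
    signed_significance_map,
    voxelwise_ttest,
)
from .metrics import NeighborhoodSpec, alff, falff, reho, standardize_map
from .preprocess import (
    BandDefinition,
    bandpass,
    build_nuisance_design,
    discard_initial_volumes,
    motion_exclusion_flag,
    nuisance_regress,
    smooth_gaussian,
)
from .roi import RoiRegion, fc_map, roi_peak, sba_group_compare, seed_timeseries
from .synthetic import Cohort

__all__ = [
    "PipelineConfig",
    "MetricGroupResult",
    "PipelineResult",
    "preprocess_run",
    "subject_metric_maps",
    "analyze_cohort",
    "run_pipeline",
    "write_report",
    "write_cohort_dir",
    "load_cohort_dir",
]

logger = logging.getLogger(__name__)

METRICS = ("alff", "falff", "reho")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters; defaults are the study conventions."""

    discard_volumes: int = 10
    motion_trans_mm: float = 3.0
    motion_rot_deg: float = 3.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.10
    smooth_fwhm_mm: float = 4.0
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    two_tailed: bool = True
    fdr_q: float = 0.05
    fdr_min_extent_voxels: int = 50
    min_roi_voxels: int = 19
    connectivity: int = 26
    reho_neighborhood: int = 27
    standardize_metric_maps: bool = True
    correction: str = "grf"  # correction driving seed definition

    def band(self) -> BandDefinition:
        return BandDefinition(self.band_low_hz, self.band_high_hz)

    def grf(self) -> GrfSettings:
        return GrfSettings(self.voxel_p, self.cluster_p, self.two_tailed)

    def fdr(self) -> FdrSettings:
        return FdrSettings(self.fdr_q, self.fdr_min_extent_voxels)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class MetricGroupResult:
    tmap: StatMap
    grf_clusters: ClusterTable
    fdr_clusters: ClusterTable
    sig_map: np.ndarray  # {-1, 0, +1}

    def chosen(self, correction: str) -> ClusterTable:
        return self.grf_clusters if correction == "grf" else self.fdr_clusters


@dataclass
class PipelineResult:
    config: PipelineConfig
    included_subjects: list[str]
    excluded_subjects: list[str]
    metric_results: dict[str, MetricGroupResult]
    rois: list[RoiRegion]
    roi_table: pd.DataFrame
    sba_tables: list[ClusterTable]
    sba_tmaps: list[StatMap]
    cognition_ttests: pd.DataFrame
    correlations: pd.DataFrame


def preprocess_run(
    run: BoldRun, csf_mask: BrainMask, wm_mask: BrainMask, config: PipelineConfig
):
    """Discard, regress, band-pass one run.

    Returns ``(run_band, run_fullband)``: the band-passed series feeds ALFF
    and ReHo; the full-band (post-regression) series feeds fALFF, which needs
    the whole spectrum in its denominator.
    """
    run = discard_initial_volumes(run, config.discard_volumes)
    design = build_nuisance_design(run, csf_mask, wm_mask)
    run_fullband = nuisance_regress(run, design)
    run_band = bandpass(run_fullband, config.band())
    return run_band, run_fullband


def subject_metric_maps(
    run_band: BoldRun,
    run_fullband: BoldRun,
    mask: BrainMask,
    config: PipelineConfig,
) -> dict[str, StatMap]:
    """ALFF/fALFF/ReHo maps for one subject, smoothed and standardized.

    Smoothing is applied to the metric maps (not the series) so ReHo is not
    inflated by pre-smoothing; standardization makes maps comparable across
    subjects and sites.
    """
    band = config.band()
    maps = {
        "alff": alff(run_band, band, mask),
        "falff": falff(run_fullband, band, mask),
        "reho": reho(run_band, mask, NeighborhoodSpec(config.reho_neighborhood)),
    }
    out = {}
    for name, m in maps.items():
        m = smooth_gaussian(m, config.smooth_fwhm_mm)
        m.values[~mask.include] = 0.0
        if config.standardize_metric_maps:
            m = standardize_map(m, mask)
        out[name] = m
    return out


def _metric_group_inference(
    maps_patients: list[StatMap],
    maps_controls: list[StatMap],
    mask: BrainMask,
    config: PipelineConfig,
) -> MetricGroupResult:
    tmap = voxelwise_ttest(maps_patients, maps_controls, mask)
    resid = group_residual_maps(maps_patients, maps_controls, mask)
    smoothness = estimate_smoothness(resid, mask)
    grf_table = grf_cluster_correct(tmap, mask, smoothness, config.grf(), config.connectivity)
    fdr_table = fdr_correct(tmap, mask, config.fdr(), config.connectivity)
    chosen = grf_table if config.correction == "grf" else fdr_table
    sig = signed_significance_map(chosen, mask.grid.shape)
    return MetricGroupResult(tmap, grf_table, fdr_table, sig)


def analyze_cohort(
    cohort: Cohort,
    config: PipelineConfig = PipelineConfig(),
    parcellation: atlas_mod.AtlasVolume | None = None,
    networks: atlas_mod.AtlasVolume | None = None,
) -> PipelineResult:
    """Run the full group analysis on an in-memory cohort."""
    from .roi import overlap_rois  # local to avoid circularity at import time

    mask = cohort.analysis_mask
    mapping = None
    if parcellation is not None and networks is not None:
        mapping = atlas_mod.winner_takes_all(parcellation, networks)

    included: list[BoldRun] = []
    excluded: list[str] = []
    band_runs: dict[str, BoldRun] = {}
    metric_maps: dict[str, dict[str, StatMap]] = {m: {} for m in METRICS}
    for run in cohort.runs:
        if run.motion is not None and motion_exclusion_flag(
            run.motion, config.motion_trans_mm, config.motion_rot_deg
        ):
            excluded.append(run.subject_id)
            logger.info("excluding %s for excessive head motion", run.subject_id)
            continue
        run_band, run_fullband = preprocess_run(run, cohort.csf_mask, cohort.wm_mask, config)
        band_runs[run.subject_id] = run_band
        maps = subject_metric_maps(run_band, run_fullband, mask, config)
        for m in METRICS:
            metric_maps[m][run.subject_id] = maps[m]
        included.append(run)

    patient_ids = [r.subject_id for r in included if r.group == "patient"]
    control_ids = [r.subject_id for r in included if r.group == "control"]
    if len(patient_ids) < 2 or len(control_ids) < 2:
        raise ValueError("fewer than 2 usable subjects in a group after motion screening")

    metric_results: dict[str, MetricGroupResult] = {}
    for m in METRICS:
        metric_results[m] = _metric_group_inference(
            [metric_maps[m][s] for s in patient_ids],
            [metric_maps[m][s] for s in control_ids],
            mask,
            config,
        )

    regions = overlap_rois(
        metric_results["alff"].sig_map,
        metric_results["falff"].sig_map,
        metric_results["reho"].sig_map,
        min_voxels=config.min_roi_voxels,
        connectivity=config.connectivity,
    )
    roi_rows = []
    for idx, region in enumerate(regions, start=1):
        peak = roi_peak(
            region,
            metric_results["alff"].tmap,
            metric_results["falff"].tmap,
            metric_results["reho"].tmap,
        )
        region.peak_ijk = peak
        region.peak_world_mm = tuple(mask.grid.voxel_to_world(peak))
        if parcellation is not None:
            region.label = atlas_mod.label_point(region.peak_world_mm, parcellation)
        if mapping is not None:
            region.network = mapping[region.label]
        roi_rows.append(
            dict(
                roi_no=idx,
                peak_x=region.peak_world_mm[0],
                peak_y=region.peak_world_mm[1],
                peak_z=region.peak_world_mm[2],
                direction=region.direction,
                label=region.label,
                network=region.network,
                size_voxels=region.size_voxels,
            )
        )
    roi_table = pd.DataFrame(
        roi_rows,
        columns=[
            "roi_no",
            "peak_x",
            "peak_y",
            "peak_z",
            "direction",
            "label",
            "network",
            "size_voxels",
        ],
    )

    # --- seed-based connectivity per ROI
    settings = config.grf() if config.correction == "grf" else config.fdr()
    sba_tables: list[ClusterTable] = []
    sba_tmaps: list[StatMap] = []
    fc_by_roi: list[dict[str, StatMap]] = []
    for region in regions:
        fc_maps: dict[str, StatMap] = {}
        for run in included:
            series = seed_timeseries(band_runs[run.subject_id], region)
            z = fc_map(band_runs[run.subject_id], series, mask)
            z = smooth_gaussian(z, config.smooth_fwhm_mm)
            z.values[~mask.include] = 0.0
            fc_maps[run.subject_id] = z
        fc_by_roi.append(fc_maps)
        table, tmap = sba_group_compare(
            [fc_maps[s] for s in patient_ids],
            [fc_maps[s] for s in control_ids],
            mask,
            settings,
            config.connectivity,
        )
        table = atlas_mod.annotate_clusters(table, parcellation, mapping)
        table.source = f"sba_roi{len(sba_tables) + 1}"
        sba_tables.append(table)
        sba_tmaps.append(tmap)

    # annotate the per-metric cluster tables too
    for m in METRICS:
        res = metric_results[m]
        res.grf_clusters = atlas_mod.annotate_clusters(res.grf_clusters, parcellation, mapping)
        res.grf_clusters.source = f"{m}_grf"
        res.fdr_clusters = atlas_mod.annotate_clusters(res.fdr_clusters, parcellation, mapping)
        res.fdr_clusters.source = f"{m}_fdr"

    # --- cognition
    included_ids = [r.subject_id for r in included]
    cog = cohort.cognition[cohort.cognition["subject_id"].isin(included_ids)]
    cog_tests = domain_group_ttest(cog)

    markers: list[ImagingMarkerVector] = []
    for m in METRICS:
        chosen = metric_results[m].chosen(config.correction)
        subject_maps = [metric_maps[m][s] for s in included_ids]
        for ci, cluster in enumerate(chosen.sorted_by_size(), start=1):
            markers.append(
                extract_marker(subject_maps, cluster, included_ids, f"{m}_cluster{ci}")
            )
    for ri, (table, fc_maps) in enumerate(zip(sba_tables, fc_by_roi), start=1):
        subject_maps = [fc_maps[s] for s in included_ids]
        for ci, cluster in enumerate(table.sorted_by_size(), start=1):
            markers.append(
                extract_marker(subject_maps, cluster, included_ids, f"roi{ri}_fc_cluster{ci}")
            )
    results = correlate_battery(cog, markers, adjust=True) if markers else []
    correlations = correlation_frame(results)

    return PipelineResult(
        config=config,
        included_subjects=included_ids,
        excluded_subjects=excluded,
        metric_results=metric_results,
        rois=regions,
        roi_table=roi_table,
        sba_tables=sba_tables,
        sba_tmaps=sba_tmaps,
        cognition_ttests=cog_tests,
        correlations=correlations,
    )


# ---------------------------------------------------------------------------
# Cohort directory layout (what `restpipe simulate` writes and `run` reads)


def write_cohort_dir(cohort: Cohort, out_dir) -> None:
    """Write a cohort as NIfTI runs, motion TSVs, cognition TSV and masks."""
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    for run in cohort.runs:
        write_volume(run, out / "runs" / f"{run.subject_id}.nii.gz")
        if run.motion is not None:
            np.savetxt(
                out / "runs" / f"{run.subject_id}_motion.tsv",
                run.motion.values,
                delimiter="\t",
                header="\t".join(
                    ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
                ),
                comments="",
            )
    cohort.cognition.to_csv(out / "cognition.tsv", sep="\t", index=False)
    write_volume(cohort.analysis_mask, out / "analysis_mask.nii.gz")
    write_volume(cohort.csf_mask, out / "csf_mask.nii.gz")
    write_volume(cohort.wm_mask, out / "wm_mask.nii.gz")
    grid = cohort.analysis_mask.grid
    for i, sphere in enumerate(cohort.effect_masks, start=1):
        write_volume(BrainMask(sphere, grid), out / f"truth_effect{i}.nii.gz")
    pd.Series(cohort.subject_effect_magnitude, name="effect_magnitude").rename_axis(
        "subject_id"
    ).reset_index().to_csv(out / "truth_subject_effects.tsv", sep="\t", index=False)


def load_cohort_dir(path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort_dir`."""
    from .synthetic import CohortSpec

    path = Path(path)
    runs = []
    for nii in sorted((path / "runs").glob("*.nii.gz")):
        sid = nii.name.replace(".nii.gz", "")
        group = "patient" if sid.startswith("patient") else "control"
        run = read_volume(nii, subject_id=sid, group=group)
        motion_path = path / "runs" / f"{sid}_motion.tsv"
        if motion_path.exists():
            run.motion = MotionTrace(np.loadtxt(motion_path, delimiter="\t", skiprows=1))
        runs.append(run)
    if not runs:
        raise FileNotFoundError(f"no runs found under {path / 'runs'}")
    cognition = pd.read_csv(path / "cognition.tsv", sep="\t")
    masks = {}
    for name in ("analysis", "csf", "wm"):
        m = read_volume(path / f"{name}_mask.nii.gz", kind="zmap")
        masks[name] = BrainMask(m.values > 0.5, m.grid)
    effect_masks = []
    for nii in sorted(path.glob("truth_effect*.nii.gz")):
        m = read_volume(nii, kind="zmap")
        effect_masks.append(m.values > 0.5)
    truth_path = path / "truth_subject_effects.tsv"
    subject_effects = {}
    if truth_path.exists():
        df = pd.read_csv(truth_path, sep="\t")
        subject_effects = dict(zip(df["subject_id"], df["effect_magnitude"]))
    n_per_group = max(2, sum(1 for r in runs if r.group == "patient"))
    spec = CohortSpec(
        n_per_group=n_per_group,
        shape=runs[0].grid.shape,
        voxel_size_mm=float(runs[0].grid.voxel_size_mm[0]),
        tr_s=runs[0].tr_s,
        n_volumes=runs[0].n_volumes,
    )
    return Cohort(
        spec=spec,
        runs=runs,
        cognition=cognition,
        analysis_mask=masks["analysis"],
        csf_mask=masks["csf"],
        wm_mask=masks["wm"],
        effect_masks=effect_masks,
        subject_effect_magnitude=subject_effects,
    )


def write_report(result: PipelineResult, out_dir) -> None:
    """Write all result tables, mirroring the published-table layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    for m, res in result.metric_results.items():
        write_cluster_table(res.grf_clusters, out / f"{m}_clusters_grf.tsv")
        write_cluster_table(res.fdr_clusters, out / f"{m}_clusters_fdr.tsv")
    result.roi_table.to_csv(out / "roi_table.tsv", sep="\t", index=False)
    for i, table in enumerate(result.sba_tables, start=1):
        write_cluster_table(table, out / f"sba_roi{i}_clusters.tsv")
    result.cognition_ttests.to_csv(out / "cognition_ttests.tsv", sep="\t", index=False)
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    summary = dict(
        included_subjects=result.included_subjects,
        excluded_subjects=result.excluded_subjects,
        n_rois=len(result.rois),
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1))


def run_pipeline(
    cohort_dir,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
    parcellation_path=None,
    networks_path=None,
) -> PipelineResult:
    """Load a cohort directory, run the analysis, optionally write a report.

    If atlas paths are given they are read as integer label volumes and
    resampled (nearest neighbor) to the analysis grid; labels are named
    ``Parcel_<i>`` / network index names unless a names table is provided
    alongside (``<atlas>.labels.json`` mapping id -> name).
    """
    cohort = load_cohort_dir(cohort_dir)
    parcellation = networks = None
    grid = cohort.analysis_mask.grid
    if parcellation_path is not None:
        parcellation = _load_atlas(parcellation_path, grid, prefix="Parcel_")
    if networks_path is not None:
        networks = _load_atlas(networks_path, grid, prefix=None)
    result = analyze_cohort(cohort, config, parcellation, networks)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def _load_atlas(path, target_grid, prefix):
    vol = read_volume(path, kind="zmap")
    labels = np.rint(vol.values).astype(int)
    names_path = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    names_file = Path(str(names_path) + ".labels.json")
    if names_file.exists():
        names = {int(k): v for k, v in json.loads(names_file.read_text()).items()}
    elif prefix is None:
        names = dict(atlas_mod.YEO7_NETWORKS)
    else:
        names = {int(i): f"{prefix}{int(i)}" for i in np.unique(labels) if i != 0}
    vol = atlas_mod.AtlasVolume(labels, vol.grid, names)
    if not vol.grid.matches(target_grid):
        vol = atlas_mod.resample_labels_nearest(vol, target_grid)
    return vol
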