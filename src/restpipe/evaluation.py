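"""Calibration and parameter-recovery evaluations of the pipeline.

These routines measure, by simulation against the synthetic generator's
ground truth, the operating characteristics that justify trusting the
pipeline's output on real data:

* the family-wise error rate of the GRF cluster correction on pure-noise
  cohorts (should sit near the nominal cluster-level alpha);
* whether the full pipeline recovers an injected effect region (seed ROI
  whose peak falls inside the true sphere) and its injected connectivity
  partner (a seed-based-analysis cluster overlapping the partner sphere);
* whether the sign of an injected cognition-imaging coupling is recovered
  by the Spearman battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BrainMask, StatMap, VolumeGrid
from .inference import (
    GrfSettings,
    estimate_smoothness,
    grf_cluster_correct,
    group_residual_maps,
    voxelwise_ttest,
)
from .metrics import alff, standardize_map
from .pipeline import PipelineConfig, analyze_cohort
from .preprocess import FWHM_TO_SIGMA
from .synthetic import STUDY_BAND, default_effect_cohort_spec, generate_cohort
from .cognition import spearman

__all__ = [
    "grf_null_familywise_rate",
    "RecoveryReplicate",
    "run_recovery_replicate",
]


def _smooth_noise_map(rng, shape, fwhm_mm, voxel_mm, grid) -> StatMap:
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    values = ndimage.gaussian_filter(
        rng.standard_normal(size=shape), sigma=sigma, mode="reflect"
    )
    return StatMap(values, grid, kind="zmap")


def grf_null_familywise_rate(
    n_replicates: int = 300,
    n_per_group: int = 10,
    shape: tuple[int, int, int] = (32, 32, 32),
    fwhm_mm: float = 6.0,
    voxel_mm: float = 3.0,
    settings: GrfSettings = GrfSettings(),
    seed: int = 0,
) -> dict:
    """Fraction of pure-noise replicates with >= 1 surviving GRF cluster.

    Each replicate draws two groups of spatially smooth Gaussian-noise maps,
    runs the pooled t test, estimates smoothness from the residuals, and
    applies the GRF cluster correction at the default thresholds. The
    returned rate estimates the family-wise error, nominally the cluster
    alpha (0.05 two-tailed).
    """
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    grid = VolumeGrid(shape, affine)
    mask = BrainMask(np.ones(shape, dtype=bool), grid)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    n_positive = 0
    for seq in seeds:
        rng = np.random.default_rng(seq)
        maps_a = [
            _smooth_noise_map(rng, shape, fwhm_mm, voxel_mm, grid)
            for _ in range(n_per_group)
        ]
        maps_b = [
            _smooth_noise_map(rng, shape, fwhm_mm, voxel_mm, grid)
            for _ in range(n_per_group)
        ]
        tmap = voxelwise_ttest(maps_a, maps_b, mask)
        smoothness = estimate_smoothness(group_residual_maps(maps_a, maps_b, mask), mask)
        table = grf_cluster_correct(tmap, mask, smoothness, settings)
        if len(table):
            n_positive += 1
    return {"rate": n_positive / n_replicates, "n": n_replicates}


@dataclass
class RecoveryReplicate:
    """Ground-truth comparison of one seeded effect-cohort analysis."""

    seed: int
    n_rois: int
    roi_peak_in_truth: bool
    sba_partner_recovered: bool
    rho_wm: float
    rho_susta: float


def _truth_sphere_marker(cohort) -> tuple[list[str], np.ndarray]:
    """Per-subject mean standardized ALFF over the true effect sphere.

    Computed straight from the generated runs (the synthetic baseline needs
    no nuisance removal), standardized within the analysis mask so the
    marker is comparable across subjects.
    """
    sphere = cohort.effect_masks[0]
    mask = cohort.analysis_mask
    ids, values = [], []
    for run in cohort.runs:
        m = standardize_map(alff(run, STUDY_BAND, mask), mask)
        ids.append(run.subject_id)
        values.append(m.values[sphere].mean())
    return ids, np.asarray(values)


def run_recovery_replicate(
    seed: int, config: PipelineConfig = PipelineConfig()
) -> RecoveryReplicate:
    """Generate the standard effect cohort at ``seed`` and score recovery."""
    spec = default_effect_cohort_spec(seed=seed)
    cohort = generate_cohort(spec)
    truth_sphere = cohort.effect_masks[0]
    connectivity_effects = [
        (i, e) for i, e in enumerate(spec.effects) if e.effect_type == "connectivity"
    ]
    partner_sphere = None
    if connectivity_effects:
        from .roi import sphere_mask

        idx, eff = connectivity_effects[0]
        partner_sphere = sphere_mask(eff.partner_center_ijk, eff.radius_mm, spec.grid())

    result = analyze_cohort(cohort, config)

    roi_hit = False
    sba_hit = False
    for region, table in zip(result.rois, result.sba_tables):
        in_truth = region.peak_ijk is not None and truth_sphere[region.peak_ijk]
        roi_hit = roi_hit or bool(in_truth)
        if in_truth and partner_sphere is not None:
            for cluster in table:
                overlap = partner_sphere[tuple(cluster.voxels.T)].any()
                if overlap:
                    sba_hit = True
                    break

    ids, marker = _truth_sphere_marker(cohort)
    cog = cohort.cognition.set_index("subject_id").loc[ids]
    rho_wm = spearman(marker, cog["WM"].to_numpy(float)).rho
    rho_susta = spearman(marker, cog["SustA"].to_numpy(float)).rho
    return RecoveryReplicate(
        seed=seed,
        n_rois=len(result.rois),
        roi_peak_in_truth=roi_hit,
        sba_partner_recovered=sba_hit,
        rho_wm=rho_wm,
        rho_susta=rho_susta,
    )
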