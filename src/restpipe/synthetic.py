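"""Two-group synthetic BOLD cohort generator with known ground truth.

Emulates the data layout of a small two-site pediatric resting-state study:
two groups of subjects, template-space 3 mm grids, TR 2 s, band-limited
spatially smooth noise, six-parameter motion traces and a per-subject
cognitive score table. Regional group effects are injected with full control:

* ``amplitude`` — the low-frequency (0.01-0.10 Hz) component inside a sphere
  is multiplied by (1 + magnitude) for the target group, raising ALFF/fALFF;
* ``synchrony`` — in-sphere voxels are mixed with a shared latent series
  (variance-preserving weights), raising ReHo without changing amplitude;
* ``connectivity`` — a sphere and a partner sphere share one latent series,
  raising their mutual functional connectivity.

Per-subject effect strength varies (uniform multiplier on the nominal
magnitude), and cognitive domain scores are coupled linearly to that
subject-level strength, so correlation analyses have a recoverable sign.
Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cognition import COGNITIVE_DOMAINS
from .core_io import BoldRun, BrainMask, MotionTrace, VolumeGrid
from .preprocess import FWHM_TO_SIGMA, BandDefinition, _bandpass_series
from .roi import sphere_mask

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "Cohort",
    "STUDY_BAND",
    "generate_cohort",
    "generate_motion_trace",
    "default_effect_cohort_spec",
]

#: The low-frequency band that defines "amplitude" effects and band shaping.
STUDY_BAND = BandDefinition(0.01, 0.10)

EFFECT_TYPES = {"amplitude", "synchrony", "connectivity"}
GROUPS = ("patient", "control")


@dataclass(frozen=True)
class EffectSpec:
    """One injected regional group effect."""

    effect_type: str
    center_ijk: tuple[int, int, int]
    radius_mm: float
    magnitude: float
    target_group: str = "patient"
    partner_center_ijk: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"effect_type must be one of {sorted(EFFECT_TYPES)}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.effect_type in ("synchrony", "connectivity") and not 0 <= self.magnitude <= 1:
            raise ValueError("synchrony/connectivity magnitude must lie in [0, 1]")
        if self.target_group not in GROUPS:
            raise ValueError(f"target_group must be one of {GROUPS}")
        if self.effect_type == "connectivity" and self.partner_center_ijk is None:
            raise ValueError("connectivity effect needs partner_center_ijk")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic two-group experiment.

    Defaults are the package's standard study conditions: 10 subjects per
    group on a 24^3 grid of 3 mm voxels, 120 volumes at TR 2 s, 6 mm smooth
    noise with low-frequency-dominant spectrum. The full-scale 15-per-group,
    240-volume configuration is supported by overriding the fields.
    """

    n_per_group: int = 10
    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 120
    noise_fwhm_mm: float = 6.0
    band_power_profile: tuple[float, float] = (1.0, 0.5)
    effects: tuple[EffectSpec, ...] = ()
    cognition_coupling: dict = field(default_factory=dict)
    cognition_baseline: float = 103.0
    cognition_noise_sd: float = 10.0
    motion_severity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_volumes < 50:
            raise ValueError("need at least 50 volumes")
        if self.noise_fwhm_mm < self.voxel_size_mm:
            raise ValueError("noise FWHM must be at least one voxel")
        object.__setattr__(self, "effects", tuple(self.effects))

    def grid(self) -> VolumeGrid:
        affine = np.eye(4)
        affine[:3, :3] *= self.voxel_size_mm
        # center the grid on the world origin, MNI-like
        affine[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size_mm
        return VolumeGrid(tuple(self.shape), affine)


@dataclass
class Cohort:
    """Generated cohort: runs, cognition table, masks, and ground truth."""

    spec: CohortSpec
    runs: list[BoldRun]
    cognition: pd.DataFrame
    analysis_mask: BrainMask
    csf_mask: BrainMask
    wm_mask: BrainMask
    effect_masks: list[np.ndarray]
    subject_effect_magnitude: dict[str, float]

    @property
    def patients(self) -> list[BoldRun]:
        return [r for r in self.runs if r.group == "patient"]

    @property
    def controls(self) -> list[BoldRun]:
        return [r for r in self.runs if r.group == "control"]


def generate_motion_trace(n_volumes: int, severity: float, seed: int) -> MotionTrace:
    """Bounded random-walk motion trace.

    ``severity`` is the maximum absolute excursion (mm for translations,
    degrees for rotations): the walk is rescaled so its largest translation
    and largest rotation both equal ``severity``. Severity 0 gives all zeros.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    if severity == 0:
        return MotionTrace(np.zeros((n_volumes, 6)))
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 1.0, size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]  # start at zero like realignment output
    for cols in (slice(0, 3), slice(3, 6)):
        peak = np.abs(walk[:, cols]).max()
        if peak > 0:
            walk[:, cols] *= severity / peak
    return MotionTrace(walk)


def _shape_spectrum(data: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Scale in-band vs out-of-band amplitudes to the stated power profile."""
    T = data.shape[-1]
    spectrum = np.fft.rfft(data, axis=-1)
    freqs = np.fft.rfftfreq(T, d=spec.tr_s)
    low_w, high_w = spec.band_power_profile
    weights = np.where(
        (freqs >= STUDY_BAND.low_hz) & (freqs <= STUDY_BAND.high_hz), low_w, high_w
    )
    weights[0] = 0.0  # zero-mean baseline
    return np.fft.irfft(spectrum * weights, n=T, axis=-1)


def _baseline_run(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(size=tuple(spec.shape) + (spec.n_volumes,))
    sigma = spec.noise_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    noise = ndimage.gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0.0), mode="reflect")
    noise /= noise.std()  # keep unit scale after smoothing
    return _shape_spectrum(noise, spec)


def _latent_series(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Spatially constant, band-shaped latent series with unit variance."""
    s = _shape_spectrum(rng.standard_normal(spec.n_volumes), spec)
    sd = s.std()
    return s / sd if sd > 0 else s


def _effect_sphere(effect: EffectSpec, spec: CohortSpec, grid: VolumeGrid) -> np.ndarray:
    sphere = sphere_mask(effect.center_ijk, effect.radius_mm, grid)
    if not grid.in_bounds(effect.center_ijk) or not sphere.any():
        raise ValueError(f"effect sphere at {effect.center_ijk} outside grid")
    idx = np.argwhere(sphere)
    if (idx.min() == 0) or ((np.asarray(grid.shape) - 1 - idx.max(axis=0)) == 0).any():
        raise ValueError(f"effect sphere at {effect.center_ijk} touches the grid edge")
    return sphere


def _mix_with_latent(data, sphere, latent, weight):
    """Variance-preserving mix of in-sphere series with a shared latent."""
    weight = float(np.clip(weight, 0.0, 1.0))
    if weight == 0:
        return
    voxel_sd = data[sphere].std(axis=-1, keepdims=True)
    data[sphere] = (
        np.sqrt(1.0 - weight) * data[sphere] + np.sqrt(weight) * voxel_sd * latent
    )


def _apply_effects(
    data: np.ndarray,
    spheres: list[np.ndarray],
    spec: CohortSpec,
    group: str,
    subject_multiplier: float,
    latents: list[np.ndarray],
) -> None:
    # mixing effects first, amplitude last: the variance-preserving mixes use
    # baseline-shaped latents and would otherwise dilute an already-applied
    # in-band boost, breaking the contract that the low-frequency component
    # ends up multiplied by (1 + magnitude)
    ordered = sorted(
        zip(spec.effects, spheres, latents),
        key=lambda t: t[0].effect_type == "amplitude",
    )
    for effect, sphere, latent in ordered:
        if group != effect.target_group:
            continue
        mag = effect.magnitude * subject_multiplier
        if effect.effect_type == "amplitude":
            inband = _bandpass_series(
                data[sphere], STUDY_BAND.low_hz, STUDY_BAND.high_hz, spec.tr_s
            )
            data[sphere] += mag * inband
        elif effect.effect_type == "synchrony":
            _mix_with_latent(data, sphere, latent, mag)
        else:  # connectivity
            partner = sphere_mask(
                effect.partner_center_ijk, effect.radius_mm, spec.grid()
            )
            _mix_with_latent(data, sphere, latent, mag)
            _mix_with_latent(data, partner, latent, mag)


def _cohort_masks(spec: CohortSpec, grid: VolumeGrid):
    shape = np.asarray(spec.shape)
    analysis = np.zeros(spec.shape, dtype=bool)
    margin = np.maximum((shape * 0.125).astype(int), 1)
    analysis[
        margin[0] : shape[0] - margin[0],
        margin[1] : shape[1] - margin[1],
        margin[2] : shape[2] - margin[2],
    ] = True
    csf = np.zeros(spec.shape, dtype=bool)
    csf[: margin[0], : margin[1], : margin[2]] = True
    wm = np.zeros(spec.shape, dtype=bool)
    wm[shape[0] - margin[0] :, : margin[1], : margin[2]] = True
    return (
        BrainMask(analysis, grid),
        BrainMask(csf, grid),
        BrainMask(wm, grid),
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a deterministic two-group cohort from a :class:`CohortSpec`."""
    grid = spec.grid()
    spheres = [_effect_sphere(e, spec, grid) for e in spec.effects]
    analysis_mask, csf_mask, wm_mask = _cohort_masks(spec, grid)

    root = np.random.SeedSequence(spec.seed)
    n_subjects = 2 * spec.n_per_group
    # children: one per subject plus one for cohort-level draws
    seeds = root.spawn(n_subjects + 1)
    cohort_rng = np.random.default_rng(seeds[-1])

    runs: list[BoldRun] = []
    cog_rows = []
    subject_effect_magnitude: dict[str, float] = {}
    subject_index = 0
    for group in GROUPS:
        for i in range(spec.n_per_group):
            sid = f"{group}{i + 1:02d}"
            rng = np.random.default_rng(seeds[subject_index])
            data = _baseline_run(spec, rng)
            multiplier = float(cohort_rng.uniform(0.5, 1.5))
            latents = [_latent_series(spec, rng) for _ in spec.effects]
            _apply_effects(data, spheres, spec, group, multiplier, latents)
            targeted = [e.magnitude for e in spec.effects if e.target_group == group]
            eff_mag = multiplier * float(np.mean(targeted)) if targeted else 0.0
            subject_effect_magnitude[sid] = eff_mag

            motion_seed = int(seeds[subject_index].generate_state(1)[0] % (2**31))
            motion = generate_motion_trace(spec.n_volumes, spec.motion_severity, motion_seed)
            runs.append(
                BoldRun(
                    data,
                    grid,
                    tr_s=spec.tr_s,
                    motion=motion,
                    subject_id=sid,
                    group=group,
                )
            )
            row = {"subject_id": sid, "group": group}
            for domain in COGNITIVE_DOMAINS:
                slope = float(spec.cognition_coupling.get(domain, 0.0))
                row[domain] = (
                    spec.cognition_baseline
                    - slope * eff_mag
                    + cohort_rng.normal(0.0, spec.cognition_noise_sd)
                )
            cog_rows.append(row)
            subject_index += 1

    cognition = pd.DataFrame(cog_rows, columns=["subject_id", "group"] + COGNITIVE_DOMAINS)
    return Cohort(
        spec=spec,
        runs=runs,
        cognition=cognition,
        analysis_mask=analysis_mask,
        csf_mask=csf_mask,
        wm_mask=wm_mask,
        effect_masks=[s.copy() for s in spheres],
        subject_effect_magnitude=subject_effect_magnitude,
    )


def default_effect_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The package's standard effect cohort.

    One region (center (9, 9, 9), radius 8 mm) carries both an amplitude
    effect (magnitude 0.5) and a synchrony effect (weight 0.5) in the patient
    group, so all three local metrics differ there; a connectivity effect
    (weight 0.5) couples that region to a partner sphere at (15, 15, 15).
    Working-memory and sustained-attention scores are negatively coupled to
    subject effect strength (slope 30 score points per unit magnitude).
    """
    center = (9, 9, 9)
    partner = (15, 15, 15)
    effects = (
        EffectSpec("amplitude", center, 8.0, 0.5),
        EffectSpec("synchrony", center, 8.0, 0.5),
        EffectSpec("connectivity", center, 8.0, 0.5, partner_center_ijk=partner),
    )
    params = dict(
        effects=effects,
        cognition_coupling={"WM": 30.0, "SustA": 30.0},
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)
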