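# Methods

`restpipe` re-implements, as a tested library, the group analysis commonly
applied to small two-group resting-state fMRI cohorts: local activity
metrics, voxelwise two-sample inference with cluster-level multiple-comparison
control, data-driven seed definition, seed-based connectivity, network
labeling, and cognition-imaging correlation. Because the kind of clinical
dataset this analysis targets is rarely shareable, the package pairs the
analysis with a synthetic BOLD cohort generator whose ground truth makes
every stage testable end to end.

## Preprocessing model

A run enters the pipeline as a 4D series with a six-parameter motion trace.
Screening excludes runs whose motion strictly exceeds 3 mm of translation or
3 degrees of rotation at any volume; a run sitting exactly at the limit is
retained (a literal reading of "exceeding"). The first 10 volumes are
discarded, then each voxel's series is replaced by its OLS residual against a
28-column nuisance design: constant, centered linear trend, mean CSF signal,
mean white-matter signal, and the Friston-24 motion expansion (6 parameters,
their one-volume lags, both squared). The global signal is deliberately not a
regressor. Temporal filtering is an ideal (boxcar) frequency-domain band-pass
at 0.01–0.10 Hz with closed band edges: DFT bins strictly outside the band,
including DC, are zeroed. The ideal filter was chosen over an IIR design
because its action on single-frequency probes is exact, which makes the
filter unit-testable against closed forms; it is also the convention of the
DPABI/REST family of resting-state tools.

Spatial smoothing (Gaussian, FWHM 4 mm, reflect boundaries) is applied to
the *metric maps*, not to the time series. Pre-smoothing the series would
mechanically inflate ReHo, which measures concordance among neighboring
voxels, so the standard ReHo pipeline convention is followed; ALFF and fALFF
are insensitive to the order. This is the one place the pipeline departs
from listing smoothing as the final preprocessing step.

## Local metrics

With one-sided amplitude spectrum a(f) = 2|DFT(x)|/T (unpaired DC and
Nyquist bins scaled by 1/T):

* **ALFF** — mean of a(f) over bins with 0.01 ≤ f ≤ 0.10 Hz, computed on the
  band-passed series.
* **fALFF** — sum of a(f) over in-band bins divided by the sum over all bins
  with 0 < f ≤ Nyquist, computed on the *full-band* post-regression series
  (the denominator is the whole spectrum by definition); 0 where the
  denominator vanishes.
* **ReHo** — Kendall's coefficient of concordance W = 12S / (K²(T³−T))
  between the time-rank vectors of a voxel and its neighbors (27-voxel cubic
  neighborhood by default; 7 and 19 supported). At mask edges the
  neighborhood shrinks to the in-mask voxels rather than zero-padding, which
  would deflate edge values with artificial flat series. Ties get average
  ranks with no tie correction: BOLD values are continuous, so exact ties
  have measure zero.

Metric maps are z-standardized within the analysis mask (population sd)
before group testing, making them comparable across subjects and acquisition
sites; a flag disables this.

## Group inference

Voxelwise pooled-variance (Student) two-sample t tests, df = n₁+n₂−2;
zero-variance voxels get t = 0 with a logged count. Two corrections are
computed side by side:

* **GRF cluster-level correction.** Cluster-forming threshold at voxel
  p < 0.001 two-tailed (p/2 per tail); positive and negative tails are
  thresholded, clustered (26-connectivity), and tested independently, each
  at cluster p < 0.025, preserving the 0.05 family-wise level. Cluster
  p-values use the standard random-field results for t fields at threshold
  u: expected cluster count E[m] = resels × ρ₃(u) with the t-field
  Euler-characteristic density ρ₃, expected suprathreshold volume
  |mask| × P(T_df > u), cluster sizes P(n ≥ k) = exp(−βk^{2/3}) with
  β = (Γ(5/2)/n̄)^{2/3}, and corrected p = 1 − exp(−E[m]·P(n ≥ k)).
* **FDR correction.** Voxelwise Benjamini–Hochberg at q = 0.05 on two-tailed
  t p-values, surviving voxels clustered, clusters below 50 voxels dropped.

Smoothness is estimated from the within-group demeaned (residual) maps:
each map is standardized by its in-mask mean and sd, and for each axis
Λ = pooled variance of first differences between in-mask neighbors gives
FWHM = √(4 ln 2 / Λ) voxels. Map-level rather than voxel-level
standardization is used because normalizing by a per-voxel sd estimated from
a handful of maps injects sampling noise that biases the field rough; the
cost is an assumption of approximate stationarity, which holds for the
synthetic cohorts (noise is smoothed before temporal shaping precisely so
that the smoothness seen by GRF is stationary). The discrete-difference
estimator overestimates FWHM by a few percent at the smoothness used here;
simulations in the test suite bound the error at 15–20%.

Calibration: on pure-noise cohorts (10+10 subjects, 32³ voxels, 6 mm
smoothness) the measured family-wise rate of ≥1 surviving cluster is around
0.01–0.02 against the nominal 0.05. The conservatism is a known property of
the closed-form cluster-size distribution when the expected cluster size
approaches one voxel (smoothness ~2 voxels FWHM); the acceptance suite
asserts the rate stays within [0.01, 0.12].

## Seed definition and seed-based connectivity

Seeds are defined by triple-metric overlap: voxels where ALFF, fALFF and
ReHo *all* show a surviving group difference of the same sign form the
positive (patients > controls) and negative overlap sets; each set is split
into 26-connected components and components smaller than 19 voxels are
excluded — 19 being the voxel count of a 5 mm sphere on a 3 mm grid, the
conventional minimum ROI extent (`sphere_voxel_count` reproduces this
geometry exactly). Each surviving component becomes a seed region. Its
representative peak is the voxel maximizing |t_ALFF + t_fALFF + t_ReHo|; the
group-difference t values are used because they are dimensionless and
comparable across the three metrics (the peak rule accepts any triple of
comparable maps, so standardized group-mean-difference maps can be
substituted), and ties break to the lexicographically smallest index. The seed for connectivity analysis is the full overlap component, not
a sphere around its peak.

Seed-based analysis: the seed series is the unweighted mean of the region's
voxels in the band-passed (unsmoothed) series; every in-mask voxel's Pearson
correlation with it is Fisher-z transformed (|r| clipped to 1−10⁻⁷ so seed
voxels, which are retained, stay finite), the z maps are smoothed (4 mm) and
handed to the same group inference machinery.

## Atlas labeling

Peaks are named against an integer-labeled anatomical parcellation, and each
parcel is assigned to one of the canonical seven resting-state networks by
winner-takes-all voxel overlap (background excluded; no overlap →
"unassigned"; ties → lowest network index, logged). A background peak snaps
to the nearest labeled voxel within 6 mm, else "unlabeled". Label volumes
are resampled by nearest neighbor only — labels are categorical. Real atlas
files are optional inputs; the test suite runs on generated toy atlases
(block parcels, slab networks), so no atlas data ships with the package.

## Cognition

The cognitive battery is modeled as 16 standardized domain scores (overall
index plus 15 domains, mean ≈ 100). Group comparison is an uncorrected
pooled two-sample t test per domain — the battery analysis is exploratory by
design. Cognition-imaging association uses Spearman rank correlation
(average ranks on ties, rho = Pearson of ranks) between domain scores and
per-subject imaging markers, a marker being the unweighted mean of a
subject's metric or connectivity-z map over a significant cluster's voxels.
The two-tailed p uses the t approximation; for n ≤ 9 an exact permutation p
over all n! orderings is reported alongside, since the approximation is
rough at such sizes. Correlations pool both groups by default (a
patients-only flag exists) and the whole battery can be BH-FDR adjusted.

## Synthetic cohort generator

The generator emulates the data layout of a small two-group pediatric
resting-state study: two groups on a 3 mm isotropic template-style grid,
TR 2 s, six-parameter motion traces, and a per-subject cognitive table. The
default scale is 10 subjects per group, 24³ voxels, 120 volumes — sized so
the full pipeline runs in seconds per cohort on one CPU — and the
full-scale 15-per-group, 240-volume configuration is supported by overriding
the spec fields.

Baseline signal: unit-variance white noise, spatially smoothed (6 mm FWHM
default), then spectrally shaped by scaling in-band (0.01–0.10 Hz) vs
out-of-band amplitudes 1.0 : 0.5 — a low-frequency-dominant spectrum that
gives realistic baseline fALFF around 0.5–0.7. Effects are injected per
subject with a uniform(0.5, 1.5) multiplier on the nominal magnitude, so
subjects vary in effect strength:

* *amplitude* — the in-band component inside a sphere is multiplied by
  (1 + magnitude) for the target group;
* *synchrony* — in-sphere voxels are mixed with a shared band-shaped latent
  series using variance-preserving weights √(1−m), √m, raising local
  concordance without changing amplitude;
* *connectivity* — a sphere and a partner sphere share one latent series at
  weight m, raising their mutual correlation.

Mixing effects are applied before the amplitude boost: the latents carry the
baseline spectrum, so mixing after the boost would dilute the injected
in-band excess and break the (1 + magnitude) contract.

Cognitive scores are baseline − slope × subject effect magnitude + Gaussian
noise (baseline 103, noise sd 10); the standard effect cohort couples
working memory and sustained attention at slope 30 points per unit
magnitude, producing both the group-level score deficit and a recoverable
negative correlation with imaging markers. Motion traces are random walks
rescaled so the peak excursion equals the severity parameter (1 mm/deg
default, below the exclusion limits).

The standard effect cohort (`default_effect_cohort_spec`) injects
amplitude 0.5 + synchrony 0.5 at one 8 mm sphere and connectivity 0.5 to a
partner sphere. These magnitudes are free parameters of the simulation —
chosen as a moderately strong, plainly recoverable effect — not estimates of
any real study's effect sizes, which are typically unreported.

What the generator does **not** model: hemodynamic response shape,
physiological noise (cardiac/respiratory), scanner drift and artifacts,
motion-correlated signal corruption, anatomical structure, lesions, or
inter-subject anatomical variability. Passing recovery tests therefore
demonstrates the correctness and calibration of the analysis chain on data
satisfying its statistical assumptions, not robustness to the full
messiness of real pediatric fMRI.

## Numerical choices and degenerate inputs

* Voxel indices 0-based; all reported coordinates are world mm through the
  affine; affines are stored as given (no reorientation or resampling).
* TSV cluster tables round peak intensity to one decimal, matching the
  conventional reporting precision; the JSON twin keeps full precision.
* Zero-variance voxels: t = 0 (logged); fALFF = 0 where the spectrum is
  empty; ReHo = 0 where fewer than 2 in-mask neighbors exist; flat maps
  refuse standardization; a flat seed series refuses connectivity.
* Rank-deficient nuisance designs fall back to the pseudo-inverse with a
  warning; residual orthogonality holds either way.
* All tie-breaks (cluster peaks, ROI peaks, winner-takes-all) are
  deterministic and logged.

## Validation problem sizes

The acceptance suite runs at the scales its guarantees name: 300 null
replicates (10+10 subjects, 32³, 6 mm) for GRF calibration; 10 seeded
cohorts at the default 24³ / 120-volume / 10-per-group scale for pipeline
recovery and cognition-sign recovery; 100 random neighborhoods for the ReHo
oracle; 50 random vectors each for the BH and Spearman oracles.

## Known limitations

* The triple-overlap seed rule is conservative by construction: requiring
  three individually-corrected detections to intersect in ≥ 19 voxels means
  a moderately strong injected effect is recovered as a seed in roughly 8–10
  of 10 seeded cohorts at the default scale, with misses occurring when the
  three surviving clusters only partially coincide — not when the effect is
  undetected.

* GRF cluster inference is conservative (measured FWE ≈ 0.01–0.02 vs
  nominal 0.05) at ~2-voxel smoothness; at higher smoothness the closed
  forms calibrate better.
* Smoothness estimation assumes stationarity; strongly non-stationary
  residual fields would bias resel counts.
* No covariate adjustment (age/sex) in the group model — the intended use
  case matches groups by design; Welch correction is available behind a
  flag but pooled-variance t is the default, following the SPM-family
  convention.
* Permutation or TFCE inference, dynamic connectivity, and graph metrics
  are out of scope.
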