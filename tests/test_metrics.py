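"""ALFF/fALFF spectral metrics, ReHo (Kendall's W), standardization.

The ReHo oracle is an independent brute-force rank-sum implementation of
Kendall's coefficient of concordance, written from the definition (enumerate
rank sums per timepoint, sum squared deviations) rather than the closed form
used by the package.
"""

import numpy as np
import pytest
from scipy.stats import rankdata

from restpipe.core_io import BoldRun, BrainMask
from restpipe.metrics import (
    NeighborhoodSpec,
    alff,
    amplitude_spectrum,
    falff,
    kendall_w,
    reho,
    standardize_map,
    DegenerateMapError,
)
from restpipe.preprocess import BandDefinition, bandpass
from .conftest import make_grid

BAND = BandDefinition(0.01, 0.10)


def brute_force_kendall_w(series):
    """Independent oracle: Kendall's W via explicit rank-sum enumeration."""
    series = np.asarray(series, float)
    K, T = series.shape
    ranks = np.empty_like(series)
    for i in range(K):
        ranks[i] = rankdata(series[i])
    rank_sums = [sum(ranks[i][t] for i in range(K)) for t in range(T)]
    mean_sum = sum(rank_sums) / T
    S = sum((rs - mean_sum) ** 2 for rs in rank_sums)
    return 12.0 * S / (K * K * (T**3 - T))


def make_run(data, tr_s=2.0):
    grid = make_grid(shape=np.asarray(data).shape[:3])
    return BoldRun(np.asarray(data, float), grid, tr_s=tr_s)


def full_mask_for(run):
    return BrainMask(np.ones(run.grid.shape, bool), run.grid)


class TestKendallW:
    def test_identical_series_give_one(self, rng):
        s = rng.standard_normal(30)
        series = np.tile(s, (27, 1))
        assert kendall_w(series) == pytest.approx(1.0)

    def test_small_example_matches_brute_force(self):
        # ranks (1,2,3,4), (1,2,3,4), (4,3,2,1): rank sums 6,7,8,9 -> S=5,
        # W = 60/540 = 1/9
        series = np.array(
            [[0.1, 0.2, 0.3, 0.4], [1.0, 2.0, 3.0, 4.0], [9.0, 7.0, 5.0, 3.0]]
        )
        w = kendall_w(series)
        assert w == pytest.approx(brute_force_kendall_w(series), abs=1e-12)
        assert w == pytest.approx(1.0 / 9.0, abs=1e-12)

    def test_oracle_equivalence_on_random_neighborhoods(self, rng):
        for _ in range(100):
            K = int(rng.integers(2, 28))
            T = int(rng.integers(5, 40))
            series = rng.standard_normal((K, T))
            assert kendall_w(series) == pytest.approx(
                brute_force_kendall_w(series), abs=1e-10
            )


class TestReho:
    def test_map_matches_brute_force_per_voxel(self, rng):
        data = rng.standard_normal((6, 6, 6, 20))
        run = make_run(data)
        mask_arr = rng.random((6, 6, 6)) > 0.2
        mask_arr[3, 3, 3] = True
        mask = BrainMask(mask_arr, run.grid)
        out = reho(run, mask, NeighborhoodSpec(27))
        # check a handful of voxels, including edges, against the oracle on
        # the in-mask neighborhood
        for ijk in [(0, 0, 0), (3, 3, 3), (5, 5, 5), (2, 4, 1)]:
            if not mask_arr[ijk]:
                continue
            neigh = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        p = (ijk[0] + di, ijk[1] + dj, ijk[2] + dk)
                        if all(0 <= c < 6 for c in p) and mask_arr[p]:
                            neigh.append(data[p])
            expected = brute_force_kendall_w(np.array(neigh)) if len(neigh) >= 2 else 0.0
            assert out.values[ijk] == pytest.approx(expected, abs=1e-10)

    def test_values_in_unit_interval(self, rng):
        run = make_run(rng.standard_normal((6, 6, 6, 15)))
        out = reho(run, full_mask_for(run))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_synchronized_region_scores_high(self, rng):
        data = rng.standard_normal((7, 7, 7, 30))
        shared = rng.standard_normal(30)
        data[2:5, 2:5, 2:5] = shared + 0.05 * rng.standard_normal((3, 3, 3, 30))
        run = make_run(data)
        out = reho(run, full_mask_for(run))
        assert out.values[3, 3, 3] > 0.9
        assert out.values[3, 3, 3] > out.values[0, 0, 0] + 0.3

    def test_too_few_timepoints_rejected(self, rng):
        run = make_run(rng.standard_normal((4, 4, 4, 2)))
        with pytest.raises(ValueError):
            reho(run, full_mask_for(run))


class TestAlff:
    def test_zero_series_zero_alff(self):
        run = make_run(np.zeros((3, 3, 3, 100)))
        out = alff(run, BAND, full_mask_for(run))
        assert not out.values.any()

    def test_pure_tone_amplitude(self):
        # 0.05 Hz is bin 10 of a 100-volume TR-2 run; a pure tone of
        # amplitude A contributes A to that bin, so ALFF = A / n_band_bins
        T, tr, A = 100, 2.0, 3.0
        t = np.arange(T) * tr
        series = A * np.sin(2 * np.pi * 0.05 * t)
        run = make_run(np.broadcast_to(series, (3, 3, 3, T)).copy(), tr_s=tr)
        out = alff(run, BAND, full_mask_for(run))
        freqs = np.fft.rfftfreq(T, d=tr)
        n_bins = int(((freqs >= 0.01) & (freqs <= 0.10)).sum())
        assert out.values[1, 1, 1] == pytest.approx(A / n_bins, rel=1e-6)

    def test_linearity(self, rng):
        data = rng.standard_normal((3, 3, 3, 80))
        run1 = make_run(data)
        run2 = make_run(2.0 * data)
        mask = full_mask_for(run1)
        a1 = alff(run1, BAND, mask).values
        a2 = alff(run2, BAND, mask).values
        assert np.allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_parseval_consistency(self, rng):
        # for a band-passed (zero-DC, zero-Nyquist) series the sum of squared
        # one-sided amplitudes equals (2/T) x signal energy
        run = bandpass(make_run(rng.standard_normal((2, 2, 2, 120))), BAND)
        _, amps = amplitude_spectrum(run.data, run.tr_s)
        energy = (run.data**2).sum(axis=-1)
        assert np.allclose((amps**2).sum(axis=-1), 2.0 / 120 * energy, rtol=1e-9)


class TestFalff:
    def test_pure_inband_tone_gives_one(self):
        T, tr = 100, 2.0
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * 0.05 * t)
        run = make_run(np.broadcast_to(series, (3, 3, 3, T)).copy(), tr_s=tr)
        out = falff(run, BAND, full_mask_for(run))
        assert out.values[1, 1, 1] == pytest.approx(1.0, abs=1e-6)

    def test_pure_outband_tone_gives_zero(self):
        T, tr = 100, 2.0
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * 0.2 * t)
        run = make_run(np.broadcast_to(series, (3, 3, 3, T)).copy(), tr_s=tr)
        out = falff(run, BAND, full_mask_for(run))
        assert out.values[1, 1, 1] == pytest.approx(0.0, abs=1e-6)

    def test_white_noise_expectation_matches_bin_fraction(self, rng):
        # flat expected amplitude spectrum: mean fALFF ~ in-band bin count /
        # nonzero bin count
        T, tr = 120, 2.0
        data = rng.standard_normal((10, 10, 10, T))
        run = make_run(data, tr_s=tr)
        out = falff(run, BAND, full_mask_for(run))
        freqs = np.fft.rfftfreq(T, d=tr)
        expected = ((freqs >= 0.01) & (freqs <= 0.10)).sum() / (freqs > 0).sum()
        assert out.values.mean() == pytest.approx(expected, abs=0.01)

    def test_values_in_unit_interval(self, rng):
        run = make_run(rng.standard_normal((5, 5, 5, 64)))
        out = falff(run, BAND, full_mask_for(run))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        run = make_run(rng.standard_normal((6, 6, 6, 50)))
        mask = full_mask_for(run)
        z = standardize_map(alff(run, BAND, mask), mask)
        inside = z.values[mask.include]
        assert inside.mean() == pytest.approx(0.0, abs=1e-9)
        assert inside.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        from restpipe.core_io import StatMap

        grid = make_grid(shape=(5, 5, 5))
        mask = BrainMask(np.ones((5, 5, 5), bool), grid)
        values = rng.standard_normal((5, 5, 5))
        z1 = standardize_map(StatMap(values, grid, kind="alff"), mask)
        z2 = standardize_map(StatMap(3.5 * values + 11.0, grid, kind="alff"), mask)
        assert np.allclose(z1.values, z2.values, atol=1e-10)

    def test_two_voxel_convention(self):
        # {1, 3} -> {-1, +1}: population (denominator n) standard deviation
        from restpipe.core_io import StatMap

        grid = make_grid(shape=(2, 1, 1))
        mask = BrainMask(np.ones((2, 1, 1), bool), grid)
        smap = StatMap(np.array([1.0, 3.0]).reshape(2, 1, 1), grid, kind="alff")
        z = standardize_map(smap, mask)
        assert np.allclose(z.values.ravel(), [-1.0, 1.0])

    def test_flat_map_rejected(self):
        from restpipe.core_io import StatMap

        grid = make_grid(shape=(3, 3, 3))
        mask = BrainMask(np.ones((3, 3, 3), bool), grid)
        with pytest.raises(DegenerateMapError):
            standardize_map(StatMap(np.ones((3, 3, 3)), grid, kind="alff"), mask)


def test_amplitude_effect_recovered_in_alff(tiny_cohort):
    """Parameter-recovery smoke test: injected amplitude effect raises
    in-sphere ALFF for the target group."""
    sphere = tiny_cohort.effect_masks[0]
    mask = tiny_cohort.analysis_mask
    means = {"patient": [], "control": []}
    for run in tiny_cohort.runs:
        z = standardize_map(alff(run, BAND, mask), mask)
        means[run.group].append(z.values[sphere].mean())
    assert np.mean(means["patient"]) > np.mean(means["control"]) + 0.5
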