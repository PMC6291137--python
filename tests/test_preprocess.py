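"""Noise estimation, peak picking, alignment, calibration, binning."""

from __future__ import annotations

import math

import numpy as np
import pytest

from aurimsi import synth
from aurimsi.chem import default_reference_set
from aurimsi.io import MSIDataset
from aurimsi.preprocess import (
    CalibrationError,
    Peak,
    align_dataset,
    apex_mz,
    apply_calibration,
    build_peak_matrix,
    calibrate,
    estimate_noise,
    mean_spectrum,
    pick_peaks,
)

REFS = default_reference_set()


@pytest.fixture(scope="module")
def uniform_grid6():
    """6x6 homogeneous scene: enough pixels for a low-noise mean spectrum."""
    ds, _ = synth.render_dataset(
        synth.default_scene("uniform", seed=11, grid_shape=(6, 6)),
        synth.InstrumentModel(), 11,
    )
    return ds


def _toy_dataset(vectors, axis=None):
    axis = np.linspace(100.0, 110.0, len(vectors[0])) if axis is None else axis
    coords = np.array([(i, 0) for i in range(len(vectors))])
    return MSIDataset(coords, [axis] * len(vectors),
                      [np.asarray(v, float) for v in vectors], shared_axis=True)


class TestEstimateNoise:
    def test_recovers_known_sd(self):
        rng = np.random.default_rng(42)
        est = estimate_noise(rng.normal(0, 1.0, 10_000))
        assert 0.8 <= est.mean() <= 1.2

    def test_scale_equivariant(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1.0, 20_000)
        r = estimate_noise(2 * y).mean() / estimate_noise(y).mean()
        assert r == pytest.approx(2.0, rel=1e-9)

    def test_zero_spectrum_gets_floor(self):
        est = estimate_noise(np.zeros(5000))
        assert np.all(est == 1e-10)

    def test_robust_to_sparse_peaks(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1.0, 20_000)
        y[5000:5010] += 500.0
        assert estimate_noise(y).mean() == pytest.approx(1.0, abs=0.15)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            estimate_noise(np.zeros(100), window=512)


class TestPickPeaks:
    def test_noiseless_gaussian_centroid(self):
        axis = np.linspace(495, 505, 4000)
        step = axis[1] - axis[0]
        y = 100 * np.exp(-0.5 * ((axis - 500.0) / 0.03) ** 2)
        peaks = pick_peaks(axis, y, snr_min=5, noise=np.full(axis.size, 1e-6),
                           subtract_baseline=False)
        assert len(peaks) == 1
        assert abs(peaks[0].mz - 500.0) < step / 4

    def test_infinite_threshold_empty(self):
        axis = np.linspace(100, 200, 5000)
        rng = np.random.default_rng(0)
        assert pick_peaks(axis, rng.normal(10, 1, 5000), snr_min=np.inf) == []

    @pytest.mark.parametrize("c", [3.7, 0.25])
    def test_scale_equivariance(self, c, uniform_noisy):
        _, _, ds, _ = uniform_noisy
        mz, y = ds.mzs[0], np.asarray(ds.intensities[0], float)
        base = pick_peaks(mz, y)
        scaled = pick_peaks(mz, c * y)
        assert len(base) == len(scaled)
        for p, q in zip(base, scaled):
            assert q.mz == pytest.approx(p.mz, abs=1e-9)
            assert q.height == pytest.approx(c * p.height, rel=1e-9)
            assert q.area == pytest.approx(c * p.area, rel=1e-9)
            assert q.snr == pytest.approx(p.snr, rel=1e-6)

    def test_recovers_species_with_accurate_heights(self, uniform_noiseless):
        _, _, ds, truth = uniform_noiseless
        for i in range(ds.n_pixels):
            peaks = pick_peaks(ds.mzs[i], ds.intensities[i], snr_min=5,
                               noise=np.full(ds.mzs[i].size, 1e-9), subtract_baseline=False)
            got_mz = np.array([p.mz for p in peaks])
            got_h = np.array([p.height for p in peaks])
            for mz, h, is_bg in zip(truth.species_mz, truth.true_heights[i],
                                    truth.species_is_background):
                k = np.argmin(np.abs(got_mz - mz))
                assert abs(got_mz[k] - mz) / mz < 2e-6  # within 2 ppm
                if not is_bg:  # species peaks are wide enough for <1% height bias
                    assert got_h[k] == pytest.approx(h, rel=0.01)


class TestAlignment:
    def test_requires_two_pixels(self):
        ds = _toy_dataset([np.zeros(100)])
        with pytest.raises(ValueError, match="2 pixels"):
            align_dataset(ds)

    def test_fixed_point_on_identical_spectra(self):
        rng = np.random.default_rng(5)
        axis = np.linspace(100, 900, 30_000)
        y = rng.normal(5, 1, 30_000)
        for c in (150.0, 400.0, 850.0):
            y += 80 * np.exp(-0.5 * ((axis - c) / 0.05) ** 2)
        ds = _toy_dataset([y, y.copy()], axis)
        out = align_dataset(ds)
        for v in out.intensities:
            assert np.allclose(v, y, atol=1e-6)

    def test_zero_drift_near_identity(self, uniform_noisy):
        _, _, ds, _ = uniform_noisy
        out = align_dataset(ds)
        for before, after in zip(ds.intensities, out.intensities):
            before = np.asarray(before, float)
            assert np.corrcoef(before, after)[0, 1] > 0.999

    def test_reduces_apex_scatter_and_conserves_intensity(self):
        inst = synth.InstrumentModel(drift_da_sd=0.05)
        scene = synth.default_scene("uniform", seed=13, grid_shape=(3, 3))
        ds, _ = synth.render_dataset(scene, inst, 13)
        au1 = 196.96656879
        pre = [apex_mz(ds.mzs[i], ds.intensities[i], au1) for i in range(ds.n_pixels)]
        out = align_dataset(ds)
        post = [apex_mz(out.mzs[i], out.intensities[i], au1) for i in range(out.n_pixels)]
        assert np.std(pre) / max(np.std(post), 1e-12) >= 5.0
        for before, after in zip(ds.intensities, out.intensities):
            assert float(np.sum(after)) == pytest.approx(float(np.sum(before)), rel=0.005)


class TestMeanSpectrum:
    def test_single_pixel_identity(self):
        ds = _toy_dataset([np.arange(100.0), np.arange(100.0)])
        _, m = mean_spectrum(ds)
        assert np.array_equal(m, np.arange(100.0))

    def test_two_pixel_average(self):
        v = np.linspace(0, 1, 50)
        _, m = mean_spectrum(_toy_dataset([v, 3 * v]))
        assert np.allclose(m, 2 * v)

    def test_mixed_axes_rejected(self):
        axis = np.linspace(100, 110, 50)
        ds = MSIDataset(np.array([[0, 0], [1, 0]]), [axis, axis * 1.001],
                        [np.zeros(50), np.zeros(50)], shared_axis=False)
        with pytest.raises(ValueError, match="align"):
            mean_spectrum(ds)


class TestCalibration:
    def test_zero_drift_gives_identity_model(self, uniform_grid6):
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        model = calibrate(mz, mean, REFS)
        assert model.unmatched == []
        assert all(abs(r) < 1.0 for r in model.residuals_ppm.values())
        grid = np.linspace(mz[0], mz[-1], 1000)
        assert np.allclose(model(grid), grid, rtol=3e-6)

    def test_recovers_injected_affine_drift(self, uniform_grid6):
        # same spectrum reported on an axis off by 80 ppm and +0.02 Da
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        drifted = mz * (1 + 80e-6) + 0.02
        model = calibrate(drifted, mean, REFS)
        for r in model.residuals_ppm.values():
            assert abs(r) < 3.0
        # the model must invert the injected perturbation
        assert np.allclose(model(drifted), mz, atol=1e-3)

    def test_underdetermined_fit_rejected(self, uniform_grid6):
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        with pytest.raises(CalibrationError, match="references"):
            calibrate(mz, mean, REFS[:1], degree=2)

    def test_missing_references_listed(self, uniform_grid6):
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        from aurimsi.chem import ReferencePeak

        fake = [ReferencePeak(f"ghost{i}", 300.0 + 7 * i) for i in range(5)]
        with pytest.raises(CalibrationError, match="ghost0"):
            calibrate(mz, mean, fake)

    def test_model_strictly_increasing(self, uniform_grid6):
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        model = calibrate(mz, mean, REFS)
        grid = np.linspace(mz[0], mz[-1], 10_000)
        assert np.all(np.diff(model(grid)) > 0)


class TestApplyCalibration:
    def test_identity_model_leaves_dataset_unchanged(self, uniform_grid6):
        ds = uniform_grid6
        from aurimsi.preprocess import CalibrationModel

        ident = CalibrationModel(np.array([1.0, 0.0, 0.0]), 2, [], fit_range=(70, 1200))
        out = apply_calibration(ds, ident)
        assert np.allclose(out.mz_axis, ds.mz_axis, rtol=1e-12)

    def test_apply_then_inverse_recovers_axis(self, uniform_grid6):
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        drifted = mz * (1 + 50e-6) + 0.01
        model = calibrate(drifted, mean, REFS)
        assert np.allclose(model(drifted), mz, atol=1e-3)

    def test_peak_list_ordering_preserved(self, uniform_grid6):
        ds = uniform_grid6
        mz, mean = mean_spectrum(ds)
        model = calibrate(mz, mean, REFS)
        peaks = [Peak(100.0 + i, 1.0, 1.0, 10.0) for i in range(50)]
        out = apply_calibration(peaks, model)
        assert all(a.mz < b.mz for a, b in zip(out, out[1:]))


class TestPeakMatrix:
    def test_single_pixel_one_bin_per_peak(self):
        peaks = [Peak(100.0, 1.0, 1.0, 10.0), Peak(200.0, 2.0, 2.0, 10.0)]
        m = build_peak_matrix([peaks], np.array([[0, 0]]))
        assert m.n_bins == 2
        assert np.allclose(m.heights, [[1.0, 2.0]])

    @pytest.mark.parametrize("gap_ppm,expected_bins", [(10, 1), (30, 2)])
    def test_gap_threshold_semantics(self, gap_ppm, expected_bins):
        mz0 = 500.0
        mz1 = mz0 * (1 + gap_ppm * 1e-6)
        lists = [[Peak(mz0, 1.0, 1.0, 10)], [Peak(mz1, 1.0, 1.0, 10)]]
        m = build_peak_matrix(lists, np.array([[0, 0], [1, 0]]), bin_tolerance_ppm=20)
        assert m.n_bins == expected_bins

    def test_row_sums_conserved(self):
        rng = np.random.default_rng(8)
        lists, coords = [], []
        for i in range(5):
            n = rng.integers(3, 20)
            mzs = np.sort(rng.uniform(100, 1000, n))
            lists.append([Peak(float(m), float(h), 1.0, 10)
                          for m, h in zip(mzs, rng.lognormal(2, 1, n))])
            coords.append((i, 0))
        m = build_peak_matrix(lists, np.array(coords))
        for i, plist in enumerate(lists):
            assert m.heights[i].sum() == pytest.approx(sum(p.height for p in plist))

    def test_bin_count_matches_injected_species(self, uniform_noiseless):
        _, _, ds, truth = uniform_noiseless
        lists = [
            pick_peaks(ds.mzs[i], ds.intensities[i], snr_min=5,
                       noise=np.full(ds.mzs[i].size, 1e-9), subtract_baseline=False)
            for i in range(ds.n_pixels)
        ]
        m = build_peak_matrix(lists, ds.coordinates)
        assert m.n_bins == len(truth.species_mz)
        assert np.allclose(np.sort(m.bin_mz), np.sort(truth.species_mz), atol=5e-3)
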