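"""Layer metrics: TIC with gold exclusion, fragmentation ratio, top-K."""

from __future__ import annotations

import math

import numpy as np
import pytest

from aurimsi.preprocess import Peak, PeakMatrix, build_peak_matrix, pick_peaks
from aurimsi.metrics import (
    compare_conditions,
    condition_metrics,
    fragmentation_ratio,
    gold_exclusion_windows,
    tic,
    top_k_pixels,
)

from conftest import rand_peak_list


def _peaks(*pairs):
    return [Peak(m, h, h, 10.0) for m, h in pairs]


class TestTic:
    def test_gold_peak_excluded(self):
        peaks = _peaks((196.97, 100.0), (300.0, 50.0))
        assert tic(peaks, gold_exclusion_windows()) == 50.0

    def test_no_exclusions_is_plain_sum(self):
        peaks = _peaks((196.97, 100.0), (300.0, 50.0))
        assert tic(peaks) == 150.0

    def test_exclusion_never_increases(self):
        rng = np.random.default_rng(17)
        windows = gold_exclusion_windows()
        for _ in range(50):
            plist = rand_peak_list(rng, int(rng.integers(1, 40)))
            assert tic(plist, windows) <= tic(plist)

    def test_matches_truth_on_uniform_scene(self, uniform_noiseless):
        _, _, ds, truth = uniform_noiseless
        gold = {"Au1", "Au2", "Au3", "Au4", "Au5"}
        for i in range(ds.n_pixels):
            plist = pick_peaks(ds.mzs[i], ds.intensities[i], snr_min=5,
                               noise=np.full(ds.mzs[i].size, 1e-9), subtract_baseline=False)
            expected = sum(h for name, h in zip(truth.species_names, truth.true_heights[i])
                           if name not in gold)
            assert tic(plist, gold_exclusion_windows()) == pytest.approx(expected, rel=0.02)


class TestFragmentationRatio:
    def test_direct_example(self):
        peaks = _peaks((184.07, 10.0), (700.0, 40.0), (800.0, 60.0))
        assert fragmentation_ratio(peaks) == pytest.approx(0.1)

    def test_zero_when_fragment_absent(self):
        peaks = _peaks((700.0, 40.0), (800.0, 60.0))
        assert fragmentation_ratio(peaks) == 0.0

    def test_infinite_when_denominator_empty(self):
        peaks = _peaks((184.07, 10.0))
        assert math.isinf(fragmentation_ratio(peaks))

    def test_scale_invariance(self):
        peaks = _peaks((184.05, 7.0), (550.0, 12.0), (900.0, 3.0))
        scaled = [Peak(p.mz, 13.7 * p.height, 13.7 * p.area, p.snr) for p in peaks]
        assert fragmentation_ratio(scaled) == pytest.approx(fragmentation_ratio(peaks))

    def test_brute_force_equivalence(self):
        # oracle: literal re-statement of the definition over raw tuples
        rng = np.random.default_rng(99)
        for _ in range(100):
            plist = rand_peak_list(rng, int(rng.integers(1, 60)))
            frag_candidates = [p.height for p in plist if abs(p.mz - 184.07) <= 0.1]
            denom = sum(p.height for p in plist if 500.0 <= p.mz <= 1000.0)
            if not frag_candidates:
                expected = 0.0
            elif denom == 0:
                expected = math.inf
            else:
                expected = max(frag_candidates) / denom
            assert fragmentation_ratio(plist) == expected


class TestTopK:
    def test_k_at_least_n_is_identity(self):
        vals = np.array([3.0, 1.0, 2.0])
        coords = np.array([[0, 0], [1, 0], [2, 0]])
        assert np.array_equal(top_k_pixels(vals, coords, 10), [0, 1, 2])

    def test_k1_finds_brightest(self):
        vals = np.array([3.0, 9.0, 2.0])
        coords = np.array([[0, 0], [1, 0], [2, 0]])
        assert np.array_equal(top_k_pixels(vals, coords, 1), [1])

    def test_selection_invariant_under_permutation(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 100, 30)
        coords = np.array([(i % 6, i // 6) for i in range(30)])
        sel = top_k_pixels(vals, coords, 10)
        perm = rng.permutation(30)
        sel_p = top_k_pixels(vals[perm], coords[perm], 10)
        assert {tuple(coords[i]) for i in sel} == {tuple(coords[perm][i]) for i in sel_p}

    def test_ties_broken_by_grid_order(self):
        vals = np.ones(4)
        coords = np.array([[1, 1], [0, 0], [1, 0], [0, 1]])
        sel = top_k_pixels(vals, coords, 2)
        assert {tuple(coords[i]) for i in sel} == {(0, 0), (1, 0)}

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            top_k_pixels(np.ones(3), np.zeros((3, 2), int), 0)


def _matrix_from_heights(heights: dict[float, np.ndarray], coords) -> PeakMatrix:
    bins = np.array(sorted(heights))
    mat = np.stack([heights[m] for m in bins], axis=1)
    return PeakMatrix(np.asarray(coords), bins, mat.astype(float))


class TestCompareConditions:
    def _condition(self, scale=1.0, n=9):
        coords = np.array([(i % 3, i // 3) for i in range(n)])
        rng = np.random.default_rng(1)
        return _matrix_from_heights(
            {
                184.07: scale * rng.uniform(5, 10, n),
                196.9666: rng.uniform(50, 60, n),   # gold, excluded
                700.5: scale * rng.uniform(30, 40, n),
                850.2: scale * rng.uniform(20, 30, n),
            },
            coords,
        )

    def test_doubled_intensities_double_median_tic(self):
        a, b = self._condition(1.0), self._condition(2.0)
        _, summary = compare_conditions([("A", a), ("B", b)], k=9)
        med = summary.set_index(["condition", "metric"])["median"]
        assert med["B", "tic"] == pytest.approx(2 * med["A", "tic"], rel=1e-6)
        assert med["B", "fragmentation_ratio"] == pytest.approx(
            med["A", "fragmentation_ratio"], rel=1e-6
        )

    def test_single_condition_block(self):
        per_pixel, summary = compare_conditions([("only", self._condition())], k=5)
        assert set(per_pixel["condition"]) == {"only"}
        assert len(per_pixel) == 5
        assert len(summary) == 2

    def test_order_invariance(self):
        a, b = self._condition(1.0), self._condition(3.0)
        p1, s1 = compare_conditions([("A", a), ("B", b)])
        p2, s2 = compare_conditions([("B", b), ("A", a)])
        assert p1.equals(p2) and s1.equals(s2)

    def test_zero_signal_condition(self):
        # a blank acquisition: no fragment, tiny residual peaks
        coords = np.array([(i, 0) for i in range(4)])
        blank = _matrix_from_heights({400.0: np.full(4, 0.5)}, coords)
        per_pixel, _ = compare_conditions([("0 s", blank)], k=4)
        assert np.all(per_pixel["fragmentation_ratio"] == 0.0)
        assert np.all(per_pixel["tic"] <= 0.5)


def test_condition_metrics_ranks_by_gold_excluded_tic():
    coords = np.array([[0, 0], [1, 0]])
    # pixel 0 is brighter only through its gold peak
    m = _matrix_from_heights(
        {196.9666: np.array([1000.0, 1.0]), 700.0: np.array([10.0, 50.0])}, coords
    )
    out = condition_metrics(m, "c", k=1)
    assert (out["x"].iloc[0], out["y"].iloc[0]) == (1, 0)
    out_raw = condition_metrics(m, "c", k=1, rank_gold_excluded=False)
    assert (out_raw["x"].iloc[0], out_raw["y"].iloc[0]) == (0, 0)
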