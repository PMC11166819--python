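"""Defect burden metrics: percentages, side splits, and the DDI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mplung as m
from mplung.cohort_stats import CDH_COHORT_SUMMARIES, CDH_SIDE_SUMMARIES
from mplung.errors import ConfigurationError


def _sided_mask(shape=(2, 10, 10)):
    labels = np.zeros(shape, dtype=np.uint8)
    labels[:, 2:8, 1:5] = 1  # right
    labels[:, 2:8, 6:9] = 2  # left
    return m.LungMask(labels)


class TestDefectPercentage:
    def test_one_in_ten(self):
        lung = np.zeros((1, 5, 5), dtype=bool)
        lung[0, 0, :5] = True
        lung[0, 1, :5] = True
        defect = np.zeros_like(lung)
        defect[0, 0, 0] = True
        assert m.defect_percentage(defect, lung) == 10.0

    def test_empty_defect_is_zero(self):
        lung = np.ones((1, 4, 4), dtype=bool)
        assert m.defect_percentage(np.zeros_like(lung), lung) == 0.0

    def test_empty_lung_rejected(self):
        lung = np.zeros((1, 4, 4), dtype=bool)
        with pytest.raises(ConfigurationError):
            m.defect_percentage(np.zeros_like(lung), lung)

    def test_defect_outside_lung_rejected(self):
        lung = np.zeros((1, 4, 4), dtype=bool)
        lung[0, 0, 0] = True
        defect = np.zeros_like(lung)
        defect[0, 1, 1] = True
        with pytest.raises(ConfigurationError):
            m.defect_percentage(defect, lung)


class TestMatchedDefects:
    def test_disjoint_masks_give_zero(self):
        lung = np.ones((1, 6, 6), dtype=bool)
        v = np.zeros_like(lung)
        q = np.zeros_like(lung)
        v[0, 0, :3] = True
        q[0, 5, :3] = True
        assert m.matched_defect_percentage(v, q, lung) == 0.0

    def test_identical_masks_equal_their_percentage(self):
        lung = np.ones((1, 10, 10), dtype=bool)
        v = np.zeros_like(lung)
        v[0, :3, :4] = True  # 12 of 100
        assert m.matched_defect_percentage(v, v.copy(), lung) == 12.0

    def test_independent_random_masks_match_binomial_expectation(self, rng):
        p = q = 0.3
        n = 5000
        lung = np.ones((1, 100, 50), dtype=bool)
        v = rng.random((1, 100, 50)) < p
        w = rng.random((1, 100, 50)) < q
        got = m.matched_defect_percentage(v, w, lung)
        sd = 100 * np.sqrt(p * q * (1 - p * q) / n)
        assert abs(got - 100 * p * q) <= 3 * sd


class TestSideSpecific:
    def test_left_only_defects(self):
        mask = _sided_mask()
        defect = np.zeros_like(mask.lung)
        left_voxels = np.argwhere(mask.side("left"))[:5]
        for s, r, c in left_voxels:
            defect[s, r, c] = True
        res = m.side_specific_percentages(defect, mask, hernia_side="left")
        n_lung = mask.lung.sum()
        assert res["affected"] == pytest.approx(500 / n_lung)
        assert res["non_affected"] == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_side_values_sum_to_whole_lung_exactly(self, seed):
        rng = np.random.default_rng(seed)
        mask = _sided_mask()
        defect = mask.lung & (rng.random(mask.lung.shape) < 0.3)
        res = m.side_specific_percentages(defect, mask, hernia_side="right")
        whole = m.defect_percentage(defect, mask.lung)
        assert res["affected"] + res["non_affected"] == pytest.approx(
            whole, abs=1e-12)

    def test_no_hernia_keeps_left_right_keys(self):
        mask = _sided_mask()
        res = m.side_specific_percentages(np.zeros_like(mask.lung), mask,
                                          hernia_side=None)
        assert set(res) == {"left", "right"}

    def test_missing_side_label_rejected(self):
        labels = np.zeros((1, 6, 6), dtype=np.uint8)
        labels[0, 1:4, 1:4] = 1  # right lung only
        with pytest.raises(ConfigurationError):
            m.side_specific_percentages(np.zeros((1, 6, 6), dtype=bool),
                                        m.LungMask(labels), "left")

    def test_published_side_means_sum_to_whole_lung_means(self):
        """Documentation of the convention: with the whole-lung denominator
        the published per-side VDP/QDP means add up to the whole-lung
        values (e.g. 8.62 + 6.91 = 15.53)."""
        for outcome, groups in (("vdp_pct", ("control", "small_CDH",
                                             "large_CDH")),
                                ("qdp_pct", ("control", "small_CDH"))):
            for g in groups:
                sides = CDH_SIDE_SUMMARIES[outcome][g]
                total = sides["non_affected"][0] + sides["affected"][0]
                whole = CDH_COHORT_SUMMARIES[outcome][g][0]
                assert total == pytest.approx(whole, abs=0.011)


class TestDDI:
    def _mask_with(self, defect_coords, shape=(1, 30, 30)):
        lung = np.ones(shape, dtype=bool)
        defect = np.zeros(shape, dtype=bool)
        for s, r, c in defect_coords:
            defect[s, r, c] = True
        return defect, lung

    def test_no_defects_zero(self):
        defect, lung = self._mask_with([])
        assert m.defect_distribution_index(defect, lung) == 0.0

    def test_isolated_voxels_far_apart_zero(self):
        coords = [(0, r, c) for r in (2, 12, 22) for c in (2, 12, 22)]
        defect, lung = self._mask_with(coords)
        assert m.defect_distribution_index(defect, lung, radius=3) == 0.0

    def test_solid_square_beats_scattered(self):
        square, lung = self._mask_with(
            [(0, 10 + i, 10 + j) for i in range(5) for j in range(5)])
        scattered, _ = self._mask_with(
            [(0, 1 + 5 * i, 1 + 5 * j) for i in range(5) for j in range(5)])
        ddi_sq = m.defect_distribution_index(square, lung)
        ddi_sc = m.defect_distribution_index(scattered, lung)
        assert ddi_sc == 0.0
        assert ddi_sq > ddi_sc

    def test_merging_clusters_never_decreases_ddi(self):
        # two 3x3 squares far apart vs one 3x6 block of equal total size
        separated, lung = self._mask_with(
            [(0, 2 + i, 2 + j) for i in range(3) for j in range(3)]
            + [(0, 20 + i, 20 + j) for i in range(3) for j in range(3)])
        merged, _ = self._mask_with(
            [(0, 10 + i, 10 + j) for i in range(3) for j in range(6)])
        assert m.defect_distribution_index(merged, lung) >= \
            m.defect_distribution_index(separated, lung)

    def test_translation_and_slice_reorder_invariance(self):
        coords = [(0, 5 + i, 5 + j) for i in range(4) for j in range(4)] \
            + [(1, 8, 8), (1, 8, 9)]
        defect, lung = self._mask_with(coords, shape=(2, 30, 30))
        base = m.defect_distribution_index(defect, lung)
        shifted = np.roll(defect, (3, 4), axis=(1, 2))
        assert m.defect_distribution_index(shifted, lung) == \
            pytest.approx(base)
        reordered = defect[::-1].copy()
        assert m.defect_distribution_index(reordered, lung) == \
            pytest.approx(base)

    def test_invalid_radius_rejected(self):
        defect, lung = self._mask_with([(0, 1, 1)])
        with pytest.raises(ConfigurationError):
            m.defect_distribution_index(defect, lung, radius=0)


class TestComputeDefectMetrics:
    def test_invariants_on_pipeline_output(self, analyzed_defect):
        metrics, _, _, _, _ = analyzed_defect
        assert 0 <= metrics.vdp <= 100 and 0 <= metrics.qdp <= 100
        assert metrics.vqd_match <= min(metrics.vdp, metrics.qdp)
        assert sum(metrics.vdp_side.values()) == pytest.approx(metrics.vdp)
        assert sum(metrics.qdp_side.values()) == pytest.approx(metrics.qdp)
        assert metrics.counts["v_defect"] > 0
        assert metrics.ddi_v > 0

    def test_ddi_zero_iff_no_defects(self):
        mask = _sided_mask()
        res = m.compute_defect_metrics(np.zeros_like(mask.lung),
                                       np.zeros_like(mask.lung), mask,
                                       hernia_side="left")
        assert res.ddi_v == 0.0 and res.ddi_q == 0.0
        assert res.vdp == 0.0 and res.vqd_match == 0.0
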