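"""Metrics and protocols against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy import ndimage

from iwnet.evaluation import (EvalRecord, asd, corrected_mean_iou,
                              equivalent_radius, interobserver_iou, iou,
                              mean_iou_vs_annotators, stratified_report,
                              texture_class)


def asd_oracle(a, b, spacing):
    """Exhaustive double loop over all surface-voxel pairs."""
    struct = ndimage.generate_binary_structure(3, 1)

    def surface(m):
        return np.argwhere(m & ~ndimage.binary_erosion(m, structure=struct,
                                                       border_value=0))

    sp = np.asarray(spacing, dtype=float)
    sa, sb = surface(a) * sp, surface(b) * sp
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(q - p) for p in sa) for q in sb]
    return 0.5 * (np.mean(d_ab) + np.mean(d_ba))


def mask_from_indices(indices, shape=(6, 6, 6)):
    m = np.zeros(shape, dtype=bool)
    m.reshape(-1)[list(indices)] = True
    return m


class TestIoU:
    def test_identical_and_disjoint(self):
        a = mask_from_indices(range(5))
        assert iou(a, a) == 1.0
        assert iou(a, mask_from_indices(range(10, 15))) == 0.0

    def test_counted_overlap(self):
        a = mask_from_indices([0, 1])
        b = mask_from_indices([1, 2, 3])
        assert iou(a, b) == pytest.approx(1.0 / 4.0)

    def test_soft_inputs_are_binarized_at_half(self):
        a = mask_from_indices([0, 1])
        soft = np.zeros((6, 6, 6))
        soft.reshape(-1)[[0, 1]] = 0.51
        soft.reshape(-1)[[2]] = 0.49
        assert iou(a, soft) == 1.0

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert iou(z, z) == 1.0

    def test_symmetry(self, rng):
        a = rng.random((5, 5, 5)) > 0.6
        b = rng.random((5, 5, 5)) > 0.6
        assert iou(a, b) == iou(b, a)


class TestASD:
    def test_identical_masks_have_zero_distance(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:6, 2:6, 2:6] = True
        assert asd(m, m) == 0.0

    def test_two_voxels_three_mm_apart(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert asd(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert asd(a, b, (0.5, 1.0, 1.0)) == pytest.approx(1.5)

    def test_matches_exhaustive_oracle_on_random_masks(self, rng):
        for _ in range(20):
            a = ndimage.binary_dilation(rng.random((7, 7, 7)) > 0.9)
            b = ndimage.binary_dilation(rng.random((7, 7, 7)) > 0.9)
            if not a.any() or not b.any():
                continue
            spacing = rng.uniform(0.5, 2.0, 3)
            assert asd(a, b, spacing) == pytest.approx(
                asd_oracle(a, b, spacing))

    def test_symmetry(self, rng):
        a = ndimage.binary_dilation(rng.random((7, 7, 7)) > 0.9)
        b = ndimage.binary_dilation(rng.random((7, 7, 7)) > 0.9)
        assert asd(a, b) == pytest.approx(asd(b, a))

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        full = ~m
        with pytest.raises(ValueError, match="empty"):
            asd(m, full)


class TestProtocols:
    def test_mean_iou_is_the_arithmetic_mean(self):
        # two annotations with IoU 0.4 and 0.6 against the prediction
        pred = mask_from_indices(range(10))          # 10 voxels
        s1 = mask_from_indices(list(range(6)) + list(range(10, 15)))
        assert iou(s1, pred) == pytest.approx(0.4)   # 6 shared, union 15
        s2 = mask_from_indices(range(4, 10))
        assert iou(s2, pred) == pytest.approx(0.6)   # 6 shared, union 10
        got = mean_iou_vs_annotators([s1, s2], pred)
        assert got == pytest.approx((0.4 + 0.6) / 2)

    def test_single_annotator_reduces_to_plain_iou(self):
        a = mask_from_indices(range(6))
        pred = mask_from_indices(range(3))
        assert mean_iou_vs_annotators([a], pred) == iou(a, pred)

    def test_perfect_prediction_scores_one(self):
        a = mask_from_indices(range(6))
        assert mean_iou_vs_annotators([a, a], a) == 1.0

    def test_interobserver_averages_all_ordered_pairs(self, rng):
        masks = [rng.random((6, 6, 6)) > 0.5 for _ in range(4)]
        manual = np.mean([iou(masks[i], masks[j])
                          for i in range(4) for j in range(4) if i != j])
        assert len([(i, j) for i in range(4) for j in range(4) if i != j]) == 12
        assert interobserver_iou(masks) == pytest.approx(manual)

    def test_interobserver_equals_unordered_pair_mean(self, rng):
        masks = [rng.random((6, 6, 6)) > 0.5 for _ in range(3)]
        unordered = np.mean([iou(masks[i], masks[j])
                             for i in range(3) for j in range(i + 1, 3)])
        assert interobserver_iou(masks) == pytest.approx(unordered)

    def test_interobserver_invariant_to_ordering(self, rng):
        masks = [rng.random((6, 6, 6)) > 0.5 for _ in range(4)]
        assert interobserver_iou(masks) == pytest.approx(
            interobserver_iou(masks[::-1]))

    def test_identical_annotations_agree_perfectly(self):
        m = mask_from_indices(range(8))
        assert interobserver_iou([m, m, m]) == 1.0

    def test_interobserver_needs_two_annotations(self):
        with pytest.raises(ValueError, match=">= 2"):
            interobserver_iou([mask_from_indices(range(4))])


class TestCorrectedMeanIoU:
    def test_keep_the_better_mixed_case(self):
        # per-annotator (initial, corrected) IoUs {(0.5, 0.7), (0.6, 0.4)}
        shape = (4, 4, 4)
        initial = mask_from_indices(range(15), shape)  # 15 voxels
        s1 = mask_from_indices(list(range(10)) + list(range(20, 25)), shape)
        assert iou(s1, initial) == pytest.approx(0.5)  # 10 shared, union 20
        c1 = mask_from_indices(list(range(10)) + list(range(20, 24))
                               + list(range(40, 45)), shape)
        assert iou(s1, c1) == pytest.approx(0.7)  # 14 shared, union 20
        s2 = mask_from_indices(list(range(12)) + list(range(25, 30)), shape)
        assert iou(s2, initial) == pytest.approx(0.6)  # 12 shared, union 20
        c2 = mask_from_indices(list(range(10)) + list(range(50, 58)), shape)
        assert iou(s2, c2) == pytest.approx(0.4)  # 10 shared, union 25
        got = corrected_mean_iou([s1, s2], initial, [c1, c2])
        assert got == pytest.approx((0.7 + 0.6) / 2)

    def test_worse_corrections_fall_back_to_the_initial(self, rng):
        masks = [rng.random((6, 6, 6)) > 0.5 for _ in range(3)]
        initial = masks[0].copy()
        empty_ish = [mask_from_indices([200]) for _ in range(3)]
        got = corrected_mean_iou(masks, initial, empty_ish)
        assert got == pytest.approx(mean_iou_vs_annotators(masks, initial))

    def test_perfect_corrections_score_one(self, rng):
        masks = [rng.random((6, 6, 6)) > 0.5 for _ in range(3)]
        assert corrected_mean_iou(masks, np.zeros((6, 6, 6), bool), masks) == 1.0

    def test_dominates_the_initial_mean(self, rng):
        masks = [rng.random((6, 6, 6)) > 0.5 for _ in range(4)]
        initial = rng.random((6, 6, 6)) > 0.5
        corrected = [rng.random((6, 6, 6)) > 0.5 for _ in range(4)]
        assert corrected_mean_iou(masks, initial, corrected) >= \
            mean_iou_vs_annotators(masks, initial)

    def test_count_mismatch_rejected(self):
        m = mask_from_indices(range(4))
        with pytest.raises(ValueError, match="one corrected"):
            corrected_mean_iou([m, m], m, [m])


class TestEquivalentRadius:
    def test_inverse_sphere_formula(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        s = (4.0 * np.pi / 3.0) ** (1.0 / 3.0)
        assert equivalent_radius([m], (s, s, s)) == pytest.approx(1.0)

    def test_mean_of_two_annotators(self):
        shape = (12, 12, 12)
        m1 = mask_from_indices(range(1), shape)
        m2 = mask_from_indices(range(8), shape)
        s = (32.0 * np.pi / 3.0) ** (1.0 / 3.0)  # radius(m1) = 2, radius(m2) = 4
        assert equivalent_radius([m1, m2], (s, s, s)) == pytest.approx(3.0)

    def test_discrete_ball_radius(self):
        xx, yy, zz = np.mgrid[:24, :24, :24]
        ball = (xx - 12) ** 2 + (yy - 12) ** 2 + (zz - 12) ** 2 <= 100
        assert equivalent_radius([ball], (1.0, 1.0, 1.0)) == pytest.approx(
            10.0, abs=0.2)


class TestTextureClass:
    @pytest.mark.parametrize("ratings,expected", [
        ((1, 2), "non-solid"),
        ((5, 5, 5), "solid"),
        ((5, 5, 4), "sub-solid"),
        ((2,), "non-solid"),
        ((3, 3), "sub-solid"),
    ])
    def test_classification_rule(self, ratings, expected):
        assert texture_class(ratings) == expected

    def test_empty_ratings_rejected(self):
        with pytest.raises(ValueError):
            texture_class([])


class TestStratifiedReport:
    def _records(self):
        return [
            EvalRecord("a", 0.5, 0.6, 0.7, 1.0, 0.8, 3.5, "solid"),
            EvalRecord("b", 0.4, 0.5, 0.6, 1.2, 1.0, 3.6, "solid"),
            EvalRecord("c", 0.3, 0.3, 0.5, 2.0, 2.0, 7.5, "non-solid"),
        ]

    def test_manual_means(self):
        table = stratified_report(self._records())
        solid = table[(table.stratum == "texture") & (table.level == "solid")]
        assert solid.iloc[0]["initial_iou_mean"] == pytest.approx(0.45)
        assert solid.iloc[0]["corrected_iou_mean"] == pytest.approx(0.55)
        assert solid.iloc[0]["improved_fraction"] == pytest.approx(1.0)
        overall = table[table.stratum == "all"].iloc[0]
        assert overall["n"] == 3
        assert overall["initial_iou_mean"] == pytest.approx(0.4)
        assert overall["improved_fraction"] == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_single_bin_equals_global_means(self):
        records = [r for r in self._records() if r.texture == "solid"]
        table = stratified_report(records, radius_bins=[3.0, 4.0])
        radius_row = table[table.stratum == "radius"].iloc[0]
        all_row = table[table.stratum == "all"].iloc[0]
        assert radius_row["initial_iou_mean"] == all_row["initial_iou_mean"]

    def test_empty_bins_are_absent_not_zero(self):
        table = stratified_report(self._records())
        levels = table[table.stratum == "radius"]["level"].tolist()
        assert not any("(9" in lv for lv in levels)  # no records near 9-10 mm

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            stratified_report([])
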