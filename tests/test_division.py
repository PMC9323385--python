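"""Proportion-based block-to-tooth division, calibration, and propagation."""

import warnings

import numpy as np
import pytest

from toothbox.division import (
    LambdaPair,
    LambdaTable,
    ProportionDivider,
    ToothProportion,
    calibrate_lambdas,
    default_lambda_table,
    divide_block,
    propagate_boxes,
    proportional_point,
    tooth_box_from_block,
)
from toothbox.geometry import (
    BlockId,
    BlockName,
    Box,
    ClassLabel,
    FdiTooth,
    Jaw,
    LayerLabel,
    block_teeth,
)
from toothbox.layers import LayerLabeling

T45 = FdiTooth.from_code(45)


def ratio_point_by_bisection(x1, x2, lam, tol=1e-12):
    """Independent oracle: solve lambda = (x - x1) / (x2 - x) for x."""
    lo, hi = x1, x2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if x2 - mid == 0:
            break
        if (mid - x1) / (x2 - mid) < lam:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestProportionalPoint:
    def test_unit_lambda_is_midpoint(self):
        assert proportional_point(Box(0, 0, 1, 1), LambdaPair(1.0, 1.0)) == (0.5, 0.5)

    def test_published_lambda_values_on_unit_box(self):
        x, y = proportional_point(Box(0, 0, 1, 1), LambdaPair(1 / 6, 2 / 9))
        assert x == pytest.approx(1 / 7)
        assert y == pytest.approx(2 / 11)

    def test_small_lambda_approaches_near_corner(self):
        x, y = proportional_point(Box(0, 0, 1, 1), LambdaPair(1e-9, 1e-9))
        assert x == pytest.approx(0.0, abs=1e-8)
        assert y == pytest.approx(0.0, abs=1e-8)

    def test_matches_ratio_definition_solved_by_bisection(self):
        box = Box(3.0, -2.0, 17.0, 9.0)
        grid = [0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
        for lx in grid:
            for ly in grid:
                x, y = proportional_point(box, LambdaPair(lx, ly))
                assert abs(x - ratio_point_by_bisection(box.L, box.R, lx)) < 1e-9
                assert abs(y - ratio_point_by_bisection(box.T, box.B, ly)) < 1e-9

    def test_lambda_pair_requires_positive_finite(self):
        for bad in [(-1, 1), (0, 1), (1, float("inf"))]:
            with pytest.raises(ValueError):
                LambdaPair(*bad)


class TestTooth45Mapping:
    def test_unit_block_reproduces_published_corners(self):
        table = default_lambda_table()
        box = tooth_box_from_block(Box(0, 0, 1, 1), table[T45])
        assert box.as_tuple() == pytest.approx((0.17, 0.28, 0.83, 0.72))

    def test_affine_form_on_shifted_block(self):
        table = default_lambda_table()
        box = tooth_box_from_block(Box(100, 200, 200, 300), table[T45])
        assert box.as_tuple() == pytest.approx((117.0, 228.0, 183.0, 272.0))

    def test_degenerate_block_collapses_with_warning(self):
        table = default_lambda_table()
        with pytest.warns(UserWarning, match="degenerate"):
            box = tooth_box_from_block(Box(50, 10, 50, 90), table[T45])
        assert box.L == box.R

    def test_affine_entry_converts_losslessly_to_lambda_form(self):
        prop = default_lambda_table()[T45]
        block = Box(7.0, 3.0, 120.0, 61.0)
        a = tooth_box_from_block(block, prop)
        b = tooth_box_from_block(block, prop.to_lambda_form())
        assert a.as_tuple() == pytest.approx(b.as_tuple(), abs=1e-9)


class TestDivideBlock:
    def test_full_upper_incisor_block_gives_four_boxes(self):
        table = default_lambda_table()
        block = BlockId(Jaw.UPPER, BlockName.INCISORS)
        out = divide_block(Box(50, 40, 200, 90), block, table)
        assert [t.code for t, _ in out] == [12, 11, 21, 22]

    def test_missing_tooth_skipped_without_shifting_neighbors(self):
        table = default_lambda_table()
        block = BlockId(Jaw.UPPER, BlockName.INCISORS)
        box = Box(50, 40, 200, 90)
        full = dict(divide_block(box, block, table))
        partial = dict(
            divide_block(box, block, table, missing={FdiTooth.from_code(12)})
        )
        assert set(t.code for t in partial) == {11, 21, 22}
        for tooth, b in partial.items():
            assert b.as_tuple() == full[tooth].as_tuple()

    def test_lower_right_canine_premolar_labels(self):
        table = default_lambda_table()
        block = BlockId(Jaw.LOWER, BlockName.RIGHT_CANINE_PREMOLAR)
        out = divide_block(Box(10, 10, 80, 60), block, table)
        assert sorted(t.code for t, _ in out) == [43, 44, 45]

    def test_table_gap_names_the_tooth(self):
        table = default_lambda_table()
        del table.entries[FdiTooth.from_code(44)]
        block = BlockId(Jaw.LOWER, BlockName.RIGHT_CANINE_PREMOLAR)
        with pytest.raises(KeyError, match="44"):
            divide_block(Box(10, 10, 80, 60), block, table)

    def test_pre_margin_boxes_contained_in_block(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            l, t = rng.uniform(0, 50, 2)
            w, h = rng.uniform(5, 150, 2)
            block_box = Box(l, t, l + w, t + h)
            lams = rng.uniform(0.05, 10.0, 4)
            prop = ToothProportion(
                T45, LambdaPair(lams[0], lams[1]), LambdaPair(lams[2], lams[3]),
                enlarge=0.0,
            )
            box = tooth_box_from_block(block_box, prop)
            assert block_box.contains_box(box, tol=1e-9)


class TestCalibration:
    @staticmethod
    def _make_truth_from_table(table, teeth, rng, n_blocks=6):
        """Block boxes plus tooth boxes generated by a known table."""
        samples = []
        for _ in range(n_blocks):
            l, t = rng.uniform(0, 60, 2)
            w, h = rng.uniform(60, 160, 2)
            block_box = Box(l, t, l + w, t + h)
            truth = {
                tooth: tooth_box_from_block(
                    block_box,
                    ToothProportion(
                        tooth,
                        table[tooth].to_lambda_form().left_top,
                        table[tooth].to_lambda_form().right_bottom,
                        enlarge=0.0,
                    ),
                )
                for tooth in teeth
            }
            samples.append((block_box, truth))
        return samples

    def test_recovers_table_from_20_percent_perturbed_init(self):
        rng = np.random.default_rng(12)
        teeth = block_teeth(BlockId(Jaw.LOWER, BlockName.RIGHT_CANINE_PREMOLAR))
        true_table = default_lambda_table()
        samples = self._make_truth_from_table(true_table, teeth, rng)
        perturbed = LambdaTable(dict(true_table.entries))
        for tooth in teeth:
            p = true_table[tooth].to_lambda_form()
            perturbed.entries[tooth] = ToothProportion(
                tooth,
                LambdaPair(p.left_top.lx * 1.2, p.left_top.ly * 1.2),
                LambdaPair(p.right_bottom.lx * 1.2, p.right_bottom.ly * 1.2),
                enlarge=p.enlarge,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, achieved = calibrate_lambdas(samples, perturbed, target_mean_iou=0.99)
        assert achieved >= 0.95

    def test_optimal_init_is_a_fixed_point(self):
        rng = np.random.default_rng(13)
        teeth = block_teeth(BlockId(Jaw.UPPER, BlockName.INCISORS))
        table = default_lambda_table()
        samples = self._make_truth_from_table(table, teeth, rng)
        out, achieved = calibrate_lambdas(samples, table, target_mean_iou=0.85)
        assert achieved > 0.999
        for tooth in teeth:
            assert out[tooth] is table[tooth]

    def test_fourteen_phantom_slices_reach_085(self, phantom):
        from conftest import calibration_samples

        _, _, truth = phantom
        crown_slices = [7, 8, 9, 10, 11, 12, 13, 23, 24, 25, 26, 27, 28, 29]
        assert len(crown_slices) == 14
        samples = calibration_samples(truth, crown_slices)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, achieved = calibrate_lambdas(
                samples, default_lambda_table(), target_mean_iou=0.85
            )
        assert achieved >= 0.85

    def test_divider_estimator_fit_predict(self, phantom):
        from conftest import calibration_samples

        _, _, truth = phantom
        est = ProportionDivider(target_mean_iou=0.9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(calibration_samples(truth, (10,)))
        assert est.mean_iou_ >= 0.9
        block = BlockId(Jaw.LOWER, BlockName.INCISORS)
        (out,) = est.predict([(block, truth.block_boxes[10][block])])
        assert len(out) == 4


class TestPropagation:
    @staticmethod
    def _toy_labeling():
        # slices: 0 no-tooth | 1..4 lower crown | 5..6 overlap | 7..8 upper
        # crown | 9 no-tooth
        layers = (
            [LayerLabel.LOWER_NO_TOOTH]
            + [LayerLabel.LOWER_CROWN] * 4
            + [LayerLabel.OVERLAP] * 2
            + [LayerLabel.UPPER_CROWN] * 2
            + [LayerLabel.UPPER_NO_TOOTH]
        )
        classes = [ClassLabel.NO_TOOTH] * 10  # not used by propagation
        return LayerLabeling(classes, layers, [1, 5, 7, 9])

    def test_nearest_key_of_own_jaw_with_ties_to_smaller_index(self):
        lab = self._toy_labeling()
        lower_a = [(FdiTooth.from_code(41), Box(0, 0, 1, 1))]
        lower_b = [(FdiTooth.from_code(41), Box(10, 10, 11, 11))]
        upper = [(FdiTooth.from_code(11), Box(5, 5, 6, 6))]
        out = propagate_boxes({1: lower_a, 3: lower_b, 7: upper}, lab)
        assert out[0] == lower_a  # adjacent no-tooth region
        assert out[2] == lower_a  # equidistant: tie breaks to the smaller key
        assert out[4] == lower_b
        # slice 9 (upper no-tooth) takes the only upper key
        assert out[9] == upper

    def test_overlap_slices_receive_union_of_both_jaws(self):
        lab = self._toy_labeling()
        lower = [(FdiTooth(4, 1), Box(0, 0, 1, 1)) for _ in range(3)]
        upper = [(FdiTooth.from_code(11), Box(5, 5, 6, 6)) for _ in range(2)]
        out = propagate_boxes({4: lower, 7: upper}, lab)
        assert len(out[5]) == len(lower) + len(upper)
        assert len(out[6]) == len(lower) + len(upper)

    def test_key_slice_keeps_its_own_boxes(self):
        lab = self._toy_labeling()
        lower = [(FdiTooth.from_code(41), Box(0, 0, 1, 1))]
        upper = [(FdiTooth.from_code(11), Box(5, 5, 6, 6))]
        out = propagate_boxes({2: lower, 8: upper}, lab)
        assert out[2] == lower
        assert out[8] == upper

    def test_empty_key_set_rejected(self):
        with pytest.raises(ValueError):
            propagate_boxes({}, self._toy_labeling())

    def test_key_outside_crown_region_rejected(self):
        lab = self._toy_labeling()
        with pytest.raises(ValueError, match="crown"):
            propagate_boxes({5: [(FdiTooth.from_code(41), Box(0, 0, 1, 1))]}, lab)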