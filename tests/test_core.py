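"""Unit tests for the weighted-bilinear operators and the combination rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsenhance import (
    EnhanceParams,
    classify_regions,
    combine_pm,
    cwb_weights,
    enhance_hwb,
    enhance_pm,
    hwb_stage,
    split_value_map,
    step_index,
    twb_stage,
    twb_weights,
)
from capsenhance.exceptions import ConfigError, ParameterError, SizeError

from conftest import random_rgb


def uniform_image(value, h=4, w=4):
    return np.full((h, w, 3), value, dtype=float)


class TestValueMap:
    @pytest.mark.parametrize("pixel, expected", [
        ((0.2, 0.5, 0.3), 0.5),
        ((0.0, 0.0, 0.0), 0.0),
        ((0.7, 0.7, 0.7), 0.7),
    ])
    def test_v_is_channel_max(self, pixel, expected):
        img = np.tile(np.array(pixel), (2, 2, 1))
        assert split_value_map(img) == pytest.approx(np.full((2, 2), expected))

    def test_input_not_mutated(self, rng):
        img = random_rgb(rng, 5, 6)
        before = img.copy()
        split_value_map(img)
        np.testing.assert_array_equal(img, before)

    def test_rejects_non_rgb(self):
        with pytest.raises(SizeError):
            split_value_map(np.zeros((4, 4)))
        with pytest.raises(SizeError):
            split_value_map(np.zeros((4, 4, 4)))


class TestRegionMasks:
    def test_threshold_is_strict_on_dark_side(self, default_params):
        vmap = np.array([[0.39, 0.40], [0.41, 0.0]])
        masks = classify_regions(vmap, default_params)
        np.testing.assert_array_equal(
            masks.darker, [[True, False], [False, True]])

    def test_masks_partition_image(self, rng, default_params):
        vmap = rng.uniform(0, 1, (16, 16))
        masks = classify_regions(vmap, default_params)
        assert not (masks.darker & masks.brighter).any()
        assert (masks.darker | masks.brighter).all()

    def test_all_bright_when_v_is_one(self, default_params):
        masks = classify_regions(np.ones((4, 4)), default_params)
        assert masks.darker.sum() == 0
        assert masks.brighter.all()


class TestCwbWeights:
    @pytest.mark.parametrize("dr, dc, expected", [
        (0.0, 0.0, (1.0, 0.0, 0.0, 0.0)),
        (0.5, 0.5, (0.25, 0.25, 0.25, 0.25)),
        (0.25, 0.5, (0.375, 0.125, 0.375, 0.125)),
    ])
    def test_bilinear_products(self, dr, dc, expected):
        assert cwb_weights(dr, dc) == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_weights_sum_to_one(self, dr, dc):
        assert abs(sum(cwb_weights(dr, dc)) - 1.0) < 1e-12

    @pytest.mark.parametrize("dr, dc", [(-0.1, 0.5), (0.5, 1.2)])
    def test_rejects_out_of_range_offsets(self, dr, dc):
        with pytest.raises(ParameterError):
            cwb_weights(dr, dc)


class TestHwbStage:
    def test_uniform_image_doubles(self):
        out = hwb_stage(uniform_image(0.3))
        assert out == pytest.approx(np.full((4, 4, 3), 0.6))

    def test_group_sum_halved(self):
        img = np.zeros((2, 2, 3))
        img[0, 0] = 0.1
        img[1, 0] = 0.2
        img[0, 1] = 0.3
        img[1, 1] = 0.4
        out = hwb_stage(img)
        assert out[0, 0] == pytest.approx([0.5, 0.5, 0.5])

    def test_all_zero_stays_zero(self):
        assert hwb_stage(np.zeros((3, 3, 3))).sum() == 0.0

    def test_output_may_exceed_one(self):
        out = hwb_stage(uniform_image(0.9))
        assert out.max() == pytest.approx(1.8)

    def test_rejects_single_pixel(self):
        with pytest.raises(SizeError):
            hwb_stage(np.zeros((1, 1, 3)))


class TestStepIndex:
    @pytest.mark.parametrize("eta, expected", [
        (0.4, 0),   # threshold pixel lands on the first step
        (1.0, 2),   # V maximum lands on the last step
        (0.61, 1),  # floor(0.21 / 0.2)
    ])
    def test_default_buckets(self, eta, expected, default_params):
        assert step_index(eta, default_params) == expected

    def test_default_step_count_is_three(self, default_params):
        assert default_params.step_count == 3

    def test_dark_pixel_is_contract_violation(self, default_params):
        with pytest.raises(ParameterError):
            step_index(0.39, default_params)


class TestTwbWeights:
    def test_first_step_matches_half_unit_gain(self):
        # (0.25 + 0.5) / 1.5 = 0.5 per weight: the bright branch starts at
        # the same effective gain (sum 2) as the dark branch.
        sw = twb_weights(0, EnhanceParams())
        assert sw.w1 == pytest.approx(0.5, abs=1e-15)
        assert sw.weight_sum == pytest.approx(2.0, abs=1e-15)

    def test_last_step_attenuated(self):
        sw = twb_weights(2, EnhanceParams())
        assert sw.w1 == pytest.approx(0.75 / 1.55, abs=1e-12)
        assert sw.weight_sum == pytest.approx(3.0 / 1.55, abs=1e-12)

    def test_weight_sum_strictly_decreasing(self, rng):
        for _ in range(100):
            params = EnhanceParams(beta=rng.uniform(1.45, 1.50),
                                   omega=rng.uniform(1e-6, 0.025))
            sums = [twb_weights(j, params).weight_sum
                    for j in range(params.step_count)]
            denominators = [twb_weights(j, params).denominator
                            for j in range(params.step_count)]
            assert all(a > b for a, b in zip(sums, sums[1:]))
            assert all(a < b for a, b in
                       zip(denominators, denominators[1:]))
            for j, s in enumerate(sums):
                assert s == pytest.approx(
                    3.0 / (params.beta + params.omega * j), abs=1e-12)

    def test_rejects_out_of_range_step(self, default_params):
        with pytest.raises(ParameterError):
            twb_weights(3, default_params)
        with pytest.raises(ParameterError):
            twb_weights(-1, default_params)


class TestTwbStage:
    def test_uniform_bright_image(self, default_params):
        img = uniform_image(0.9)
        out = twb_stage(img, split_value_map(img), default_params)
        assert out == pytest.approx(
            np.full((4, 4, 3), 0.9 * 3.0 / 1.55), abs=1e-12)

    def test_matches_hwb_at_threshold_step(self, default_params):
        img = uniform_image(0.4)
        out = twb_stage(img, split_value_map(img), default_params)
        np.testing.assert_allclose(out, hwb_stage(img), atol=1e-15)

    def test_all_zero_stays_zero(self, default_params):
        img = np.zeros((3, 3, 3))
        assert twb_stage(img, np.zeros((3, 3)), default_params).sum() == 0.0

    def test_rejects_mismatched_value_map(self, default_params):
        with pytest.raises(SizeError):
            twb_stage(uniform_image(0.5), np.zeros((5, 5)), default_params)

    def test_bounded_by_hwb_at_beta_150(self, rng):
        params = EnhanceParams(beta=1.5)
        for _ in range(10):
            img = random_rgb(rng, 12, 12)
            twb = twb_stage(img, split_value_map(img), params)
            assert (twb <= hwb_stage(img) + 1e-12).all()


class TestCombineAndPipeline:
    def test_dark_uniform_average(self, default_params):
        out = enhance_pm(uniform_image(0.2), default_params)
        assert out == pytest.approx(np.full((4, 4, 3), 0.3), abs=1e-12)

    def test_bright_uniform_average_clips(self, default_params):
        # branch = 0.9 * 3/1.55 ~ 1.742; (1.742 + 0.9)/2 ~ 1.32 -> clip
        out = enhance_pm(uniform_image(0.9), default_params)
        assert out == pytest.approx(np.ones((4, 4, 3)))

    def test_additive_mode(self):
        params = EnhanceParams(combine_mode="additive")
        out = enhance_pm(uniform_image(0.2), params)
        assert out == pytest.approx(np.full((4, 4, 3), 0.5), abs=1e-12)

    def test_zero_image_fixed_point(self):
        for mode in ("average", "additive"):
            out = enhance_pm(np.zeros((4, 4, 3)),
                             EnhanceParams(combine_mode=mode))
            assert out.sum() == 0.0

    def test_pipeline_equals_manual_composition(self, rng, default_params):
        img = random_rgb(rng, 9, 7)
        vmap = split_value_map(img)
        masks = classify_regions(vmap, default_params)
        expected = combine_pm(img, hwb_stage(img),
                              twb_stage(img, vmap, default_params),
                              masks, default_params)
        np.testing.assert_array_equal(enhance_pm(img, default_params),
                                      expected)

    @pytest.mark.parametrize("mode", ["average", "additive"])
    def test_never_darkens_on_average(self, rng, mode):
        params = EnhanceParams(combine_mode=mode)
        for _ in range(10):
            img = random_rgb(rng, 32, 32)
            out = enhance_pm(img, params)
            assert out.mean() >= img.mean()
            assert out.shape == img.shape
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_combine_mode_rejected(self):
        with pytest.raises(ConfigError):
            EnhanceParams(combine_mode="geometric")

    def test_hwb_everywhere_baseline_ignores_threshold(self, rng):
        img = random_rgb(rng, 8, 8)
        out = enhance_hwb(img)
        manual = np.clip((hwb_stage(img) + img) / 2.0, 0.0, 1.0)
        np.testing.assert_array_equal(out, manual)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"threshold": 0.0}, {"threshold": 1.0},
        {"beta": 1.44}, {"beta": 1.51},
        {"omega": 0.0}, {"omega": 0.026},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            EnhanceParams(**kwargs)

    def test_step_count_scales_with_threshold(self):
        assert EnhanceParams(threshold=0.5).step_count == 2
        assert EnhanceParams(threshold=0.2).step_count == 5
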