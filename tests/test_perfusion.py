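"""Colorbar LUT construction, heatmap inversion, and perfusion statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from keloidscope.errors import (
    AmbiguousLUTError,
    EmptyRegionError,
    InvalidInputError,
    InvalidLUTError,
)
from keloidscope.perfusion import (
    build_lut,
    crop_and_mask,
    default_lut,
    lut_from_colorbar_image,
    mean_perfusion,
    perfusion_error,
    rgb_to_pu,
)
from keloidscope.synthetic import render_heatmap


class TestBuildLut:
    def test_two_anchor_blue_to_red(self):
        lut = build_lut([((0, 0, 255), 0.0), ((255, 0, 0), 200.0)])
        assert lut.n_anchors == 2
        assert lut.pu_min == 0.0 and lut.pu_max == 200.0

    @pytest.mark.parametrize(
        "anchors",
        [
            [((0, 0, 255), 0.0)],  # single anchor
            [((0, 0, 255), 0.0), ((0, 255, 0), 100.0), ((255, 0, 0), 50.0)],  # non-monotone
            [((0, 0, 255), 0.0), ((255, 0, 0), 0.0)],  # non-increasing
        ],
    )
    def test_invalid_tables_rejected(self, anchors):
        with pytest.raises(InvalidLUTError):
            build_lut(anchors)

    def test_duplicate_color_conflicting_pu_rejected(self):
        with pytest.raises(AmbiguousLUTError):
            build_lut([((0, 0, 255), 0.0), ((0, 0, 255), 100.0), ((255, 0, 0), 200.0)])

    def test_densify_interpolates_both_rgb_and_pu(self):
        lut = build_lut([((0, 0, 255), 0.0), ((255, 0, 0), 200.0)], densify=5)
        assert lut.n_anchors == 5
        np.testing.assert_allclose(lut.pu, [0, 50, 100, 150, 200])
        assert tuple(lut.colors[2]) == (128, 0, 128)

    def test_default_ramp_has_unique_colors(self):
        lut = default_lut()
        assert lut.n_anchors == 256
        assert len(np.unique(lut.colors, axis=0)) == 256


class TestLutFromColorbarImage:
    def test_roundtrip_from_rendered_strip(self, lut):
        # render the LUT itself as a 256-px horizontal strip, 5 rows tall
        strip = np.repeat(lut.colors[None, :, :], 5, axis=0)
        recovered = lut_from_colorbar_image(strip, lut.pu_min, lut.pu_max, axis="column")
        np.testing.assert_array_equal(recovered.colors, lut.colors)
        np.testing.assert_allclose(recovered.pu, lut.pu)

    def test_two_pixel_strip_gives_endpoint_anchors(self):
        strip = np.array([[[0, 0, 255]], [[255, 0, 0]]], dtype=np.uint8)  # 2 rows
        recovered = lut_from_colorbar_image(strip, 10.0, 90.0, axis="row")
        assert recovered.n_anchors == 2
        np.testing.assert_allclose(recovered.pu, [10.0, 90.0])

    def test_degenerate_pu_range_rejected(self):
        strip = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(InvalidInputError):
            lut_from_colorbar_image(strip, 100.0, 100.0)


class TestRgbToPu:
    def test_exact_anchor_colors_recover_exact_pu(self, lut):
        img = np.tile(lut.colors[37], (4, 6, 1)).astype(np.uint8)
        field, dist = rgb_to_pu(img, lut)
        np.testing.assert_allclose(field, lut.pu[37])
        assert dist.max() == 0.0

    def test_tie_breaks_to_lower_pu(self):
        lut = build_lut([((0, 0, 0), 0.0), ((0, 0, 100), 50.0), ((0, 0, 200), 100.0)])
        img = np.full((1, 1, 3), 0, dtype=np.uint8)
        img[0, 0] = (0, 0, 150)  # equidistant from anchors 1 and 2
        field, _ = rgb_to_pu(img, lut)
        assert field[0, 0] == 50.0

    def test_off_palette_pixels_flagged_not_fatal(self, lut):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)  # white: not on the ramp
        field, dist = rgb_to_pu(img, lut)
        assert np.isfinite(field).all()
        assert dist.min() > 50  # far from every anchor

    def test_roundtrip_within_half_quantization_step(self, lut, rng):
        field = rng.uniform(lut.pu_min, lut.pu_max, size=(64, 64))
        recovered, dist = rgb_to_pu(render_heatmap(field, lut), lut)
        assert np.abs(recovered - field).max() <= lut.quantization_step / 2 + 1e-9
        assert dist.max() == 0.0


class TestCropAndMask:
    def test_full_mask_is_identity_with_full_frame_box(self, rng):
        field = rng.uniform(0, 100, size=(8, 10))
        masked, bbox = crop_and_mask(field, np.ones((8, 10), bool))
        np.testing.assert_array_equal(masked, field)
        assert bbox == (0, 0, 8, 10)

    def test_single_pixel_mask_bbox_convention(self):
        mask = np.zeros((9, 9), bool)
        mask[3, 5] = True
        _, bbox = crop_and_mask(np.ones((9, 9)), mask)
        assert bbox == (3, 5, 4, 6)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            crop_and_mask(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_outside_mask_zeroed(self, rng):
        field = rng.uniform(1, 2, size=(6, 6))
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        masked, _ = crop_and_mask(field, mask)
        assert (masked[~mask] == 0).all()
        np.testing.assert_array_equal(masked[mask], field[mask])


class TestMeanPerfusion:
    def test_constant_field(self):
        mask = np.zeros((5, 5), bool)
        mask[1:3, 1:4] = True
        stats = mean_perfusion(np.full((5, 5), 130.0), mask)
        assert stats.mean_pu == pytest.approx(130.0)
        assert stats.n_pixels == 6

    def test_two_level_field_averages(self):
        field = np.zeros((4, 4))
        field[:2] = 100.0
        field[2:] = 200.0
        stats = mean_perfusion(field, np.ones((4, 4), bool))
        assert stats.mean_pu == pytest.approx(150.0)

    def test_matches_bruteforce_sum_over_mask(self, rng):
        field = rng.uniform(0, 300, size=(17, 13))
        mask = rng.random((17, 13)) > 0.6
        if not mask.any():
            mask[0, 0] = True
        stats = mean_perfusion(field, mask)
        brute = sum(field[r, c] for r in range(17) for c in range(13) if mask[r, c]) / mask.sum()
        assert stats.mean_pu == pytest.approx(brute)

    def test_invariant_to_bounding_box_crop(self, rng):
        field = rng.uniform(0, 300, size=(20, 20))
        mask = np.zeros((20, 20), bool)
        mask[5:12, 7:15] = rng.random((7, 8)) > 0.4
        mask[6, 8] = True
        full = mean_perfusion(field, mask)
        r0, c0, r1, c1 = full.bounding_box
        cropped = mean_perfusion(field[r0:r1, c0:c1], mask[r0:r1, c0:c1])
        assert full.mean_pu == pytest.approx(cropped.mean_pu)
        assert full.n_pixels == cropped.n_pixels


class TestPerfusionErrorFormula:
    @pytest.mark.parametrize(
        "a,b,abs_exp,rel_exp",
        [(100.0, 92.0, 8.0, 8.0), (50.0, 100.0, 50.0, 50.0), (77.3, 77.3, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_worked_examples(self, a, b, abs_exp, rel_exp):
        err = perfusion_error(a, b)
        assert err.abs_error == pytest.approx(abs_exp)
        assert err.rel_error == pytest.approx(rel_exp)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidInputError):
            perfusion_error(-1.0, 5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0, 1e4, allow_nan=False),
        b=st.floats(0, 1e4, allow_nan=False),
        k=st.floats(0.01, 100.0),
    )
    def test_symmetry_and_scale_invariance(self, a, b, k):
        e1, e2 = perfusion_error(a, b), perfusion_error(b, a)
        assert e1.abs_error == e2.abs_error and e1.rel_error == e2.rel_error
        scaled = perfusion_error(k * a, k * b)
        assert scaled.rel_error == pytest.approx(e1.rel_error, abs=1e-9)
        assert 0 <= e1.rel_error <= 100
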