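"""Cascade evaluator: masking, patch selection, fusion contracts, erasing."""

import numpy as np
import pytest

from keloidscope.errors import EmptyRegionError, EmptySelectionError, InvalidInputError
from keloidscope.evaluator import (
    EvalConfig,
    build_evaluator,
    encode_perfusion,
    fuse_features,
    mask_and_resize,
    predict_stage,
    random_erase,
    select_perfusion_patches,
)
from keloidscope.nn import Tensor
from keloidscope.segmentation import PatchGrid


class TestMaskAndResize:
    def test_full_mask_is_plain_resize(self, rng):
        field = rng.uniform(10, 100, size=(128, 128))
        out = mask_and_resize(field, np.ones((128, 128), bool), 64)
        assert out.shape == (64, 64)
        # area-weighted mean approximately preserved by resampling
        assert abs(out.mean() / field.mean() - 1) < 0.02

    def test_zero_field_propagates(self):
        out = mask_and_resize(np.zeros((64, 64)), np.ones((64, 64), bool), 32)
        assert (out == 0).all()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            mask_and_resize(np.ones((32, 32)), np.zeros((32, 32), bool), 32)


class TestSelectPerfusionPatches:
    def test_all_zero_image_raises(self):
        with pytest.raises(EmptySelectionError):
            select_perfusion_patches(np.zeros((64, 64)), 8)

    def test_every_pixel_positive_selects_all(self):
        sel = select_perfusion_patches(np.ones((64, 64)), 8)
        assert len(sel.indices) == 64

    def test_exact_patch_aligned_mask_selects_exactly_k(self):
        img = np.zeros((64, 64))
        img[8:24, 16:40] = 5.0  # exactly 2×3 patch cells at patch size 8
        sel = select_perfusion_patches(img, 8)
        assert len(sel.indices) == 6
        rows_cols = [divmod(int(i), 8) for i in sel.indices]
        assert rows_cols == [(1, 2), (1, 3), (1, 4), (2, 2), (2, 3), (2, 4)]

    def test_threshold_tau_filters_low_perfusion(self):
        img = np.full((16, 16), 3.0)
        img[:8, :8] = 10.0
        sel = select_perfusion_patches(img, 8, tau=5.0)
        assert list(sel.indices) == [0]

    def test_indices_strictly_increasing_and_in_range(self, rng):
        img = (rng.random((64, 64)) > 0.8) * rng.uniform(1, 5, (64, 64))
        sel = select_perfusion_patches(img, 8)
        assert (np.diff(sel.indices) > 0).all()
        assert sel.indices.min() >= 0 and sel.indices.max() < 64


class TestEncodeFusePredict:
    @pytest.fixture()
    def setup(self, rng):
        cfg = EvalConfig.tiny(seed=0)
        model = build_evaluator(cfg, intensity_dim=16)
        img = np.zeros((64, 64))
        img[16:40, 16:48] = rng.uniform(0.4, 0.9, (24, 32))
        sel = select_perfusion_patches(img, cfg.patch_size)
        toks = rng.normal(size=(len(sel.indices), 16))
        glob = rng.normal(size=16)
        return cfg, model, img, sel, toks, glob

    def test_token_count_is_selection_plus_summary(self, setup):
        cfg, model, img, sel, toks, glob = setup
        out = encode_perfusion(sel, model.perf_encoder)
        assert out.shape == (1, len(sel.indices) + 1, cfg.perf_dim)

    def test_prediction_invariant_to_non_selected_content(self, setup, rng):
        cfg, model, img, sel, toks, glob = setup
        p1 = predict_stage(model, sel, toks, glob)
        # permute non-selected patch contents: selection and prediction fixed
        img2 = img.copy()
        img2[48:, 48:] = 0.0  # already zero; prediction must not depend on it
        sel2 = select_perfusion_patches(img2, cfg.patch_size)
        np.testing.assert_array_equal(sel.indices, sel2.indices)
        p2 = predict_stage(model, sel2, toks, glob)
        np.testing.assert_allclose(p1.probabilities, p2.probabilities)

    def test_sensitive_to_perfusion_scale(self, setup):
        cfg, model, img, sel, toks, glob = setup
        sel_scaled = select_perfusion_patches(img * 2.0, cfg.patch_size)
        p1 = predict_stage(model, sel, toks, glob)
        p2 = predict_stage(model, sel_scaled, toks, glob)
        assert not np.allclose(p1.probabilities, p2.probabilities)

    def test_probabilities_sum_to_one_and_label_consistent(self, setup):
        cfg, model, img, sel, toks, glob = setup
        pred = predict_stage(model, sel, toks, glob)
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.label_index == int(np.argmax(pred.probabilities))

    def test_fused_width_is_sum_of_widths(self, rng):
        a = Tensor(rng.normal(size=(1, 4, 6)))
        b = Tensor(rng.normal(size=(1, 4, 10)))
        assert fuse_features(a, b).shape == (1, 4, 16)

    def test_grid_mismatch_rejected(self, rng):
        a = Tensor(rng.normal(size=(1, 4, 6)))
        b = Tensor(rng.normal(size=(1, 5, 6)))
        with pytest.raises(InvalidInputError):
            fuse_features(a, b)

    def test_zeroed_intensity_ablation_still_runs(self, setup):
        cfg, model, img, sel, toks, glob = setup
        pred = predict_stage(model, sel, np.zeros_like(toks), np.zeros_like(glob))
        assert pred.probabilities.shape == (3,)

    def test_empty_selection_rejected(self, setup):
        cfg, model, img, sel, toks, glob = setup
        from keloidscope.evaluator import SelectedPatches

        empty = SelectedPatches(indices=np.array([], dtype=int),
                                contents=np.zeros((0, 64)), grid=PatchGrid(64, 8))
        with pytest.raises(EmptySelectionError):
            encode_perfusion(empty, model.perf_encoder)


class TestNegativeControl:
    def test_permuted_labels_drop_to_chance(self):
        """With stage labels shuffled there is nothing to learn."""
        from keloidscope.metrics import stratified_kfold
        from keloidscope.evaluator import train_evaluator
        from keloidscope.segmentation import SegConfig, build_seg_model
        from keloidscope.synthetic import SceneSpec, generate_dataset

        records, _ = generate_dataset(
            36, seed=17, base_spec=SceneSpec(image_height=128, image_width=128),
            site_profiles=[("all", 129.9, 1.0)],
        )
        rng = np.random.default_rng(17)
        stages = [records[j].stage for j in rng.permutation(len(records))]
        for rec, s in zip(records, stages):
            rec.stage = s
        folds = stratified_kfold([r.stage for r in records], k=2, seed=17)
        seg_model = build_seg_model(SegConfig.tiny(seed=17))
        cfg = EvalConfig.tiny(seed=17, epochs=15)
        res = train_evaluator(records, cfg, seg_model, folds)
        assert res.accuracy < 0.60  # prior-weighted chance is ~0.36


class TestRandomErase:
    def test_zero_fraction_is_identity(self, rng):
        img = rng.uniform(size=(32, 32))
        np.testing.assert_array_equal(random_erase(img, 0.0, rng), img)

    def test_exact_erase_count(self, rng):
        img = np.ones((64, 64))
        out = random_erase(img, 0.25, rng)
        assert int((out == 0).sum()) == 1024  # round(0.25 × 4096)

    def test_positions_uniform_chi_square(self):
        # pool erased positions over many seeds; coarse 4×4 cell occupancy
        from scipy.stats import chisquare

        counts = np.zeros((4, 4))
        for seed in range(300):
            out = random_erase(np.ones((16, 16)), 0.25, seed)
            erased = out == 0
            counts += erased.reshape(4, 4, 4, 4).sum(axis=(1, 3))
        _, p = chisquare(counts.ravel())
        assert p > 0.01

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            random_erase(np.ones((4, 4)), 1.0, 0)
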