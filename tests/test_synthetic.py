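"""Synthetic LSCI generator: masks, perfusion fields, intensity images, datasets."""

import numpy as np
import pytest
from dataclasses import replace

from keloidscope.errors import EmptyRegionError, InsufficientNError, InvalidSpecError
from keloidscope.perfusion import rgb_to_pu
from keloidscope.segmentation import dice
from keloidscope.synthetic import (
    DEFAULT_STAGE_MIX,
    STAGES,
    SceneSpec,
    expected_dataset_mean_pu,
    generate_dataset,
    largest_remainder_counts,
    load_dataset,
    make_intensity_image,
    make_keloid_mask,
    make_perfusion_field,
    render_heatmap,
    write_dataset,
)
from scipy.ndimage import label as cc_label


class TestKeloidMask:
    def test_seeded_determinism(self, small_spec):
        assert np.array_equal(make_keloid_mask(small_spec), make_keloid_mask(small_spec))

    def test_component_count_and_area_over_seeds(self):
        # 40 seeds: every component's area fraction stays inside the band
        for seed in range(40):
            spec = SceneSpec(image_height=128, image_width=128, seed=seed,
                             area_fraction_range=(0.02, 0.30))
            mask = make_keloid_mask(spec)
            labels, n_cc = cc_label(mask)
            assert n_cc == 1
            frac = mask.mean()
            assert 0.02 <= frac <= 0.30

    def test_multiple_keloids(self):
        spec = SceneSpec(image_height=128, image_width=128, seed=9, n_keloids=2,
                         area_fraction_range=(0.02, 0.10))
        mask = make_keloid_mask(spec)
        _, n_cc = cc_label(mask)
        assert n_cc == 2

    @pytest.mark.parametrize("bad", [
        dict(n_keloids=0),
        dict(area_fraction_range=(0.3, 0.1)),
        dict(area_fraction_range=(0.0, 0.5)),
        dict(stage="exploding"),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            make_keloid_mask(SceneSpec(**bad))


class TestPerfusionField:
    def test_infinite_correlation_length_gives_constant_inside(self, small_spec):
        mask = make_keloid_mask(small_spec)
        spec = replace(small_spec, heterogeneity_scale=np.inf)
        field = make_perfusion_field(mask, spec)
        assert np.allclose(field[mask], spec.target_mean_pu)

    def test_inside_mean_tracks_target_over_seeds(self):
        # standardized noise makes the inside mean exact up to clipping
        devs = []
        for seed in range(25):
            spec = SceneSpec(image_height=128, image_width=128, seed=seed)
            mask = make_keloid_mask(spec)
            field = make_perfusion_field(mask, spec)
            devs.append(field[mask].mean() / spec.target_mean_pu - 1.0)
        assert abs(np.mean(devs)) < 0.10

    def test_progressive_inside_exceeds_outside(self):
        spec = SceneSpec(image_height=128, image_width=128, seed=3, stage="progressive",
                         target_mean_pu=162.0)
        mask = make_keloid_mask(spec)
        field = make_perfusion_field(mask, spec)
        assert field[mask].mean() > field[~mask].mean()

    def test_nonnegative_everywhere(self, small_spec):
        mask = make_keloid_mask(small_spec)
        field = make_perfusion_field(mask, small_spec)
        assert (field >= 0).all()

    def test_empty_mask_raises(self, small_spec):
        with pytest.raises(EmptyRegionError):
            make_perfusion_field(np.zeros((128, 128), bool), small_spec)


class TestRenderHeatmap:
    def test_uniform_field_at_lut_min_renders_first_anchor(self, lut):
        img = render_heatmap(np.full((4, 4), lut.pu_min), lut)
        assert (img == lut.colors[0]).all()

    def test_above_range_clips_to_last_anchor(self, lut):
        img = render_heatmap(np.full((2, 2), lut.pu_max + 500.0), lut)
        assert (img == lut.colors[-1]).all()


class TestIntensityImage:
    def test_seeded_determinism(self, small_spec):
        mask = make_keloid_mask(small_spec)
        a = make_intensity_image(mask, small_spec)
        assert np.array_equal(a, make_intensity_image(mask, small_spec))

    def test_no_distractors_threshold_recovers_mask(self):
        spec = SceneSpec(image_height=128, image_width=128, seed=11,
                         pigmentation_distractors=0)
        mask = make_keloid_mask(spec)
        img = make_intensity_image(mask, spec)
        # keloid is the bright tissue: a fixed global threshold suffices
        assert dice(img > 120, mask) > 0.9

    def test_distractor_pixels_are_mask_negative(self):
        spec = SceneSpec(image_height=128, image_width=128, seed=13,
                         pigmentation_distractors=3)
        mask = make_keloid_mask(spec)
        img = make_intensity_image(mask, spec)
        dark = img < 75  # distractor level sits well below skin
        assert not (dark & mask).sum() > 0.001 * mask.sum()


class TestGenerateDataset:
    def test_table_mix_at_n150_small_replica(self, small_dataset):
        records, manifest = small_dataset
        assert len(records) == len(manifest) == 24
        counts = [sum(r.stage == s for r in records) for s in STAGES]
        assert counts == largest_remainder_counts(24, DEFAULT_STAGE_MIX)

    def test_equal_mix_n3_rounds_to_one_each(self):
        records, _ = generate_dataset(3, stage_mix=(1 / 3, 1 / 3, 1 / 3), seed=1,
                                      base_spec=SceneSpec(image_height=128, image_width=128))
        assert sorted(r.stage for r in records) == sorted(STAGES)

    def test_insufficient_n_rejected(self):
        with pytest.raises(InsufficientNError):
            generate_dataset(2, seed=1)

    def test_shapes_consistent_and_nonnegative(self, small_dataset):
        for rec in small_dataset[0]:
            assert rec.intensity.shape == rec.mask.shape == rec.field.shape
            assert rec.heatmap.shape == rec.mask.shape + (3,)
            assert (rec.field >= 0).all()
            assert rec.mask.dtype == bool

    def test_stage_ordering_of_mean_perfusion(self, small_dataset):
        # the learnable signal: progressive > stable > regressive on average
        records, _ = small_dataset
        means = {s: np.mean([r.meta["mean_pu_inside"] for r in records if r.stage == s])
                 for s in STAGES}
        assert means["progressive"] > means["stable"] > means["regressive"]

    def test_byte_reproducible(self):
        base = SceneSpec(image_height=128, image_width=128)
        a, _ = generate_dataset(4, seed=77, base_spec=base)
        b, _ = generate_dataset(4, seed=77, base_spec=base)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.intensity, rb.intensity)
            assert np.array_equal(ra.heatmap, rb.heatmap)
            assert np.array_equal(ra.field, rb.field)
            assert np.array_equal(ra.mask, rb.mask)

    def test_roundtrip_through_disk(self, tmp_path, small_dataset):
        records, manifest = small_dataset
        write_dataset(records[:3], manifest[:3], tmp_path)
        loaded, rows = load_dataset(tmp_path)
        assert len(loaded) == 3
        assert np.array_equal(loaded[0].intensity, records[0].intensity)
        assert np.array_equal(loaded[0].mask, records[0].mask)
        # TSV stores 4 decimals
        assert np.abs(loaded[0].field - records[0].field).max() < 1e-3

    def test_law_of_large_numbers_mean_pu(self):
        # at n=120 the dataset mean approaches the analytic site/stage mixture
        base = SceneSpec(image_height=96, image_width=96)
        records, _ = generate_dataset(120, seed=5, base_spec=base)
        got = np.mean([r.meta["mean_pu_inside"] for r in records])
        expected = expected_dataset_mean_pu()
        assert abs(got / expected - 1.0) < 0.05
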