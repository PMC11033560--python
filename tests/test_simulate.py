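from dataclasses import replace

import numpy as np
import pytest

from pcmfiber import (
    SceneSpec,
    easy_scene_spec,
    generate_scene,
    measure_semantic_style,
    meets_criteria,
    scene_to_density,
)
from pcmfiber.simulate import dist_mean

SMALL = dict(image_size_px=(300, 300), field_diameter_um=85.0)


def small_spec(**kw):
    base = dict(
        SMALL,
        n_fibers=4,
        length_um_dist=("uniform", 6.0, 20.0),
        width_um_dist=("uniform", 0.6, 1.5),
        waviness=0.0,
        n_particles=2,
        noise_sd=0.01,
        seed=0,
    )
    base.update(kw)
    return SceneSpec(**base)


class TestDeterminism:
    def test_same_spec_and_seed_bit_identical(self):
        spec = small_spec(waviness=0.08)
        img1, fib1, ann1 = generate_scene(spec, seed=5)
        img2, fib2, ann2 = generate_scene(spec, seed=5)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        assert len(fib1) == len(fib2)
        for a, b in zip(fib1, fib2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
            assert a.true_length_um == b.true_length_um
        for sa, sb in zip(ann1.shapes, ann2.shapes):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_different_seeds_differ(self):
        spec = small_spec()
        img1, _, _ = generate_scene(spec, seed=1)
        img2, _, _ = generate_scene(spec, seed=2)
        assert not np.array_equal(img1.pixels, img2.pixels)


class TestCountConservation:
    def test_requested_fiber_count_is_honored(self):
        img, fibers, ann = generate_scene(small_spec(n_fibers=5), seed=3)
        assert len(fibers) == 5
        assert len(ann.shapes) == 5

    def test_zero_fibers_gives_empty_annotations(self):
        img, fibers, ann = generate_scene(small_spec(n_fibers=0), seed=3)
        assert fibers == []
        assert ann.shapes == []
        assert img.pixels.shape == (300, 300)


class TestGeometry:
    def test_all_fiber_pixels_inside_field_disc(self):
        spec = small_spec(n_fibers=6, waviness=0.1)
        img, fibers, _ = generate_scene(spec, seed=9)
        h, w = img.pixels.shape
        cx, cy = (w - 1) / 2, (h - 1) / 2
        R = spec.field_radius_px
        for f in fibers:
            r = np.hypot(f.pixels[:, 1] - cx, f.pixels[:, 0] - cy)
            assert (r <= R).all()

    def test_outside_disc_is_constant_background(self):
        spec = small_spec(noise_sd=0.05)
        img, _, _ = generate_scene(spec, seed=2)
        h, w = img.pixels.shape
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = (w - 1) / 2, (h - 1) / 2
        outside = (xx - cx) ** 2 + (yy - cy) ** 2 > spec.field_radius_px**2
        values = np.unique(img.pixels[outside])
        assert len(values) == 1
        assert values[0] == round(spec.background * 255)

    def test_width_always_below_length(self):
        spec = small_spec(n_fibers=8, length_um_dist=("fixed", 6.0),
                          width_um_dist=("uniform", 0.5, 12.0))
        _, fibers, _ = generate_scene(spec, seed=4)
        for f in fibers:
            assert f.true_width_um < f.true_length_um

    def test_fiber_longer_than_field_errors(self):
        spec = small_spec(length_um_dist=("fixed", 200.0), n_fibers=1)
        with pytest.raises(RuntimeError):
            generate_scene(spec, seed=0)


class TestGroundTruthConsistency:
    def test_countable_flag_matches_criteria_on_true_dimensions(self):
        spec = small_spec(n_fibers=10, length_um_dist=("uniform", 3.0, 18.0),
                          width_um_dist=("uniform", 0.5, 2.5))
        _, fibers, _ = generate_scene(spec, seed=6)
        for f in fibers:
            assert f.is_countable == meets_criteria(f.true_length_um, f.true_width_um)

    def test_morphometry_recovers_true_dimensions_within_one_pixel(self):
        spec = easy_scene_spec(seed=21, noise_sd=0.0)
        _, fibers, _ = generate_scene(spec, seed=21)
        assert fibers
        for f in fibers:
            c = measure_semantic_style(f.pixels, spec.scale_um_per_px)
            assert c.length_um == pytest.approx(f.true_length_um, abs=spec.scale_um_per_px)
            assert c.width_um == pytest.approx(f.true_width_um, abs=spec.scale_um_per_px)

    def test_annotation_labels_follow_countability(self):
        spec = small_spec(n_fibers=10, length_um_dist=("uniform", 3.0, 18.0))
        _, fibers, ann = generate_scene(spec, seed=8)
        for f, s in zip(fibers, ann.shapes):
            expected = "countable_fiber" if f.is_countable else "subcriteria_fiber"
            assert s.label == expected


class TestSampledLengths:
    def test_mean_length_matches_distribution_within_three_se(self):
        spec = small_spec(n_fibers=5, length_um_dist=("uniform", 4.0, 20.0), waviness=0.06)
        lengths = []
        for s in range(40):  # 200 fibers
            _, fibers, _ = generate_scene(spec, seed=100 + s)
            lengths.extend(f.true_length_um for f in fibers)
        lengths = np.asarray(lengths)
        mu = dist_mean(("uniform", 4.0, 20.0))
        se = (20.0 - 4.0) / np.sqrt(12) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - mu) < 3 * se


class TestDensity:
    def test_fixed_count_all_countable_gives_exact_mean(self):
        spec = small_spec(n_fibers=9, length_um_dist=("uniform", 8.0, 20.0),
                          width_um_dist=("uniform", 0.6, 1.2))
        assert scene_to_density(spec, n_scenes=3) == 9.0

    def test_mixed_spec_density_equals_criteria_applied_to_truth(self):
        spec = small_spec(n_fibers=6, length_um_dist=("uniform", 3.0, 18.0))
        d = scene_to_density(spec, n_scenes=5)
        total = 0
        for i in range(5):
            _, fibers, _ = generate_scene(
                replace(spec, noise_sd=0.0, n_particles=0), seed=spec.seed + i
            )
            total += sum(meets_criteria(f.true_length_um, f.true_width_um) for f in fibers)
        assert d == total / 5

    def test_default_rates_target_reference_density(self):
        # default fiber rate + length law scaled to a small raster; the
        # countable mean should sit at 5.5 per field (3 SE band)
        spec = SceneSpec(
            image_size_px=(340, 340),
            field_diameter_um=100.0,
            n_particles=0,
            noise_sd=0.0,
            waviness=0.0,
            seed=500,
        )
        n_scenes = 120
        d = scene_to_density(spec, n_scenes=n_scenes)
        se = np.sqrt(5.5 / n_scenes)
        assert abs(d - 5.5) < 3 * se

    def test_invalid_scene_count_rejected(self):
        with pytest.raises(ValueError):
            scene_to_density(small_spec(), n_scenes=0)


def test_field_must_fit_in_image():
    with pytest.raises(ValueError):
        SceneSpec(image_size_px=(200, 200), field_diameter_um=300.0)
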