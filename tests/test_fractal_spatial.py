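import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tregswitch import fractal_spatial as fx
from tregswitch import synthetic_data as sd
from tregswitch.errors import (
    DegenerateThresholdError,
    EmptyForegroundError,
    InsufficientScalesError,
    ParameterError,
)

from .conftest import naive_box_masses

LN8_LN3 = np.log(8) / np.log(3)


def single_pixel(shape=(32, 32)):
    pixels = np.zeros(shape, dtype=bool)
    pixels[0, 0] = True
    return fx.BinaryImage(pixels)


class TestSegment:
    def test_idempotent_on_binary(self):
        pixels = np.zeros((16, 16), dtype=np.uint8)
        pixels[4:8, 4:8] = 255
        once = fx.segment(pixels, method="otsu")
        twice = fx.segment(once.pixels, method="otsu")
        np.testing.assert_array_equal(once.pixels, twice.pixels)
        np.testing.assert_array_equal(once.pixels, pixels > 0)

    def test_two_level_otsu(self):
        image = np.full((10, 10), 10, dtype=np.uint8)
        image[3:6, 3:6] = 200
        mask = fx.segment(image, method="otsu")
        np.testing.assert_array_equal(mask.pixels, image == 200)

    def test_ramp_fixed_threshold(self):
        ramp = np.tile(np.arange(256, dtype=np.uint8), (8, 1))
        mask = fx.segment(ramp, method="fixed", threshold=127)
        assert mask.pixels.mean() == pytest.approx(128 / 256, abs=0.01)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateThresholdError):
            fx.segment(np.full((8, 8), 7), method="otsu")

    def test_fixed_requires_threshold(self):
        with pytest.raises(ParameterError):
            fx.segment(np.zeros((8, 8)), method="fixed")

    def test_treg_mask_intersection(self):
        cd4 = fx.BinaryImage(np.eye(8, dtype=bool) | True)
        foxp3 = fx.BinaryImage(np.eye(8, dtype=bool))
        both = fx.treg_mask(cd4, foxp3)
        assert both.n_foreground == 8


class TestBoxCount:
    def test_solid_full_tiling(self):
        img = fx.BinaryImage(np.ones((64, 64), dtype=bool))
        curve = fx.box_count(img, box_sizes=[8])
        assert curve.occupied[0] == 64
        assert curve.n_boxes[0] == 64

    def test_single_pixel_always_one_box(self):
        curve = fx.box_count(single_pixel())
        assert np.all(curve.occupied == 1)

    def test_carpet_one_level(self, carpet_81):
        curve = fx.box_count(carpet_81, box_sizes=[27])
        assert curve.occupied[0] == 8

    def test_default_ladder(self):
        img = fx.BinaryImage(np.ones((64, 64), dtype=bool))
        curve = fx.box_count(img)
        np.testing.assert_array_equal(curve.box_sizes, [1, 2, 4, 8, 16, 32])

    def test_base_three_ladder(self, carpet_81):
        curve = fx.box_count(carpet_81, base=3)
        np.testing.assert_array_equal(curve.box_sizes, [1, 3, 9, 27])

    def test_agrees_with_naive_oracle(self, rng):
        for _ in range(5):
            h, w = rng.integers(8, 64, size=2)
            pixels = rng.random((h, w)) < rng.uniform(0.05, 0.6)
            if not pixels.any():
                pixels[0, 0] = True
            img = fx.BinaryImage(pixels)
            sizes = [s for s in (1, 2, 3, 4, 5, 7, 8) if s <= min(h, w)]
            curve = fx.box_count(img, box_sizes=sizes)
            for i, eps in enumerate(curve.box_sizes):
                masses = naive_box_masses(pixels, int(eps))
                assert curve.occupied[i] == sum(m > 0 for m in masses)
                assert curve.n_boxes[i] == len(masses)
                assert curve.mass_mean[i] == pytest.approx(np.mean(masses))
                assert curve.mass_var[i] == pytest.approx(np.var(masses))

    def test_empty_foreground_rejected(self):
        with pytest.raises(EmptyForegroundError):
            fx.box_count(fx.BinaryImage(np.zeros((8, 8), dtype=bool)))

    def test_bad_sizes_rejected(self):
        img = fx.BinaryImage(np.ones((8, 8), dtype=bool))
        with pytest.raises(ParameterError):
            fx.box_count(img, box_sizes=[0, 2])
        with pytest.raises(ParameterError):
            fx.box_count(img, box_sizes=[16])

    @settings(max_examples=25, deadline=None)
    @given(
        pixels=hnp.arrays(
            bool,
            st.tuples(st.integers(8, 40), st.integers(8, 40)),
            elements=st.booleans(),
        )
    )
    def test_occupancy_monotone_in_scale(self, pixels):
        if not pixels.any():
            pixels[0, 0] = True
        curve = fx.box_count(fx.BinaryImage(pixels))
        assert np.all(np.diff(curve.occupied) <= 0)
        assert np.all(curve.occupied >= 1)
        assert np.all(curve.mass_var >= 0)


class TestFractalDimension:
    def test_solid_square_plane_filling(self):
        img = fx.BinaryImage(np.ones((64, 64), dtype=bool))
        metrics = fx.fractal_dimension(fx.box_count(img))
        assert metrics.fd == pytest.approx(2.0, abs=0.02)
        assert metrics.r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_pixel_dimension_zero(self):
        metrics = fx.fractal_dimension(fx.box_count(single_pixel()))
        assert metrics.fd == 0.0

    def test_sierpinski_carpet_similarity_dimension(self, carpet_81):
        metrics = fx.fractal_dimension(fx.box_count(carpet_81, base=3))
        assert metrics.fd == pytest.approx(LN8_LN3, abs=0.05)

    def test_insufficient_scales(self, carpet_81):
        curve = fx.box_count(carpet_81, box_sizes=[1, 3])
        with pytest.raises(InsufficientScalesError):
            fx.fractal_dimension(curve)

    def test_translation_and_rotation_tolerance(self):
        spec = sd.SpatialImageSpec(
            shape=(64, 64), pattern="uniform_random", n_points=600, seed=4
        )
        pixels = sd.generate_spatial_image(spec).pixels
        fd0 = fx.fractal_dimension(fx.box_count(fx.BinaryImage(pixels))).fd
        rolled = np.roll(pixels, (3, 5), axis=(0, 1))
        rotated = np.rot90(pixels)
        for variant in (rolled, rotated):
            fd1 = fx.fractal_dimension(fx.box_count(fx.BinaryImage(variant))).fd
            assert fd1 == pytest.approx(fd0, abs=0.02)

    @settings(max_examples=25, deadline=None)
    @given(
        pixels=hnp.arrays(
            bool,
            st.tuples(st.integers(8, 40), st.integers(8, 40)),
            elements=st.booleans(),
        )
    )
    def test_dimension_bounds(self, pixels):
        if not pixels.any():
            pixels[0, 0] = True
        curve = fx.box_count(fx.BinaryImage(pixels))
        if curve.box_sizes.size < 3:
            return
        metrics = fx.fractal_dimension(curve)
        assert -1e-9 <= metrics.fd <= 2 + 1e-9
        assert -1e-9 <= metrics.r2 <= 1 + 1e-9


class TestLacunarity:
    def test_uniform_fill_is_one(self):
        img = fx.BinaryImage(np.ones((64, 64), dtype=bool))
        curve = fx.box_count(img)
        per_scale = fx.lacunarity_per_scale(curve)
        np.testing.assert_allclose(per_scale, 1.0)
        assert fx.lacunarity(curve).lacunarity == pytest.approx(1.0)

    def test_single_occupied_box_equals_box_total(self):
        # one foreground pixel: lambda(eps) = B, the Bernoulli moment ratio
        curve = fx.box_count(single_pixel(shape=(16, 16)), box_sizes=[4, 8])
        per_scale = fx.lacunarity_per_scale(curve)
        np.testing.assert_allclose(per_scale, curve.n_boxes.astype(float))

    def test_poisson_limit(self):
        # uniform random points: lambda -> 1 + 1/(mean mass) from above
        img = sd.generate_spatial_image(
            sd.SpatialImageSpec(
                shape=(128, 128), pattern="uniform_random", n_points=4000, seed=8
            )
        )
        curve = fx.box_count(img, box_sizes=[8])
        lam = fx.lacunarity_per_scale(curve)[0]
        expected = 1.0 + 1.0 / curve.mass_mean[0]
        # without-replacement placement is slightly under-dispersed vs Poisson
        assert lam == pytest.approx(expected, rel=0.05)
        assert lam >= 1.0

    def test_lacunarity_at_least_one(self, rng):
        for _ in range(5):
            pixels = rng.random((32, 32)) < 0.2
            if not pixels.any():
                pixels[0, 0] = True
            metrics = fx.lacunarity(fx.box_count(fx.BinaryImage(pixels)))
            assert metrics.lacunarity >= 1.0


class TestCompareGroups:
    def test_identical_lists_symmetric(self):
        metrics = [fx.FractalMetrics(fd=v) for v in (1.0, 1.2, 1.4, 1.6)]
        result = fx.compare_groups(metrics, metrics, measure="fd")
        assert result.u == pytest.approx(len(metrics) ** 2 / 2)
        assert result.p == pytest.approx(1.0)

    def test_directionality(self):
        dense = [
            fx.compute_metrics(
                sd.generate_spatial_image(
                    sd.SpatialImageSpec(
                        shape=(64, 64),
                        pattern="clustered",
                        n_points=1500,
                        cluster_count=8,
                        cluster_sd=4.0,
                        seed=s,
                    )
                )
            )
            for s in range(8)
        ]
        sparse = [
            fx.compute_metrics(
                sd.generate_spatial_image(
                    sd.SpatialImageSpec(
                        shape=(64, 64),
                        pattern="uniform_random",
                        n_points=150,
                        seed=100 + s,
                    )
                )
            )
            for s in range(8)
        ]
        fd_cmp = fx.compare_groups(dense, sparse, measure="fd")
        lc_cmp = fx.compare_groups(dense, sparse, measure="lacunarity")
        assert fd_cmp.mean_a > fd_cmp.mean_b
        assert lc_cmp.mean_a < lc_cmp.mean_b

    def test_group_size_validation(self):
        metrics = [fx.FractalMetrics(fd=1.0)]
        with pytest.raises(ParameterError):
            fx.compare_groups(metrics, metrics, measure="fd")
        with pytest.raises(ParameterError):
            fx.compare_groups(metrics * 3, metrics * 3, measure="area")
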