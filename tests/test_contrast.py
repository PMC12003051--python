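import numpy as np
import pytest

from speckleflow.contrast import (
    ContrastMap,
    KernelSpec,
    contrast_direct,
    contrast_sums,
    contrast_variant,
    crop_edges,
    disc_offsets,
    mean_ks,
    relative_error_map,
)


def brute_force_window_ks(values, divisor="population_n"):
    """Oracle: Ks of one window from the plain definitions, python floats only."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n if divisor == "population_n" else n - 1)
    return var ** 0.5 / mean


class TestWindowExamples:
    def test_outlier_window(self):
        """24 pixels of 1 and one of 26: mean 2, population variance 24."""
        img = np.ones((5, 5))
        img[0, 0] = 26.0
        expected = brute_force_window_ks(img.ravel())
        assert expected == pytest.approx(np.sqrt(24.0) / 2.0, abs=1e-12)
        for fn in (contrast_direct, contrast_sums):
            out = fn(img, KernelSpec(size=5))
            assert out.values[2, 2] == pytest.approx(expected, abs=1e-9)

    def test_consecutive_integers_window(self):
        """1..25: mean 13, variance (n^2 - 1) / 12 = 52."""
        img = np.arange(1.0, 26.0).reshape(5, 5)
        expected = brute_force_window_ks(img.ravel())
        assert expected == pytest.approx(np.sqrt(52.0) / 13.0, abs=1e-12)
        out = contrast_direct(img, KernelSpec(size=5))
        assert out.values[2, 2] == pytest.approx(expected, abs=1e-12)

    def test_constant_image_has_zero_contrast(self):
        img = np.full((16, 16), 7.0)
        for kernel in (KernelSpec(size=5), KernelSpec(shape="disc", size=5, engine="sums_disc")):
            out = contrast_variant(img, kernel)
            vals = crop_edges(out).values
            assert np.all(vals[np.isfinite(vals)] == 0.0)

    def test_disc_membership_counts(self):
        # ImageJ circular-mask convention (default) vs plain Euclidean rule
        assert disc_offsets(5)[0].size == 21
        assert disc_offsets(7)[0].size == 37
        assert disc_offsets(5, rule="euclidean")[0].size == 13
        assert disc_offsets(7, rule="euclidean")[0].size == 29


class TestEngineEquivalence:
    @pytest.mark.parametrize("size", [5, 7])
    @pytest.mark.parametrize("divisor", ["population_n", "sample_n_minus_1"])
    def test_sums_square_engines_match_direct_interior(self, size, divisor):
        """Convolution engines equal explicit summation on the valid interior to 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            img = rng.exponential(1.0, (64, 64))
            ref = crop_edges(contrast_direct(img, KernelSpec(size=size, divisor=divisor))).values
            for engine, padding in (
                ("sums_uniform", "reflect"),
                ("sums_correlate_pad", "constant_zero"),
            ):
                spec = KernelSpec(size=size, divisor=divisor, padding=padding, engine=engine)
                got = crop_edges(contrast_variant(img, spec)).values
                assert np.nanmax(np.abs(got - ref)) < 1e-9

    @pytest.mark.parametrize("size", [5, 7])
    def test_sums_disc_matches_direct_disc_interior(self, size):
        rng = np.random.default_rng(99)
        for _ in range(5):
            img = rng.exponential(1.0, (48, 48))
            ref = crop_edges(contrast_direct(img, KernelSpec(shape="disc", size=size))).values
            got = crop_edges(
                contrast_variant(img, KernelSpec(shape="disc", size=size, padding="reflect", engine="sums_disc"))
            ).values
            assert np.nanmax(np.abs(got - ref)) < 1e-9

    def test_padding_affects_only_the_border(self):
        rng = np.random.default_rng(3)
        img = rng.exponential(1.0, (40, 40))
        spec_r = KernelSpec(size=7, padding="reflect", engine="sums_uniform")
        spec_z = KernelSpec(size=7, padding="constant_zero", engine="sums_uniform")
        a = contrast_sums(img, spec_r).values
        b = contrast_sums(img, spec_z).values
        assert np.allclose(a[3:-3, 3:-3], b[3:-3, 3:-3], atol=1e-12)
        assert not np.allclose(a[:3], b[:3], atol=1e-6)

    def test_divisor_scaling_is_exact(self):
        rng = np.random.default_rng(8)
        img = rng.exponential(1.0, (32, 32))
        for kernel in (KernelSpec(size=5), KernelSpec(shape="disc", size=7)):
            n = kernel.n_pixels
            pop = contrast_direct(img, kernel).values
            sam = contrast_direct(
                img, KernelSpec(shape=kernel.shape, size=kernel.size, divisor="sample_n_minus_1")
            ).values
            np.testing.assert_allclose(sam, pop * np.sqrt(n / (n - 1.0)), rtol=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(21)
        img = rng.exponential(1.0, (48, 48))
        spec = KernelSpec(size=5, engine="sums_uniform")
        full = crop_edges(contrast_variant(img, spec)).values
        shifted = crop_edges(contrast_variant(img[3:, 5:], spec)).values
        np.testing.assert_allclose(shifted, full[3:, 5:], rtol=0, atol=1e-12)


class TestEdgesAndErrors:
    def test_image_smaller_than_kernel(self):
        with pytest.raises(ValueError, match="smaller"):
            contrast_direct(np.ones((4, 4)), KernelSpec(size=5))

    def test_engine_shape_compatibility(self):
        with pytest.raises(ValueError):
            contrast_variant(np.ones((16, 16)), KernelSpec(shape="disc", size=5, engine="sums_uniform"))

    @pytest.mark.parametrize("n, size, expected", [(100, 7, 94), (120, 5, 116)])
    def test_crop_arithmetic(self, n, size, expected):
        cmap = contrast_sums(np.random.default_rng(0).exponential(1.0, (n, n)),
                             KernelSpec(size=size, padding="reflect", engine="sums_uniform"))
        cropped = crop_edges(cmap)
        assert cropped.values.shape == (expected, expected)
        assert cropped.valid_margin == 0

    def test_crop_is_idempotent_in_content(self):
        rng = np.random.default_rng(1)
        cmap = contrast_sums(rng.exponential(1.0, (30, 30)), KernelSpec(size=5, padding="reflect", engine="sums_uniform"))
        once = crop_edges(cmap)
        twice = crop_edges(once)
        assert np.array_equal(twice.values, once.values)

    def test_zero_mean_windows_are_nan_not_infinite(self):
        img = np.zeros((16, 16))
        img[12:, 12:] = 3.0
        out = contrast_sums(img, KernelSpec(size=5, padding="reflect", engine="sums_uniform"))
        assert not np.any(np.isinf(out.values))
        assert np.isnan(out.values[2, 2])

    def test_mean_ks_uses_cropped_region_only(self):
        rng = np.random.default_rng(17)
        img = rng.exponential(1.0, (40, 40))
        cmap = contrast_sums(img, KernelSpec(size=7, padding="constant_zero", engine="sums_uniform"))
        assert mean_ks(cmap) == pytest.approx(float(np.nanmean(crop_edges(cmap).values)))


class TestRelativeError:
    def _map(self, values):
        return ContrastMap(values, 1.0, KernelSpec(size=5), valid_margin=0)

    def test_identity_and_scaling(self):
        rng = np.random.default_rng(5)
        ref = self._map(rng.exponential(1.0, (10, 10)))
        err, stats = relative_error_map(ref, ref)
        assert np.allclose(err, 0.0)
        scaled = self._map(0.8 * ref.values)
        err, stats = relative_error_map(scaled, ref)
        np.testing.assert_allclose(err, -20.0, rtol=1e-12)
        assert stats.mean == pytest.approx(-20.0)

    def test_zero_reference_pixels_are_undefined(self):
        ref = self._map(np.ones((6, 6)))
        ref.values[2, 2] = 0.0
        test = self._map(np.ones((6, 6)))
        err, _ = relative_error_map(test, ref)
        assert np.isnan(err[2, 2])
        assert not np.any(np.isinf(err))

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="shape"):
            relative_error_map(self._map(np.ones((6, 6))), self._map(np.ones((8, 8))))
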