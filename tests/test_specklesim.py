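import dataclasses

import numpy as np
import pytest
from scipy.special import j1

from speckleflow import (
    DecorrelationSpec,
    SimulationConfig,
    generate_field_sequence,
    integrate_exposure,
    quantize,
    simulate_mesi_stack,
)
from speckleflow.contrast import KernelSpec, contrast_variant, mean_ks

from conftest import siegert_gaps


def _config(**kw):
    base = dict(
        decorrelation=DecorrelationSpec(tau_c=1.0),
        image_shape=(128, 128),
        exposure_times=(1.0,),
        n_polarization=1,
        seed=42,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_aliased_speckle(self):
        with pytest.raises(ValueError, match="px_per_speckle"):
            _config(px_per_speckle=1.5)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(exposure_times=(1.0, 0.5)),  # not ascending
            dict(exposure_times=(-1.0,)),
            dict(mean_fill_fraction=1.5),
            dict(n_polarization=0),
        ],
    )
    def test_rejects_invalid_fields(self, kw):
        with pytest.raises(ValueError):
            _config(**kw)

    def test_g1_forms_start_at_one_and_decrease(self):
        taus = np.linspace(0, 5, 40)
        for form in ("neg_exponential", "gaussian", "sqrt_exponential"):
            g = DecorrelationSpec(tau_c=0.7, form=form).g1(taus)
            assert g[0] == 1.0
            assert np.all(np.diff(g) <= 0)


class TestFieldStatistics:
    def test_fully_developed_marginal_has_unit_contrast(self):
        """Polarized fully developed speckle has exponential intensities (sigma/mu = 1)."""
        frame = generate_field_sequence(_config(image_shape=(256, 256)), duration=0.05).frames[0]
        contrast = frame.std() / frame.mean()
        assert 0.95 < contrast < 1.05

    def test_unpolarized_detection_halves_intensity_variance(self):
        frame = generate_field_sequence(
            _config(image_shape=(256, 256), n_polarization=2), duration=0.05
        ).frames[0]
        assert 0.95 / np.sqrt(2) < frame.std() / frame.mean() < 1.05 / np.sqrt(2)

    def test_static_field_does_not_evolve(self):
        config = _config(decorrelation=DecorrelationSpec(tau_c=1.0, static=True), image_shape=(64, 64))
        frames = generate_field_sequence(config, duration=0.3).frames
        assert len(frames) > 2
        assert np.array_equal(frames[0], frames[-1])

    def test_speckle_grain_size_sets_spatial_correlation(self):
        """Nearest-neighbour intensity correlation matches the pupil's Airy profile."""
        for s in (3.0, 6.0):
            frame = generate_field_sequence(
                _config(image_shape=(256, 256), px_per_speckle=s), duration=0.05
            ).frames[0]
            d = frame - frame.mean()
            rho1 = float(np.mean(d[:, :-1] * d[:, 1:]) / np.mean(d * d))
            arg = np.pi / s
            theory = (2 * j1(arg) / arg) ** 2
            assert abs(rho1 - theory) < 0.08

    def test_siegert_relation_for_raw_sequences(self):
        """g2(tau) - 1 tracks |g1(tau)|^2 at all tested lags (Monte-Carlo tolerance)."""
        gaps = siegert_gaps()
        assert np.all(np.abs(gaps) < 0.03)

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            generate_field_sequence(_config(), duration=0.0)


class TestIntegration:
    def test_short_exposure_is_a_single_raw_frame(self):
        frame = integrate_exposure(_config(image_shape=(192, 192)), T=1e-4)
        assert 0.95 < frame.std() / frame.mean() < 1.05

    def test_contrast_squared_halves_when_exposure_doubles(self):
        """Deep in the averaging regime Ks^2 scales as tau_c / T."""
        config = _config(
            decorrelation=DecorrelationSpec(tau_c=0.1), image_shape=(128, 128), n_polarization=2
        )
        kernel = KernelSpec(engine="sums_uniform", size=7)
        rngs = np.random.SeedSequence(5).spawn(2)
        k30 = mean_ks(contrast_variant(integrate_exposure(config, 30.0, np.random.default_rng(rngs[0])), kernel))
        k60 = mean_ks(contrast_variant(integrate_exposure(config, 60.0, np.random.default_rng(rngs[1])), kernel))
        ratio = k30 ** 2 / k60 ** 2
        assert 1.7 < ratio < 2.3

    def test_mean_contrast_nonincreasing_over_exposure_ladder(self, small_stack):
        kernel = KernelSpec(engine="sums_uniform", size=7)
        ks = [
            mean_ks(contrast_variant(f.astype(float), kernel, T))
            for f, T in zip(small_stack.frames, small_stack.exposure_time_per_frame)
        ]
        for a, b in zip(ks, ks[1:]):
            assert b <= a * 1.01  # 1% statistical tolerance between adjacent exposures

    def test_subframe_cap_signals_resource_exhaustion(self):
        config = _config(max_subframes=10, decorrelation=DecorrelationSpec(tau_c=0.1))
        with pytest.raises(RuntimeError, match="sub-frames"):
            integrate_exposure(config, T=60.0)

    def test_identical_seed_and_config_reproduce_bit_identical_stacks(self):
        config = _config(image_shape=(64, 64), exposure_times=(0.2, 1.0), n_polarization=2)
        a = simulate_mesi_stack(config)
        b = simulate_mesi_stack(dataclasses.replace(config))
        assert np.array_equal(a.frames, b.frames)


class TestQuantize:
    def test_constant_frame_maps_to_fill_fraction(self):
        out, sat = quantize(np.ones((8, 8)), bit_depth=12, mean_fill_fraction=0.25)
        assert np.all(out == 1024)  # round(0.25 * 4095)
        assert sat == 0.0

    def test_full_scale_is_bit_depth_limited(self, rng):
        out, _ = quantize(rng.exponential(1.0, (64, 64)), bit_depth=12)
        assert out.max() <= 4095

    def test_exponential_tail_saturation_fraction(self, rng):
        """Mean at quarter scale clips the exponential tail beyond 4*mu: P = e^-4."""
        frame = rng.exponential(1.0, (512, 512))
        _, sat = quantize(frame, bit_depth=12, mean_fill_fraction=0.25)
        assert abs(sat - np.exp(-4)) < 0.003

    def test_all_zero_frame_has_no_scale(self):
        with pytest.raises(ValueError, match="all-zero"):
            quantize(np.zeros((4, 4)))
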