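"""Ground-truth properties of the synthetic speckle generator."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from speckleflow.errors import InvalidConfigError
from speckleflow.metrics import compute_autocovariance, compute_contrast, estimate_speckle_size
from speckleflow.synthetic import (
    SimulationConfig,
    generate_dynamic_stack,
    generate_flow_front_stack,
    generate_fluorescence_image,
    generate_grain_ramp_stack,
    generate_static_speckle,
    pupil_cutoff_for_grain,
)


class TestStaticSpeckle:
    def test_intensity_follows_negative_exponential_law(self):
        """Fully developed speckle intensity is exponentially distributed.

        Pixels are subsampled on a grid spaced 3 grains apart to
        approximate independence (neighbouring pixels are correlated over
        one grain); the KS test against Exp(sample mean) must not reject
        at alpha = 0.01.
        """
        config = SimulationConfig(image_shape=(512, 512), grain_size_px=6.0, seed=1)
        frame = generate_static_speckle(config)
        step = 18  # 3 grains
        samples = frame.intensity[::step, ::step].ravel()
        _, p = sps.kstest(samples, "expon", args=(0, samples.mean()))
        assert p > 0.01

    def test_nonnegative_and_unit_contrast_without_noise(self, static_frame):
        assert static_frame.intensity.min() >= 0
        assert abs(compute_contrast(static_frame).contrast - 1.0) < 0.05

    def test_seeded_determinism(self):
        config = SimulationConfig(image_shape=(128, 128), grain_size_px=5.0, seed=42)
        a = generate_static_speckle(config)
        b = generate_static_speckle(config)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_rejects_subnyquist_grain(self):
        with pytest.raises(InvalidConfigError):
            generate_static_speckle(
                SimulationConfig(image_shape=(64, 64), grain_size_px=1.5)
            )

    def test_warns_when_image_under_8x_grain(self):
        with pytest.warns(UserWarning, match="8x grain"):
            generate_static_speckle(
                SimulationConfig(image_shape=(64, 64), grain_size_px=10.0)
            )

    def test_halving_cutoff_doubles_autocovariance_width(self):
        """Fourier scaling: doubling the pupil radius halves the measured
        autocovariance width within 5%."""
        widths = {}
        for grain in (6.0, 12.0):
            config = SimulationConfig(image_shape=(512, 512),
                                      grain_size_px=grain, seed=5)
            frame = generate_static_speckle(config)
            acov = compute_autocovariance(frame)
            widths[grain] = estimate_speckle_size(acov, 1.0).size_px
        # cutoff(12) = cutoff(6)/2, so width should double
        assert pupil_cutoff_for_grain(12.0) == pytest.approx(
            pupil_cutoff_for_grain(6.0) / 2
        )
        assert widths[12.0] / widths[6.0] == pytest.approx(2.0, rel=0.05)

    def test_offset_and_noise_are_applied(self):
        config = SimulationConfig(image_shape=(128, 128), grain_size_px=5.0,
                                  seed=3, offset=500.0, noise_sd=10.0)
        clean = generate_static_speckle(
            SimulationConfig(image_shape=(128, 128), grain_size_px=5.0, seed=3)
        )
        noisy = generate_static_speckle(config)
        assert noisy.intensity.mean() == pytest.approx(
            clean.intensity.mean() + 500.0, rel=0.01
        )


class TestDynamicStack:
    def test_infinite_correlation_time_freezes_the_field(self):
        config = SimulationConfig(image_shape=(128, 128), grain_size_px=5.0,
                                  correlation_time_s=math.inf, n_frames=4, seed=2)
        stack, truth = generate_dynamic_stack(config)
        for frame in stack.frames[1:]:
            np.testing.assert_allclose(frame.intensity, stack[0].intensity)
        assert truth.true_correlation_time_s == math.inf

    def test_fast_decorrelation_matches_subframe_averaging_oracle(self):
        """With correlation time far below the exposure, the 8 sub-frames
        are effectively independent, so per-frame contrast must match the
        oracle: an explicit average of 8 independent static patterns."""
        config = SimulationConfig(
            image_shape=(256, 256), grain_size_px=5.0,
            correlation_time_s=1e-6, frame_rate_hz=1250.0,
            exposure_time_s=0.8e-3, n_frames=3, seed=9,
        )
        stack, _ = generate_dynamic_stack(config)
        measured = np.mean([compute_contrast(f).contrast for f in stack.frames])

        rng = np.random.default_rng(123)
        oracle_frames = [
            generate_static_speckle(
                SimulationConfig(image_shape=(256, 256), grain_size_px=5.0,
                                 seed=int(rng.integers(2 ** 31)))
            ).intensity
            for _ in range(8)
        ]
        oracle = compute_contrast(np.mean(oracle_frames, axis=0)).contrast
        assert measured == pytest.approx(oracle, rel=0.10)
        assert measured < 0.5  # far below the static value of 1

    def test_frame_correlation_decays_monotonically_with_lag(self):
        config = SimulationConfig(
            image_shape=(128, 128), grain_size_px=5.0,
            correlation_time_s=4e-3, frame_rate_hz=1250.0,
            exposure_time_s=0.2e-3, n_frames=40, seed=4,
        )
        stack, _ = generate_dynamic_stack(config)
        movie = stack.as_array().reshape(len(stack), -1)
        movie = movie - movie.mean(axis=1, keepdims=True)
        ref = movie[0]
        corr = [float(np.dot(ref, movie[k]) /
                      (np.linalg.norm(ref) * np.linalg.norm(movie[k])))
                for k in range(0, 25, 6)]
        assert all(a > b for a, b in zip(corr, corr[1:]))

    def test_rejects_nonpositive_correlation_time(self):
        with pytest.raises(InvalidConfigError):
            generate_dynamic_stack(
                SimulationConfig(image_shape=(64, 64), grain_size_px=4.0,
                                 correlation_time_s=0.0)
            )

    def test_exposure_longer_than_frame_period_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(image_shape=(64, 64), grain_size_px=4.0,
                             frame_rate_hz=1250.0,
                             exposure_time_s=1e-3).validate()


class TestFlowFront:
    @staticmethod
    def _config(speed, n_frames, frame_rate=1250.0, shape=(32, 320), seed=0):
        return SimulationConfig(
            image_shape=shape, grain_size_px=4.0,
            correlation_time_s=math.inf, frame_rate_hz=frame_rate,
            exposure_time_s=0.5 / frame_rate, n_frames=n_frames,
            front_speed_px_per_s=speed, seed=seed,
        )

    def test_crossing_frame_count_equals_length_over_speed(self):
        # crossing frames = roi_length / speed * frame_rate
        _, truth = generate_flow_front_stack(
            self._config(speed=1000.0, n_frames=400), roi_length_px=300
        )
        assert truth.exit_frame - truth.entry_frame == pytest.approx(
            300 / 1000.0 * 1250.0, abs=1
        )

    def test_doubling_speed_halves_crossing_frames(self):
        _, slow = generate_flow_front_stack(
            self._config(speed=500.0, n_frames=780), roi_length_px=300
        )
        _, fast = generate_flow_front_stack(
            self._config(speed=1000.0, n_frames=780), roi_length_px=300
        )
        slow_frames = slow.exit_frame - slow.entry_frame
        fast_frames = fast.exit_frame - fast.entry_frame
        assert slow_frames == pytest.approx(2 * fast_frames, abs=1)

    def test_front_position_is_monotone_nondecreasing(self):
        stack, _ = generate_flow_front_stack(
            self._config(speed=2000.0, n_frames=200), roi_length_px=300
        )
        # last lit column per frame, from construction
        lit = [int(np.flatnonzero(f.intensity.mean(axis=0) > 0)[-1])
               if np.any(f.intensity.mean(axis=0) > 0) else -1
               for f in stack.frames]
        assert all(a <= b for a, b in zip(lit, lit[1:]))

    def test_error_when_front_cannot_cross_in_time(self):
        with pytest.raises(InvalidConfigError, match="n_frames"):
            generate_flow_front_stack(
                self._config(speed=10.0, n_frames=50), roi_length_px=300
            )


class TestGrainRamp:
    def test_ramp_spans_requested_grains(self):
        config = SimulationConfig(image_shape=(256, 256), grain_size_px=6.0,
                                  n_frames=5, frame_rate_hz=10.0,
                                  exposure_time_s=0.05, seed=8)
        stack, truth = generate_grain_ramp_stack(config, 6.0, 10.0)
        assert len(stack) == 5
        assert truth.true_grain_size_px == pytest.approx(8.0)
        first = estimate_speckle_size(
            compute_autocovariance(stack[0]), 1.0).size_px
        last = estimate_speckle_size(
            compute_autocovariance(stack[-1]), 1.0).size_px
        assert last > first


class TestFluorescenceImage:
    def test_zero_blobs_gives_background_plus_noise_only(self):
        frame, truth = generate_fluorescence_image(
            blob_count=0, blob_intensity=100.0, background_level=10.0, seed=1
        )
        assert not truth.blob_mask.any()
        assert frame.intensity.mean() == pytest.approx(10.0, abs=0.5)

    def test_brighter_blobs_raise_mask_mean(self):
        dim, truth = generate_fluorescence_image(
            blob_count=5, blob_intensity=50.0, background_level=10.0, seed=2
        )
        bright, _ = generate_fluorescence_image(
            blob_count=5, blob_intensity=200.0, background_level=10.0, seed=2
        )
        mask = truth.blob_mask
        assert bright.intensity[mask].mean() > dim.intensity[mask].mean()

    def test_seeded_repeatability(self):
        a, _ = generate_fluorescence_image(3, 80.0, 5.0, seed=7)
        b, _ = generate_fluorescence_image(3, 80.0, 5.0, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_warns_when_blobs_dimmer_than_background(self):
        with pytest.warns(UserWarning, match="near-zero score"):
            generate_fluorescence_image(2, 5.0, 50.0, seed=1)
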