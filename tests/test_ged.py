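"""GED fit, component space, reconstruction, batch and streaming pipelines."""

import numpy as np
import pytest
import scipy.linalg

from conftest import random_spd
from gedclean import (
    RunConfig,
    SessionSpec,
    calibrate_stream,
    components,
    denoise_batch,
    denoise_stream,
    ged_fit,
    reconstruct,
    synthesize_session,
)
from gedclean.covariance import SpdError


class TestGedFit:
    def test_identical_covariances_give_unit_eigenvalues(self):
        model = ged_fit(np.eye(4), np.eye(4))
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-12)
        np.testing.assert_allclose(model.filters @ model.filters.T, np.eye(4), atol=1e-10)

    def test_diagonal_contrast(self):
        model = ged_fit(np.diag([9.0, 1.0]), np.eye(2))
        np.testing.assert_allclose(model.eigenvalues, [9.0, 1.0])
        np.testing.assert_allclose(np.abs(model.filters), np.eye(2), atol=1e-12)

    def test_normalization_identities_and_oracle(self):
        """W^T C_r W = I, W^T C_m W = diag(eigs); eigenvalues match a direct
        eigendecomposition of C_r^{-1} C_m."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            c_r, c_m = random_spd(rng, 8), random_spd(rng, 8)
            model = ged_fit(c_m, c_r)
            w = model.filters
            np.testing.assert_allclose(w.T @ c_r @ w, np.eye(8), atol=1e-8)
            np.testing.assert_allclose(
                w.T @ c_m @ w, np.diag(model.eigenvalues), atol=1e-8
            )
            oracle = np.sort(np.linalg.eigvals(np.linalg.solve(c_r, c_m)).real)[::-1]
            np.testing.assert_allclose(model.eigenvalues, oracle, rtol=1e-8)

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(1)
        model = ged_fit(random_spd(rng, 6), random_spd(rng, 6))
        assert np.all(np.diff(model.eigenvalues) <= 0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        c_r, c_m = random_spd(rng, 5), random_spd(rng, 5)
        w = ged_fit(c_m, c_r).filters
        peaks = np.abs(w).argmax(axis=0)
        assert np.all(w[peaks, np.arange(5)] > 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ged_fit(np.eye(3), np.eye(4))

    def test_singular_rest_covariance_instructs_regularization(self):
        c_r = np.diag([1.0, 0.0])
        with pytest.raises((SpdError, scipy.linalg.LinAlgError, np.linalg.LinAlgError)):
            ged_fit(np.eye(2), c_r)


class TestComponents:
    def test_identity_filters_pass_through(self):
        model = ged_fit(np.eye(3), np.eye(3))
        x = np.random.default_rng(0).standard_normal((3, 50))
        # identity contrast yields orthogonal W; undo it for the check
        y = components(model, x)
        np.testing.assert_allclose(model.filters @ y, x, atol=1e-10)

    def test_zero_in_zero_out(self):
        rng = np.random.default_rng(1)
        model = ged_fit(random_spd(rng, 4), random_spd(rng, 4))
        assert not components(model, np.zeros((4, 10))).any()

    def test_round_trip_inverse_filters(self):
        rng = np.random.default_rng(2)
        model = ged_fit(random_spd(rng, 6), random_spd(rng, 6))
        x = rng.standard_normal((6, 100))
        np.testing.assert_allclose(model.inverse_filters @ components(model, x), x,
                                   atol=1e-8)


class TestReconstruct:
    @pytest.fixture()
    def model_and_data(self):
        rng = np.random.default_rng(3)
        model = ged_fit(random_spd(rng, 6), random_spd(rng, 6))
        return model, rng.standard_normal((6, 200))

    def test_empty_set_identity(self, model_and_data):
        model, x = model_and_data
        denoised, removed = reconstruct(model, x, [])
        np.testing.assert_allclose(denoised, x, atol=1e-8)
        assert not removed.any()

    def test_full_set_zeroes_signal(self, model_and_data):
        model, x = model_and_data
        denoised, _ = reconstruct(model, x, range(6))
        np.testing.assert_allclose(denoised, 0.0, atol=1e-8)

    def test_exact_additive_decomposition(self, model_and_data):
        model, x = model_and_data
        denoised, removed = reconstruct(model, x, [0, 2])
        np.testing.assert_allclose(denoised + removed, x, rtol=0,
                                   atol=np.abs(x).max() * 1e-14)

    def test_projection_idempotent(self, model_and_data):
        model, x = model_and_data
        once, _ = reconstruct(model, x, [0, 1])
        twice, _ = reconstruct(model, once, [0, 1])
        np.testing.assert_allclose(twice, once, atol=1e-8)

    def test_index_out_of_range(self, model_and_data):
        model, x = model_and_data
        with pytest.raises(IndexError):
            reconstruct(model, x, [7])

    def test_single_source_recovery(self):
        """Removing the top component from a one-artefact session recovers the
        brain mixture and isolates the artefact, on burst samples."""
        spec = SessionSpec(n_channels=16, rest_duration=30, motion_duration=30,
                           n_brain=8, n_motion=1, artefact_rms_ratio=10.0, seed=5)
        rest, motion, truth = synthesize_session(spec)
        result = denoise_batch(rest, motion, RunConfig(null_b=50, seed=5))
        assert result.artefact_indices == (0,)
        mask = motion.sample_mask("noisy")
        brain = truth.brain_contribution
        art = truth.motion_contribution
        for i in range(16):
            assert np.corrcoef(result.denoised.data[i, mask], brain[i, mask])[0, 1] > 0.9
            assert np.corrcoef(result.removed[i, mask], art[i, mask])[0, 1] > 0.9


class TestDenoiseBatch:
    def test_recovers_three_dominant_sources(self, small_session):
        rest, motion, truth = small_session
        result = denoise_batch(rest, motion, RunConfig(null_b=50, seed=7))
        assert result.artefact_indices == (0, 1, 2)
        assert not result.passthrough
        # subspace recovery: removed patterns span the true mixing columns
        patterns = result.model.inverse_filters[:, list(result.artefact_indices)]
        cosines = np.cos(scipy.linalg.subspace_angles(truth.motion_mixing, patterns))
        assert cosines.min() > 0.95

    def test_metadata_preserved(self, small_session):
        rest, motion, _ = small_session
        result = denoise_batch(rest, motion, RunConfig(null_b=50, seed=7))
        assert result.denoised.fs == motion.fs
        assert result.denoised.labels == motion.labels
        assert result.denoised.data.shape == motion.data.shape
        np.testing.assert_allclose(result.denoised.data + result.removed, motion.data,
                                   rtol=0, atol=np.abs(motion.data).max() * 1e-14)

    def test_artefact_free_contrast_passes_through(self):
        spec = SessionSpec(n_channels=12, rest_duration=40, motion_duration=40,
                           n_brain=6, n_motion=0, seed=3)
        rest, motion, _ = synthesize_session(spec)
        result = denoise_batch(rest, motion, RunConfig(null_b=50, seed=3))
        assert result.passthrough
        assert result.artefact_indices == ()
        np.testing.assert_array_equal(result.denoised.data, motion.data)


class TestDenoiseStream:
    def test_clean_stream_is_nearly_identity(self):
        spec = SessionSpec(n_channels=12, rest_duration=60, motion_duration=30,
                           n_brain=6, n_motion=0, seed=2)
        rest, motion, _ = synthesize_session(spec)
        calib = calibrate_stream(rest, RunConfig(seed=2))
        result = denoise_stream(calib, motion, config=RunConfig(seed=2))
        rms_in = np.sqrt(np.mean(motion.data**2, axis=1))
        rms_diff = np.sqrt(np.mean((motion.data - result.denoised.data) ** 2, axis=1))
        assert np.median(rms_diff / rms_in) < 0.05

    def test_stationary_artefacts_flagged_consistently_with_batch(self, small_session):
        """With a stationary artefact structure (constant-amplitude motion
        sources), the stream flags the same components as batch in >= 90%
        of windows."""
        rest, motion, truth = small_session
        fs = motion.fs
        t = np.arange(motion.n_samples) / fs
        art_sources = np.vstack([
            np.sin(2 * np.pi * f * t + p)
            for f, p in [(3.0, 0.1), (5.2, 1.3), (7.1, 2.6)]
        ])
        brain = truth.brain_contribution
        art = truth.motion_mixing @ art_sources
        art *= 10.0 * np.sqrt(np.mean(brain**2) / np.mean(art**2))
        stationary = motion.with_data(brain + art)
        stationary.segments = [type(motion.segments[0])(0, motion.n_samples, "noisy")]

        cfg = RunConfig(seed=7)
        batch = denoise_batch(rest, stationary, cfg)
        assert batch.artefact_indices == (0, 1, 2)

        calib = calibrate_stream(rest, cfg)
        result = denoise_stream(calib, stationary, config=cfg)
        n_w = int(fs)
        n_windows = stationary.n_samples // n_w
        hits = 0
        from gedclean import ged_fit, identify_artefacts
        from gedclean.covariance import regularize_spd, window_covariances
        alpha_w = 1 - (1 - cfg.alpha) ** (1 / n_windows)
        for k in range(n_windows):
            sl = slice(k * n_w, (k + 1) * n_w)
            cov = regularize_spd(
                window_covariances(stationary.with_data(stationary.data[:, sl]), 1.0)[0],
                1e-6,
            )
            model = ged_fit(cov, calib.rest_cov)
            dec = identify_artefacts(model.eigenvalues, calib.null, alpha=alpha_w)
            hits += set(dec.consensus) == {0, 1, 2}
        assert hits / n_windows >= 0.9
        # and the stream output actually suppresses the artefact power
        p_before = np.mean(stationary.data**2)
        p_after = np.mean(result.denoised.data**2)
        assert p_after < 0.05 * p_before

    def test_partial_tail_passes_through_and_is_flagged(self, small_session):
        rest, motion, _ = small_session
        cfg = RunConfig(seed=7)
        calib = calibrate_stream(rest, cfg)
        clipped = motion.with_data(motion.data[:, : int(5.5 * motion.fs)])
        result = denoise_stream(calib, clipped, config=cfg)
        tail = int(0.5 * motion.fs)
        assert result.tail_passthrough_samples == tail
        np.testing.assert_array_equal(
            result.denoised.data[:, -tail:], clipped.data[:, -tail:]
        )

    def test_window_longer_than_recording(self, small_session):
        rest, motion, _ = small_session
        calib = calibrate_stream(rest, RunConfig(seed=7))
        short = motion.with_data(motion.data[:, :100])
        with pytest.raises(ValueError, match="longer than recording"):
            denoise_stream(calib, short, config=RunConfig(seed=7))
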