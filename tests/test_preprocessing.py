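"""Preprocessing: resampling, FIR filters, bad channels, spline interpolation."""

import numpy as np
import pytest

from gedclean import (
    Recording,
    default_filter_order,
    detect_bad_channels,
    fir_filter,
    generate_brain_sources,
    interpolate_channels,
    preprocess,
    resample_to,
)
from gedclean.preprocessing import spline_interpolation_matrix
from gedclean.synthetic import equidistant_layout


def _rec(data, fs=256.0, positions=None, condition="rest"):
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, labels=labels, positions=positions,
                     condition=condition)


class TestResample:
    def test_same_rate_identity(self):
        rec = _rec(np.random.default_rng(0).standard_normal((4, 1000)))
        out = resample_to(rec, rec.fs)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_sine_amplitude_and_timing_preserved(self):
        """A 10 Hz sine resampled 1024 -> 256 Hz matches the analytic signal."""
        fs_in, fs_out, dur = 1024.0, 256.0, 4.0
        t_in = np.arange(int(fs_in * dur)) / fs_in
        rec = _rec(np.tile(np.sin(2 * np.pi * 10 * t_in), (2, 1)), fs=fs_in)
        out = resample_to(rec, fs_out)
        t_out = np.arange(out.n_samples) / fs_out
        expected = np.sin(2 * np.pi * 10 * t_out)
        # ignore filter edge effects
        sl = slice(64, -64)
        assert np.abs(out.data[0, sl]).max() == pytest.approx(1.0, abs=0.01)
        assert np.abs(out.data[0, sl] - expected[sl]).max() < 0.01

    def test_length_arithmetic(self):
        rec = _rec(np.zeros((2, 2560)), fs=1024.0)
        assert resample_to(rec, 256.0).n_samples == 640

    def test_rejects_upsampling(self):
        rec = _rec(np.zeros((2, 100)), fs=256.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample_to(rec, 512.0)


class TestFilterOrder:
    @pytest.mark.parametrize(
        "fs,cutoff,expected",
        [(256, 1, 768), (256, 40, 18), (2048, 1, 6144)],
    )
    def test_order_rule(self, fs, cutoff, expected):
        assert default_filter_order(fs, cutoff) == expected

    def test_rejects_cutoff_at_nyquist(self):
        with pytest.raises(ValueError):
            default_filter_order(256, 128)


class TestFirFilter:
    def test_highpass_rejects_dc(self):
        rec = _rec(np.full((2, 4000), 50.0))
        out = fir_filter(rec, "highpass", 1.0, order=512)
        assert np.abs(out.data).max() < 1e-6 * 50.0

    def test_passband_gain_near_unity(self):
        t = np.arange(60 * 256) / 256
        rec = _rec(np.tile(np.sin(2 * np.pi * 10 * t), (2, 1)))
        out = fir_filter(fir_filter(rec, "highpass", 1.0), "lowpass", 40.0)
        mid = out.data[0, 2000:-2000]
        assert 0.99 < np.abs(mid).max() < 1.01

    def test_lowpass_attenuates_60hz(self):
        t = np.arange(30 * 256) / 256
        rec = _rec(np.tile(np.sin(2 * np.pi * 60 * t), (2, 1)))
        out = fir_filter(rec, "lowpass", 40.0)
        gain = np.abs(out.data[0, 2000:-2000]).max()
        assert 20 * np.log10(1.0 / gain) >= 20  # >= 20 dB down

    def test_zero_phase_no_lag(self):
        """Cross-correlation between input and filtered output peaks at lag 0."""
        rng = np.random.default_rng(4)
        x = generate_brain_sources(1, 256 * 20, 256, seed=4) + 0 * rng.standard_normal(1)
        rec = _rec(np.vstack([x, x]))
        out = fir_filter(rec, "lowpass", 40.0)
        a, b = rec.data[0], out.data[0]
        lags = np.arange(-5, 6)
        xc = [np.dot(a[5:-5], b[5 + k : len(b) - 5 + k]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_symmetric_impulse_stays_symmetric(self):
        n = 4001
        x = np.zeros((2, n))
        x[:, n // 2] = 1.0
        out = fir_filter(_rec(x), "lowpass", 40.0, order=256)
        y = out.data[0]
        np.testing.assert_allclose(y, y[::-1], atol=1e-12)

    def test_too_short_signal_names_minimum(self):
        rec = _rec(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="need more than"):
            fir_filter(rec, "lowpass", 40.0, order=256)


class TestBadChannels:
    @pytest.fixture()
    def clean_rest(self):
        # realistic 1/f channels: no channel should stand out
        data = 10 * generate_brain_sources(16, 256 * 60, 256, seed=11)
        return _rec(data)

    def test_no_false_positives_on_clean_data(self, clean_rest):
        report = detect_bad_channels(clean_rest)
        assert report.flagged == ()

    def test_amplitude_outlier_flagged_by_criterion_1(self, clean_rest):
        data = clean_rest.data.copy()
        data[5] *= 50
        report = detect_bad_channels(_rec(data))
        assert 5 in report.per_criterion[1]
        assert 5 in report.flagged

    def test_flat_spectrum_flagged_by_criterion_5(self, clean_rest):
        data = clean_rest.data.copy()
        data[3] = 10 * np.random.default_rng(0).standard_normal(data.shape[1])
        report = detect_bad_channels(_rec(data))
        assert 3 in report.per_criterion[5]

    def test_drifting_channel_flagged_by_criterion_2(self, clean_rest):
        data = clean_rest.data.copy()
        data[7] += np.linspace(0, 500, data.shape[1])
        report = detect_bad_channels(_rec(data))
        assert 7 in report.per_criterion[2]

    def test_flagged_is_union_of_criteria(self, clean_rest):
        data = clean_rest.data.copy()
        data[5] *= 50
        report = detect_bad_channels(_rec(data))
        union = sorted(set().union(*report.per_criterion.values()))
        assert list(report.flagged) == union

    def test_needs_four_channels(self):
        with pytest.raises(ValueError, match="4 channels"):
            detect_bad_channels(_rec(np.zeros((3, 1000))))


class TestInterpolation:
    def test_empty_set_is_identity(self):
        pos = equidistant_layout(16)
        rec = _rec(np.random.default_rng(0).standard_normal((16, 100)), positions=pos)
        out = interpolate_channels(rec, [])
        np.testing.assert_array_equal(out.data, rec.data)

    def test_recovers_spherical_harmonic_field(self):
        """A degree-2 harmonic sampled at 64 electrodes is recovered at a
        deleted site within 5% relative error."""
        pos = equidistant_layout(64)
        # real degree-2 spherical harmonic: Y ~ x*y (l=2, m=-2 combination)
        field = 3 * pos[:, 0] * pos[:, 1] + 2.0
        data = np.tile(field[:, None], (1, 10))
        rec = _rec(data, positions=pos)
        bad = 20
        corrupted = rec.copy()
        corrupted.data[bad] = 999.0
        out = interpolate_channels(corrupted, [bad])
        rel_err = abs(out.data[bad, 0] - field[bad]) / abs(field[bad])
        assert rel_err < 0.05
        # untouched channels stay bit-identical
        good = [i for i in range(64) if i != bad]
        np.testing.assert_array_equal(out.data[good], corrupted.data[good])

    def test_operator_is_time_independent_linear(self):
        pos = equidistant_layout(32)
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal((32, 200)), positions=pos)
        out = interpolate_channels(rec, [4])
        good = [i for i in range(32) if i != 4]
        op = spline_interpolation_matrix(pos[good], pos[[4]])
        np.testing.assert_allclose(out.data[4], (op @ rec.data[good])[0], atol=1e-10)

    def test_matches_mne_interpolation_operator(self):
        """Independent cross-check against mne's spherical-spline matrix."""
        mne_interp = pytest.importorskip("mne.channels.interpolation")
        pos = equidistant_layout(32)
        good, bad = pos[:28], pos[28:]
        ours = spline_interpolation_matrix(good, bad)
        theirs = mne_interp._make_interpolation_matrix(good, bad)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_rejects_all_bad(self):
        pos = equidistant_layout(8)
        rec = _rec(np.zeros((8, 50)), positions=pos)
        with pytest.raises(ValueError):
            interpolate_channels(rec, list(range(8)))

    def test_requires_positions(self):
        rec = _rec(np.zeros((8, 50)))
        with pytest.raises(ValueError, match="positions"):
            interpolate_channels(rec, [0])


class TestFullChain:
    def test_preserves_geometry_and_labels(self):
        data = 10 * generate_brain_sources(8, 1024 * 10, 1024, seed=2)
        rec = Recording(data=data, fs=1024.0, labels=[f"E{i}" for i in range(8)],
                        positions=equidistant_layout(8), condition="rest")
        out, report = preprocess(rec)
        assert out.fs == 256.0
        assert out.labels == rec.labels
        assert out.n_channels == 8
        assert report is not None

    def test_motion_data_skips_bad_channel_handling_by_default(self):
        data = 10 * generate_brain_sources(8, 256 * 10, 256, seed=2)
        rec = _rec(data, condition="motion")
        _, report = preprocess(rec)
        assert report is None
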