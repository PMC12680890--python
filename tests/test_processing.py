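"""Preprocessing and feature extraction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sonoyeast.processing import (
    DEFAULT_ECHO_WINDOWS,
    AScan,
    EchoWindow,
    PipelineConfig,
    bandpass_zero_phase,
    block_average,
    envelope,
    extract_echo_features,
    feature_vector,
)
from sonoyeast.simulate import AcousticParams, SampleRecord, Strain, simulate_measurement

RATE = 1e8  # Hz


def _scan(x, rate=RATE, **kw):
    return AScan(raw=np.asarray(x, float), sampling_rate=rate, **kw)


def _toneburst(rate=RATE, n=8000, center_ns=62_500.0, f0=2e6, sigma_ns=500.0, amp=1.0, phase="sin"):
    t_ns = np.arange(n) * 1e9 / rate
    dt = t_ns - center_ns
    carrier = np.sin if phase == "sin" else np.cos
    return amp * np.exp(-(dt**2) / (2 * sigma_ns**2)) * carrier(2 * np.pi * f0 / 1e9 * dt)


def _brute_envelope(x, half):
    """Naive truncated moving-window maximum of |x|."""
    ax = np.abs(x)
    return np.array([ax[max(0, i - half) : i + half + 1].max() for i in range(len(ax))])


class TestBandpass:
    def test_inband_tone_passes(self):
        t = np.arange(40_000) / RATE
        x = np.sin(2 * np.pi * 2e6 * t)
        y = bandpass_zero_phase(_scan(x)).filtered
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(y**2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_stopband_tone_rejected(self):
        t = np.arange(40_000) / RATE
        x = np.sin(2 * np.pi * 10e6 * t)
        y = bandpass_zero_phase(_scan(x)).filtered
        atten_db = 20 * np.log10(np.sqrt(np.mean(x**2)) / np.sqrt(np.mean(y**2)))
        assert atten_db > 40

    def test_dc_removed(self):
        y = bandpass_zero_phase(_scan(np.ones(8000))).filtered
        assert np.sqrt(np.mean(y**2)) < 1e-3

    def test_zero_in_zero_out(self):
        y = bandpass_zero_phase(_scan(np.zeros(8000))).filtered
        assert np.all(y == 0.0)

    def test_zero_phase_no_lag(self):
        x = _toneburst()
        y = bandpass_zero_phase(_scan(x)).filtered
        xc = np.correlate(y, x, mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0

    def test_peak_time_preserved_within_one_sample(self):
        # cosine phase: the burst has a unique central peak, so the argmax
        # is well-conditioned on both sides of the filter
        cfg = PipelineConfig()
        scan = _scan(_toneburst(phase="cos"))
        filt = bandpass_zero_phase(scan, cfg)
        w = DEFAULT_ECHO_WINDOWS[1]
        env_raw = envelope(_scan(scan.raw), cfg)
        env_filt = envelope(filt, cfg)
        _, t_raw, _ = extract_echo_features(_scan(scan.raw), env_raw, w)
        _, t_filt, _ = extract_echo_features(filt, env_filt, w)
        assert abs(t_raw - t_filt) <= 1e9 / RATE

    def test_infeasible_passband_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_zero_phase(_scan(np.zeros(100), rate=4e6))


class TestBlockAverage:
    def test_fifty_to_ten(self):
        scans = [_scan(np.full(100, float(i))) for i in range(50)]
        out = block_average(scans, 5)
        assert len(out) == 10
        np.testing.assert_allclose(out[0].raw, np.full(100, 2.0))  # mean of 0..4

    def test_mean_of_identical_is_identity(self):
        x = np.sin(np.arange(200) / 7.0)
        out = block_average([_scan(x) for _ in range(5)], 5)
        # identical up to one ulp of rounding in the running mean
        np.testing.assert_allclose(out[0].raw, x, rtol=1e-15, atol=0)

    def test_noise_reduced_by_sqrt_block(self):
        rng = np.random.default_rng(42)
        clean = _toneburst(n=2000)
        residual_stds = []
        for _ in range(100):
            scans = [_scan(clean + rng.normal(0, 0.1, clean.shape)) for _ in range(5)]
            residual_stds.append(np.std(block_average(scans, 5)[0].raw - clean))
        mean_std = np.mean(residual_stds)
        assert abs(mean_std - 0.1 / np.sqrt(5)) / (0.1 / np.sqrt(5)) < 0.2

    def test_partial_blocks_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            block_average([_scan(np.zeros(10)) for _ in range(7)], 5)


class TestEnvelope:
    def test_constant_signal(self):
        env = envelope(_scan(np.full(500, -3.0)))
        np.testing.assert_array_equal(env.values, np.full(500, 3.0))

    def test_unit_impulse_plateau(self):
        x = np.zeros(1000)
        k = 400
        x[k] = 1.0
        cfg = PipelineConfig(envelope_window_ns=1000.0)  # 100 samples at 100 MHz
        env = envelope(_scan(x), cfg)
        half = 100 // 2
        expected = np.zeros(1000)
        expected[k - half : k + half + 1] = 1.0
        np.testing.assert_array_equal(env.values, expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(size=1500)
        env = envelope(_scan(x))
        np.testing.assert_array_equal(env.values, _brute_envelope(x, 100 // 2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(float, st.integers(50, 400), elements=st.floats(-1e6, 1e6)))
    def test_envelope_dominates_signal(self, x):
        env = envelope(_scan(x))
        assert np.all(env.values >= np.abs(x))

    def test_envelope_of_envelope_dominates(self):
        x = np.random.default_rng(3).normal(size=800)
        e1 = envelope(_scan(x)).values
        e2 = envelope(_scan(e1)).values
        assert np.all(e2 >= e1)


class TestEchoFeatures:
    WINDOW = EchoWindow(2, 60_000.0, 65_000.0)

    def test_zero_signal_degenerate(self):
        scan = _scan(np.zeros(8000))
        env = envelope(scan)
        a_max, t_max, a_sum = extract_echo_features(scan, env, self.WINDOW)
        assert a_max == 0.0 and a_sum == 0.0
        assert t_max == self.WINDOW.a_ns  # earliest sample on ties

    def test_constant_signal_sum_counts_samples(self):
        scan = _scan(np.ones(8000))
        env = envelope(scan)
        a, b = self.WINDOW.to_indices(RATE)
        _, _, a_sum = extract_echo_features(scan, env, self.WINDOW)
        assert a_sum == b - a + 1

    def test_toneburst_peak_location_and_oracle(self):
        x = _toneburst(center_ns=62_500.0)
        scan = _scan(x)
        env = envelope(scan)
        a_max, t_max, a_sum = extract_echo_features(scan, env, self.WINDOW)
        cfg = PipelineConfig()
        assert abs(t_max - 62_500.0) <= cfg.envelope_window_ns
        # independent brute-force scan over the window
        a, b = self.WINDOW.to_indices(RATE)
        brute_env = _brute_envelope(x, 100 // 2)[a : b + 1]
        assert a_max == brute_env.max()
        assert t_max == (a + int(np.argmax(brute_env))) * 1e9 / RATE
        assert a_sum == pytest.approx(np.abs(x[a : b + 1]).sum())

    def test_window_outside_record_rejected(self):
        scan = _scan(np.zeros(1000))  # 10 us record, window at 60 us
        with pytest.raises(ValueError, match="outside"):
            extract_echo_features(scan, envelope(scan), self.WINDOW)


class TestFeatureVector:
    def test_default_measurement_yields_ten_sets_of_nine(self, params, geometry, sim_config, rng):
        rec = SampleRecord(Strain.WB06, 12.0, 0.4, 1, 126e6, 126e6)
        scans = simulate_measurement(rec, params, geometry, sim_config, rng)
        sets = feature_vector(scans)
        assert len(sets) == 10
        assert all(fs.to_array().shape == (9,) for fs in sets)

    def test_deterministic_on_identical_waveforms(self, quiet_params, geometry, sim_config):
        rec = SampleRecord(Strain.W3470, 10.0, 0.8, 1, 132e6, 132e6)
        scans = simulate_measurement(rec, quiet_params, geometry, sim_config)
        a = [fs.to_array() for fs in feature_vector(scans)]
        b = [fs.to_array() for fs in feature_vector(scans)]
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_amplitude_features_decrease_with_yeast(self, quiet_params, geometry, sim_config):
        """End-to-end pipeline monotonicity with simulator noise off."""
        values = {}
        for yeast in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            rec = SampleRecord(Strain.S_CEREVISIAE, 12.0, yeast, 1, 0.0, 0.0)
            scans = simulate_measurement(rec, quiet_params, geometry, sim_config)
            fs = feature_vector(scans)[0]
            values[yeast] = (fs.A_max_2, fs.A_sum_2)
        ordered = [values[y] for y in sorted(values)]
        assert all(a[0] > b[0] for a, b in zip(ordered, ordered[1:]))
        assert all(a[1] > b[1] for a, b in zip(ordered, ordered[1:]))
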