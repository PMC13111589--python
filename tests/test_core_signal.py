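"""Filtering, epoching, rejection and Morlet transform contracts."""

import numpy as np
import pytest
from scipy.signal import periodogram

from eegmark.core_signal import (
    EpochSet,
    Recording,
    WaveletSpec,
    bandpass,
    epoch,
    morlet_kernel,
    morlet_transform,
    notch,
    reject_amplitude,
    rereference,
)

from conftest import RATE, make_recording, sinusoid


def band_power_ratio(x, rate, band):
    f, p = periodogram(x, fs=rate)
    inside = (f >= band[0]) & (f <= band[1])
    outside = (f > 0.1) & ~inside
    return p[inside].mean() / p[outside].mean()


class TestBandpass:
    def test_sleep_band_passes_sigma_rejects_gamma(self):
        x = sinusoid(13.5, 30) + sinusoid(55.0, 30)
        rec = make_recording(x)
        out = bandpass(rec, 0.3, 35.0).data[0]
        seg = slice(2000, -2000)  # away from filter edge transients
        amp_135 = _tone_amplitude(out[seg], RATE, 13.5)
        amp_55 = _tone_amplitude(out[seg], RATE, 55.0)
        assert amp_135 == pytest.approx(1.0, rel=0.05)
        assert amp_55 < 10 ** (-20 / 20)  # >= 20 dB down

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros(4000))
        assert np.allclose(bandpass(rec, 0.3, 35).data, 0.0)

    def test_white_noise_vs_fft_mask_oracle(self, rng):
        """Out-of-band PSD after the IIR filter is suppressed >= 20 dB,
        matching what an ideal FFT-mask filter achieves in-band."""
        x = rng.standard_normal(int(60 * RATE))
        out = bandpass(make_recording(x), 10.0, 50.0).data[0]
        # independent oracle: zero out-of-band FFT coefficients directly
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(len(x), 1 / RATE)
        spec[(f < 10) | (f > 50)] = 0
        oracle = np.fft.irfft(spec, n=len(x))
        f_o, p_or = periodogram(oracle, fs=RATE)
        f_i, p_iir = periodogram(out, fs=RATE)
        inband = (f_i >= 15) & (f_i <= 45)
        assert np.mean(p_iir[inband]) == pytest.approx(np.mean(p_or[inband]), rel=0.15)
        far_out = (f_i >= 100) | ((f_i > 0.1) & (f_i <= 5))
        ratio = np.mean(p_iir[inband]) / np.mean(p_iir[far_out])
        assert ratio > 100  # >= 20 dB power suppression

    @pytest.mark.parametrize(
        "lo,hi,msg",
        [(0, 35, "low"), (35, 10, "high"), (10, 300, "high")],
    )
    def test_invalid_band_names_offending_edge(self, lo, hi, msg):
        rec = make_recording(np.zeros(1000))
        with pytest.raises(ValueError, match=msg):
            bandpass(rec, lo, hi)


def _tone_amplitude(x, rate, freq):
    t = np.arange(len(x)) / rate
    c = np.exp(-2j * np.pi * freq * t)
    return 2 * np.abs(np.mean(x * c))


class TestNotch:
    def test_line_tone_suppressed(self):
        rec = make_recording(sinusoid(60.0, 30))
        out = notch(rec, 60.0).data[0][2000:-2000]
        assert np.sqrt(np.mean(out**2)) <= 0.1 * np.sqrt(0.5)

    def test_sigma_tone_untouched(self):
        rec = make_recording(sinusoid(13.5, 30))
        out = notch(rec, 60.0).data[0][2000:-2000]
        assert _tone_amplitude(out, RATE, 13.5) == pytest.approx(1.0, rel=0.05)

    def test_mixture_recovers_clean_component(self):
        clean = sinusoid(13.5, 30)
        rec = make_recording(clean + sinusoid(60.0, 30))
        out = notch(rec, 60.0).data[0]
        seg = slice(2000, -2000)
        resid = out[seg] - clean[seg]
        assert np.sqrt(np.mean(resid**2)) <= 0.1 * np.sqrt(np.mean(clean[seg] ** 2))

    def test_nyquist_rejected(self):
        rec = make_recording(np.zeros(1000))
        with pytest.raises(ValueError):
            notch(rec, 250.0)


class TestRereference:
    def test_zero_reference_is_identity(self, rng):
        data = np.vstack([rng.standard_normal(500), np.zeros(500), np.zeros(500)])
        rec = make_recording(data, labels=["Cz", "M1", "M2"])
        out = rereference(rec, ["M1", "M2"])
        assert np.allclose(out.data[0], rec.data[0])

    def test_self_reference_zeroes_channel(self, rng):
        data = np.vstack([rng.standard_normal(500)])
        rec = make_recording(data, labels=["Cz"])
        assert np.allclose(rereference(rec, ["Cz"]).data[0], 0.0)

    def test_constant_offsets_closed_form(self, rng):
        sig = rng.standard_normal(500)
        a, b = 3.0, -7.0
        data = np.vstack([sig, np.full(500, a), np.full(500, b)])
        rec = make_recording(data, labels=["Cz", "M1", "M2"])
        out = rereference(rec, ["M1", "M2"])
        assert np.allclose(out.data[0], sig - (a + b) / 2)

    def test_unknown_label_raises(self):
        rec = make_recording(np.zeros((1, 100)), labels=["Cz"])
        with pytest.raises(KeyError, match="M9"):
            rereference(rec, ["M9"])


class TestEpoch:
    def test_ramp_signal_window_values(self):
        t = np.arange(int(20 * RATE)) / RATE
        rec = make_recording(t)
        ep = epoch(rec, [10.0], -0.1, 0.4)
        assert ep.data.shape == (1, 1, 200)
        assert ep.data[0, 0, 0] == pytest.approx(9.9, abs=1e-9)
        assert ep.data[0, 0, -1] == pytest.approx(10.4 - 1 / RATE, abs=1e-9)

    def test_zero_events(self):
        rec = make_recording(np.zeros(1000))
        ep = epoch(rec, [], -0.1, 0.4)
        assert ep.n_trials == 0

    def test_many_events_match_direct_slice_oracle(self, rng):
        x = rng.standard_normal(int(300 * RATE))
        rec = make_recording(x)
        onsets = np.sort(rng.uniform(1.0, 295.0, 240))
        onsets = np.round(onsets * RATE) / RATE  # sample-aligned
        ep = epoch(rec, onsets, -0.1, 0.4)
        assert ep.n_trials == 240
        for k in [0, 17, 239]:
            i0 = int(round((onsets[k] - 0.1) * RATE))
            assert np.array_equal(ep.data[k, 0], x[i0 : i0 + 200])

    def test_out_of_bounds_event_dropped_with_warning(self):
        rec = make_recording(np.zeros(1000))
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = epoch(rec, [0.01, 1.0], -0.1, 0.4)
        assert ep.n_trials == 1


class TestRejectAmplitude:
    def test_bounded_trials_all_kept(self, rng):
        data = rng.uniform(-50, 50, (10, 2, 100))
        ep = EpochSet(data, RATE, -0.1, ["a"] * 10, np.ones(10, bool))
        assert reject_amplitude(ep, 100.0).kept_mask.all()

    def test_single_spike_rejects_exactly_that_trial(self, rng):
        data = rng.uniform(-50, 50, (5, 2, 100))
        data[3, 1, 42] = 101.0
        ep = EpochSet(data, RATE, -0.1, ["a"] * 5, np.ones(5, bool))
        kept = reject_amplitude(ep, 100.0).kept_mask
        assert list(kept) == [True, True, True, False, True]

    def test_matches_bruteforce_scan(self, rng):
        data = rng.normal(0, 60, (50, 3, 80))
        ep = EpochSet(data, RATE, -0.1, ["a"] * 50, np.ones(50, bool))
        kept = reject_amplitude(ep, 100.0).kept_mask
        oracle = np.array(
            [not any(abs(v) > 100 for v in trial.ravel()) for trial in data]
        )
        assert np.array_equal(kept, oracle)

    def test_infinite_limit_is_identity(self, rng):
        data = rng.normal(0, 500, (10, 1, 50))
        ep = EpochSet(data, RATE, -0.1, ["a"] * 10, np.ones(10, bool))
        assert reject_amplitude(ep, np.inf).kept_mask.all()


class TestMorlet:
    def test_unit_sinusoid_normalization(self):
        x = sinusoid(13.5, 20)
        tf = morlet_transform(x, RATE, WaveletSpec([13.5], 7))
        mag = np.abs(tf.coefs[0])[tf.valid[0]]
        assert np.median(mag) == pytest.approx(1.0, rel=0.02)

    def test_zero_signal(self):
        tf = morlet_transform(np.zeros(4000), RATE, WaveletSpec([13.5], 7))
        assert np.allclose(tf.coefs, 0.0)

    def test_grid_peak_at_nearest_frequency_vs_fft_oracle(self):
        freqs = np.linspace(10, 100, 30)
        x = sinusoid(40.0, 10)
        tf = morlet_transform(x, RATE, WaveletSpec(freqs, 7))
        mid = tf.coefs.shape[-1] // 2
        mags = np.abs(tf.coefs[:, mid])
        assert freqs[np.argmax(mags)] == pytest.approx(
            freqs[np.argmin(np.abs(freqs - 40.0))]
        )
        # oracle: same convolution through an explicit full FFT product
        k = morlet_kernel(freqs[np.argmax(mags)], RATE, 7.0)
        n = len(x) + len(k) - 1
        full = np.fft.ifft(np.fft.fft(x, n) * np.fft.fft(k, n))
        oracle_mid = full[mid + len(k) // 2]
        assert abs(tf.coefs[np.argmax(mags), mid] - oracle_mid) < 1e-8

    def test_signal_shorter_than_wavelet_raises(self):
        with pytest.raises(ValueError, match="at least"):
            morlet_transform(np.zeros(100), RATE, WaveletSpec([10.0], 7))

    def test_phase_invariance_of_magnitude(self):
        mags = []
        for phase in (0.0, 1.1, 2.7):
            x = sinusoid(13.5, 10, phase=phase)
            tf = morlet_transform(x, RATE, WaveletSpec([13.5], 7))
            mags.append(np.median(np.abs(tf.coefs[0])[tf.valid[0]]))
        assert np.ptp(mags) < 0.02 * np.mean(mags)


class TestRejectionProperty:
    """Amplitude rejection equals the brute-force scan for any limit."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**16), limit=st.floats(1.0, 200.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_kept_mask_matches_bruteforce(self, seed, limit):
        data = np.random.default_rng(seed).normal(0, 60, (12, 2, 40))
        ep = EpochSet(data, RATE, -0.1, ["a"] * 12, np.ones(12, bool))
        kept = reject_amplitude(ep, limit).kept_mask
        oracle = np.array([np.abs(trial).max() <= limit for trial in data])
        assert np.array_equal(kept, oracle)


class TestLinearity:
    """Filters and the wavelet transform are linear operators."""

    @pytest.mark.parametrize("op_name", ["bandpass", "notch", "morlet"])
    def test_superposition(self, rng, op_name):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        a, b = 2.5, -1.3

        def op(v):
            if op_name == "bandpass":
                return bandpass(make_recording(v), 1.0, 45.0).data[0]
            if op_name == "notch":
                return notch(make_recording(v), 60.0).data[0]
            return morlet_transform(v, RATE, WaveletSpec([13.5, 40.0], 7)).coefs

        lhs = op(a * x + b * y)
        rhs = a * op(x) + b * op(y)
        assert np.allclose(lhs, rhs, atol=1e-8)
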