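"""LFP preprocessing, envelope extraction, and the two event detectors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pupephys.core import EpochSet, SampledSignal
from pupephys.signal import (
    DetectorParams,
    design_band_fir,
    detect_spindle_bursts,
    detect_spindles_in_lfp,
    envelope_threshold,
    estimate_movement_baseline,
    extract_movement_periods,
    preprocess_lfp,
    spindle_envelope,
)
from pupephys.simulate import SimParams, SpindleSpec, generate_lfp, generate_state_sequence


def _sine(freq, dur=10.0, rate=1000.0, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return SampledSignal("lfp", amp * np.sin(2 * np.pi * freq * t), rate)


class TestPreprocess:
    def test_constant_signal_unchanged(self):
        sig = SampledSignal("lfp", np.full(4000, 3.7), 2000.0)
        out = preprocess_lfp(sig)
        assert out.rate_hz == 1000.0
        np.testing.assert_allclose(out.samples[50:-50], 3.7, rtol=1e-6)

    def test_downsample_halves_length(self):
        sig = SampledSignal("lfp", np.random.default_rng(0).normal(size=4000), 2000.0)
        out = preprocess_lfp(sig)
        assert abs(out.n - 2000) <= 1

    def test_no_upsampling(self):
        sig = SampledSignal("lfp", np.zeros(100), 500.0)
        with pytest.raises(ValueError, match="not upsampling"):
            preprocess_lfp(sig, target_rate_hz=1000.0)

    def test_smoothing_reduces_variance(self, rng):
        """Moving-average smoothing of white noise reduces variance, and
        matches a brute-force moving average."""
        x = rng.normal(size=2000)
        sig = SampledSignal("lfp", x, 1000.0)
        out = preprocess_lfp(sig, target_rate_hz=1000.0, smooth_s=0.005)
        assert out.samples.var() < sig.samples.var()
        w = 5
        brute = np.convolve(x, np.ones(w) / w, mode="same")
        np.testing.assert_allclose(out.samples, brute, rtol=1e-9)


class TestEnvelope:
    def test_passband_sinusoid_envelope_equals_amplitude(self):
        env = spindle_envelope(_sine(15.0, amp=2.5))
        mid = env.samples[3000:-3000]
        np.testing.assert_allclose(mid, 2.5, rtol=0.02)

    def test_stopband_attenuated_60db(self):
        env = spindle_envelope(_sine(40.0, amp=1.0))
        assert env.samples[3000:-3000].max() <= 10 ** (-60 / 20) * 1.5

    def test_am_carrier_envelope_tracks_modulator(self):
        """Known-modulator oracle: a 15 Hz carrier with a slow raised-cosine
        modulator yields an envelope within 5% RMS of the modulator."""
        rate, dur = 1000.0, 20.0
        t = np.arange(int(dur * rate)) / rate
        modulator = 1.0 + 0.5 * np.cos(2 * np.pi * 0.5 * t)
        sig = SampledSignal("lfp", modulator * np.sin(2 * np.pi * 15.0 * t), rate)
        env = spindle_envelope(sig)
        sl = slice(4000, -4000)
        rms_err = np.sqrt(np.mean((env.samples[sl] - modulator[sl]) ** 2))
        assert rms_err / np.sqrt(np.mean(modulator[sl] ** 2)) < 0.05

    def test_rate_too_low_errors(self):
        with pytest.raises(ValueError, match="too low"):
            spindle_envelope(_sine(15.0, rate=30.0))

    def test_filter_meets_spec_at_band_edges(self):
        from scipy.signal import freqz
        taps = design_band_fir(1000.0, DetectorParams())
        w, h = freqz(taps, worN=8192, fs=1000.0)
        gain_db = 20 * np.log10(np.abs(h) + 1e-12)
        assert gain_db[(w > 12) & (w < 18)].min() > -1.0
        assert gain_db[(w < 8.5) | (w > 21.5)].max() < -60.0


class TestSpindleDetection:
    def test_flat_envelope_no_bursts(self):
        env = SampledSignal("spindle_envelope", np.full(5000, 1.0), 1000.0)
        assert detect_spindle_bursts(env) == []

    def test_single_excursion_detected_with_accurate_onset(self):
        rng = np.random.default_rng(2)
        env_vals = np.abs(rng.normal(1.0, 0.1, 10000))
        env_vals[4000:4200] += 5 * 0.1 * 10  # 200 ms excursion, 5 SD above
        env = SampledSignal("spindle_envelope", env_vals, 1000.0)
        bursts = detect_spindle_bursts(env)
        assert len(bursts) == 1
        assert bursts[0].onset_s == pytest.approx(4.0, abs=0.025)
        assert bursts[0].duration_s >= 0.1

    def test_80ms_excursion_rejected_150ms_accepted(self):
        """The minimum-duration rule: same amplitude, only the 150 ms
        excursion qualifies."""
        base = np.full(20000, 1.0)
        base[5000:5080] = 10.0  # 80 ms
        base[12000:12150] = 10.0  # 150 ms
        noise = np.random.default_rng(3).normal(0, 0.05, base.size)
        env = SampledSignal("spindle_envelope", np.abs(base + noise), 1000.0)
        bursts = detect_spindle_bursts(env)
        assert len(bursts) == 1
        assert bursts[0].onset_s == pytest.approx(12.0, abs=0.01)

    def test_short_baseline_errors(self):
        env = SampledSignal("spindle_envelope", np.ones(100), 1000.0)
        with pytest.raises(ValueError, match="baseline"):
            detect_spindle_bursts(env)

    def test_explicit_baseline_epochs_change_threshold(self):
        env_vals = np.concatenate([np.full(5000, 1.0), np.full(5000, 10.0)])
        env = SampledSignal("spindle_envelope", env_vals, 1000.0)
        thr_first = envelope_threshold(env, EpochSet([(0, 5, "pre")]))
        thr_whole = envelope_threshold(env)
        assert thr_first < thr_whole

    def test_threshold_monotonicity(self):
        """Raising the SD multiplier or the minimum duration never
        increases the burst count."""
        p = SimParams(seed=21, duration_s=600.0)
        states = generate_state_sequence(p)
        lfp, _ = generate_lfp(states, {}, p)
        env = spindle_envelope(lfp)
        counts_k = [
            len(detect_spindle_bursts(env, params=DetectorParams(threshold_k=k)))
            for k in (1.0, 2.0, 3.0, 5.0)
        ]
        assert counts_k == sorted(counts_k, reverse=True)
        counts_d = [
            len(detect_spindle_bursts(env, params=DetectorParams(min_duration_s=d)))
            for d in (0.05, 0.1, 0.2, 0.4)
        ]
        assert counts_d == sorted(counts_d, reverse=True)

    def test_recovery_on_generator_truth(self):
        """On embedded bursts >= 5x background SD the detector recalls nearly
        all of them with accurate onsets and few false discoveries."""
        p = SimParams(seed=22, duration_s=600.0)
        states = generate_state_sequence(p)
        lfp, truth = generate_lfp(states, {}, p)
        bursts = detect_spindles_in_lfp(lfp)
        onsets = np.array([b.onset_s for b in bursts])
        errs = []
        hits = 0
        for a, b, _ in truth:
            overlap = [d for d in bursts if d.onset_s < b and d.offset_s > a]
            if overlap:
                hits += 1
                errs.append(min(abs(d.onset_s - a) for d in overlap))
        assert hits / len(truth) >= 0.9
        assert np.mean(errs) <= 0.030
        matched = sum(
            1 for d in bursts if any(d.onset_s < b and d.offset_s > a
                                     for a, b, _ in truth)
        )
        assert (len(bursts) - matched) / max(len(bursts), 1) <= 0.1


class TestMovementPeriods:
    def _trace(self, values, rate=100.0):
        return SampledSignal("movement", np.asarray(values, dtype=float), rate)

    def test_300ms_supra_threshold_is_one_period(self):
        x = np.ones(1000)
        x[500:530] = 4.0  # 300 ms at 4x baseline
        eps = extract_movement_periods(self._trace(x), baseline_level=1.0)
        assert eps.intervals_for("movement") == [(5.0, 5.3)]

    def test_200ms_supra_threshold_rejected(self):
        x = np.ones(1000)
        x[500:520] = 4.0  # 200 ms only
        eps = extract_movement_periods(self._trace(x), baseline_level=1.0)
        assert eps.intervals_for("movement") == []

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError):
            extract_movement_periods(self._trace(np.ones(1000)), baseline_level=0.0)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(4)
        x = np.abs(rng.normal(1, 0.3, 5000))
        eps = extract_movement_periods(self._trace(x), baseline_level=1.0)
        assert eps.duration() == pytest.approx(50.0)
        assert eps.span() == (0.0, 50.0)

    @staticmethod
    def brute_force_periods(x, thr, min_n):
        """Run-length oracle: pure-python scan."""
        periods = []
        start = None
        for i, v in enumerate(x):
            if v > thr and start is None:
                start = i
            elif v <= thr and start is not None:
                if i - start >= min_n:
                    periods.append((start, i))
                start = None
        if start is not None and len(x) - start >= min_n:
            periods.append((start, len(x)))
        return periods

    @given(st.integers(0, 2**31 - 1))
    def test_equals_run_length_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.choice([0.5, 1.0, 4.0, 6.0], size=600, p=[0.3, 0.4, 0.2, 0.1])
        trace = self._trace(x)
        eps = extract_movement_periods(trace, baseline_level=1.0)
        got = [
            (round(a * 100), round(b * 100)) for a, b in eps.intervals_for("movement")
        ]
        assert got == self.brute_force_periods(x, 3.0, 25)

    def test_baseline_estimator_on_quiet_floor(self):
        rng = np.random.default_rng(5)
        x = np.full(10000, 2.0) + rng.normal(0, 0.01, 10000)
        x[::50] = 8.0  # sparse movement spikes
        level = estimate_movement_baseline(SampledSignal("movement", x, 100.0))
        assert level == pytest.approx(2.0, abs=0.05)
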