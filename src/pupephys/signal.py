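"""LFP preprocessing, spindle-burst detection, and movement-period extraction.

Spindle bursts are brief 10–20 Hz thalamocortical oscillations prominent in
infant cortex. They are detected here by band-passing the LFP with a
zero-phase FIR filter (60 dB stopband attenuation, 1 Hz transition band),
taking the analytic-signal (Hilbert) amplitude, and finding maximal runs of
at least 100 ms during which the envelope exceeds the baseline median plus
``k`` baseline standard deviations (default k = 2).

Movement periods are maximal runs of the video-derived pixel-change trace
exceeding 3x a baseline level for at least 250 ms; the period ends as soon
as the trace falls back below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EpochSet, SampledSignal, restrict_signal


@dataclass
class DetectorParams:
    """Filter and threshold settings for both event detectors."""

    band_low_hz: float = 10.0
    band_high_hz: float = 20.0
    stopband_atten_db: float = 60.0
    transition_hz: float = 1.0
    min_duration_s: float = 0.100
    threshold_k: float = 2.0  # SD multiplier over the baseline median
    movement_threshold_mult: float = 3.0
    movement_min_duration_s: float = 0.250

    def __post_init__(self) -> None:
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        if self.min_duration_s <= 0 or self.movement_min_duration_s <= 0:
            raise ValueError("minimum durations must be positive")


@dataclass
class SpindleBurst:
    """One detected oscillatory event."""

    onset_s: float
    offset_s: float
    peak_envelope: float
    area: str = ""

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def preprocess_lfp(
    raw: SampledSignal, target_rate_hz: float = 1000.0, smooth_s: float = 0.005
) -> SampledSignal:
    """Anti-aliased downsample to ``target_rate_hz`` then moving-average
    smoothing over ``smooth_s``.

    Upsampling is refused: the raw rate must be at least the target rate.
    """
    if raw.rate_hz < target_rate_hz:
        raise ValueError(
            f"raw rate {raw.rate_hz} Hz below target {target_rate_hz} Hz; not upsampling"
        )
    if raw.rate_hz == target_rate_hz:
        x = raw.samples
    else:
        from fractions import Fraction

        frac = Fraction(target_rate_hz / raw.rate_hz).limit_denominator(1000)
        x = sps.resample_poly(raw.samples, frac.numerator, frac.denominator)
    win = max(1, int(round(smooth_s * target_rate_hz)))
    if win > 1:
        kernel = np.ones(win) / win
        x = np.convolve(x, kernel, mode="same")
    return SampledSignal(raw.label, x, target_rate_hz, raw.t0_s)


def design_band_fir(rate_hz: float, params: DetectorParams) -> np.ndarray:
    """Linear-phase FIR band-pass meeting the stopband/transition spec."""
    nyq = rate_hz / 2.0
    width = params.transition_hz / nyq
    numtaps, beta = sps.kaiserord(params.stopband_atten_db + 5.0, width)
    numtaps |= 1  # odd length -> integer group delay, exact zero-phase
    return sps.firwin(
        numtaps,
        [params.band_low_hz, params.band_high_hz],
        window=("kaiser", beta),
        pass_zero=False,
        fs=rate_hz,
    )


def spindle_envelope(
    lfp: SampledSignal, params: DetectorParams | None = None
) -> SampledSignal:
    """Zero-phase 10–20 Hz band-pass followed by Hilbert amplitude.

    The symmetric FIR is applied centered (via FFT convolution), so the
    output has no phase distortion, the same length and the same rate as
    the input.
    """
    params = params or DetectorParams()
    if lfp.rate_hz < 2 * params.band_high_hz:
        raise ValueError(
            f"rate {lfp.rate_hz} Hz too low for a {params.band_high_hz} Hz passband"
        )
    taps = design_band_fir(lfp.rate_hz, params)
    filtered = sps.fftconvolve(lfp.samples, taps, mode="same")
    from scipy.fft import next_fast_len

    n = filtered.size
    m = next_fast_len(n)
    analytic = sps.hilbert(filtered, N=m)[:n]
    env = np.abs(analytic)
    return SampledSignal("spindle_envelope", env, lfp.rate_hz, lfp.t0_s)


def baseline_stats(
    envelope: SampledSignal,
    baseline: EpochSet | None = None,
    min_baseline_s: float = 1.0,
) -> tuple[float, float]:
    """(median, SD) of the envelope over the baseline segment.

    ``baseline`` defaults to the whole record; an explicit epoch set (e.g.
    a pre-injection period) restricts the statistics to that segment.
    """
    if baseline is None:
        base = envelope.samples
        dur = envelope.duration_s
    else:
        base, dur = restrict_signal(envelope, baseline)
    if dur < min_baseline_s:
        raise ValueError(f"baseline of {dur:.3f} s too short for a stable threshold")
    return float(np.median(base)), float(np.std(base))


def envelope_threshold(
    envelope: SampledSignal,
    baseline: EpochSet | None = None,
    k: float = 2.0,
    min_baseline_s: float = 1.0,
) -> float:
    """Detection threshold: baseline median + k x baseline SD of the envelope."""
    med, sd = baseline_stats(envelope, baseline, min_baseline_s)
    return med + k * sd


def _supra_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def detect_spindle_bursts(
    envelope: SampledSignal,
    baseline: EpochSet | None = None,
    params: DetectorParams | None = None,
    area: str = "",
    refine_onset: bool = True,
    max_refine_s: float = 0.200,
) -> list[SpindleBurst]:
    """Maximal supra-threshold envelope runs lasting at least 100 ms.

    "Exceeds" is strict (envelope > threshold), so a constant envelope —
    where the threshold collapses onto the median — yields no bursts.
    A run qualifies if it stays above threshold for at least
    ``min_duration_s``; its offset is the first sub-threshold sample after
    the run (half-open). With ``refine_onset`` (default), the reported
    onset is refined by a dual-threshold rule: walk back from the
    detection crossing to the last sample at or below a lower threshold
    (median + k/2 x SD), then linearly extrapolate the rising flank down
    to the baseline median. This recovers the ramp a hard threshold clips
    off a gradually waxing oscillation. Bursts separated by any
    sub-threshold gap remain distinct. Returned sorted, non-overlapping.
    """
    params = params or DetectorParams()
    if not np.all(np.isfinite(envelope.samples)):
        raise ValueError("envelope contains non-finite samples")
    med, sd = baseline_stats(envelope, baseline)
    thr = med + params.threshold_k * sd
    low = med + 0.5 * params.threshold_k * sd
    x = envelope.samples
    min_n = int(round(params.min_duration_s * envelope.rate_hz))
    max_back = int(round(max_refine_s * envelope.rate_hz))
    bursts = []
    for i0, i1 in _supra_runs(x > thr):
        if i1 - i0 < min_n:
            continue
        onset_i = float(i0)
        if refine_onset:
            lo = max(0, i0 - max_back)
            below = np.flatnonzero(x[lo:i0] <= low)
            i_low = lo + below[-1] + 1 if below.size else lo
            onset_i = float(i_low)
            if i0 > i_low:  # extrapolate the flank down to the median
                slope = (x[i0] - x[i_low]) / (i0 - i_low)
                if slope > 0:
                    onset_i = i_low - min((x[i_low] - med) / slope, max_back / 2)
        bursts.append(
            SpindleBurst(
                onset_s=envelope.t0_s + onset_i / envelope.rate_hz,
                offset_s=envelope.t0_s + i1 / envelope.rate_hz,
                peak_envelope=float(x[i0:i1].max()),
                area=area,
            )
        )
    # onset refinement can only move onsets earlier; keep bursts disjoint
    for j in range(1, len(bursts)):
        if bursts[j].onset_s < bursts[j - 1].offset_s:
            bursts[j].onset_s = bursts[j - 1].offset_s
    return bursts


def detect_spindles_in_lfp(
    lfp: SampledSignal,
    baseline: EpochSet | None = None,
    params: DetectorParams | None = None,
    area: str = "",
) -> list[SpindleBurst]:
    """Convenience chain: envelope then threshold detection."""
    env = spindle_envelope(lfp, params)
    return detect_spindle_bursts(env, baseline, params, area=area)


def estimate_movement_baseline(movement: SampledSignal, quantile: float = 0.10) -> float:
    """Baseline level of a pixel-change trace: central value (median) of the
    samples at or below the given low quantile — a robust stand-in for the
    mode of the quiet-floor distribution."""
    x = movement.samples
    cut = np.quantile(x, quantile)
    low = x[x <= cut]
    return float(np.median(low))


def extract_movement_periods(
    movement: SampledSignal,
    baseline_level: float | None = None,
    params: DetectorParams | None = None,
) -> EpochSet:
    """Movement periods from the whole-body pixel-change trace.

    A period starts when the trace exceeds ``movement_threshold_mult`` x
    baseline (default 3x) and persists for at least
    ``movement_min_duration_s`` (default 250 ms); it ends at the first
    sample back below threshold. The complement is labeled ``no_movement``,
    so the two labels exactly partition the analyzed span.
    """
    params = params or DetectorParams()
    if baseline_level is None:
        baseline_level = estimate_movement_baseline(movement)
    if baseline_level <= 0:
        raise ValueError(f"baseline level must be positive, got {baseline_level}")
    thr = params.movement_threshold_mult * baseline_level
    min_n = int(round(params.movement_min_duration_s * movement.rate_hz))
    rate, t0 = movement.rate_hz, movement.t0_s
    n = movement.n
    intervals: list[tuple[float, float, str]] = []
    prev = 0
    for i0, i1 in _supra_runs(movement.samples > thr):
        if i1 - i0 < min_n:
            continue
        if i0 > prev:
            intervals.append((t0 + prev / rate, t0 + i0 / rate, "no_movement"))
        intervals.append((t0 + i0 / rate, t0 + i1 / rate, "movement"))
        prev = i1
    if prev < n:
        intervals.append((t0 + prev / rate, t0 + n / rate, "no_movement"))
    return EpochSet(intervals)
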