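"""Synthetic session generator with ground-truth sidecars.

Emulates the statistical structure of neonatal rat cortical recordings so
that every analysis stage can be verified against known truth:

* sleep–wake cycling with an active-sleep-dominant time budget (alternating
  renewal process, exponential dwell times),
* myoclonic twitches confined to active-sleep atonia and wake movements
  confined to wake, each adding a supra-threshold bump to the video-derived
  movement trace,
* a forelimb-stimulation block appended after the free-behavior period,
* 10–20 Hz spindle bursts (Hann-windowed sinusoids) riding on 1/f-like
  background LFP, with state-dependent rates and an optional event-coupled
  fraction,
* inhomogeneous-Poisson spike trains with state-dependent baselines, causal
  sensory-response kernels, a discontinuous (P8-like) on/off gate or a
  continuous (P12-like) regime, and an anesthetized burst-suppression regime
  with inter-burst silences of at least 10 s.

All randomness derives from a single master seed via named substreams, so a
fixed seed yields a bit-identical session and ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import EpochSet, EventSeries, SampledSignal, Session, SpikeTrain

logger = logging.getLogger(__name__)

# substream indices for component-independent RNGs
_STREAMS = {"states": 1, "behavior": 2, "lfp": 3, "spikes": 4, "urethane": 5}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[component]])


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class UnitSpec:
    """One simulated unit: state-dependent baseline plus a causal response
    kernel (boxcar of added rate after each sensory event)."""

    unit_id: str
    area: str = "M1"
    rate_as_hz: float = 4.0
    rate_wake_hz: float = 2.0
    rate_quiescence_hz: float = 1.0
    responsive: bool = False
    response_latency_s: float = 0.03
    response_width_s: float = 0.10
    response_gain: float = 3.0  # added rate = gain x AS baseline during kernel
    responds_to: tuple[str, ...] = ("twitch", "wake_movement", "stimulation")


@dataclass
class SpindleSpec:
    """Spindle-burst placement and waveform parameters."""

    rate_as_per_min: float = 4.0
    rate_wake_per_min: float = 1.0
    freq_hz: float = 15.0
    duration_range_s: tuple[float, float] = (0.15, 0.40)
    amplitude_mult: float = 5.0  # peak amplitude as multiple of background SD
    coupled_fraction: float = 0.0  # fraction of bursts placed 0-500 ms after events
    coupled_delay_range_s: tuple[float, float] = (0.05, 0.45)

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if lo < 0.1:
            raise ValueError("spindle durations must be at least 0.1 s")
        if not lo <= hi:
            raise ValueError("invalid duration range")


@dataclass
class SimParams:
    """Full configuration of one synthetic session.

    Defaults describe a P8-like pup: active sleep 57.7% / wake 30.9% /
    quiescence 11.4% of the free-behavior period, discontinuous cortical
    activity, spindle bursts concentrated in active sleep, and 50 forelimb
    stimulations delivered 2–3 s apart after the free period.
    """

    seed: int = 0
    duration_s: float = 600.0  # free-behavior period
    regime: str = "p8_discontinuous"  # | "p12_continuous" | "urethane"
    state_dwell_means_s: dict = field(
        default_factory=lambda: {"AS": 57.7, "wake": 30.9, "quiescence": 11.4}
    )
    include_quiescence: bool = True
    # behavior
    twitch_rate_hz: float = 0.20
    wake_move_rate_hz: float = 0.15
    n_stimulations: int = 50
    stim_gap_range_s: tuple[float, float] = (2.0, 3.0)
    stim_lead_in_s: float = 5.0
    frame_rate_hz: float = 100.0
    emg_rate_hz: float = 500.0
    movement_baseline: float = 1.0
    movement_noise_sd: float = 0.05
    twitch_bump_mult: float = 5.0  # bump height as multiple of baseline
    twitch_bump_dur_s: float = 0.30
    wake_move_bump_mult: float = 5.0
    wake_move_bump_dur_s: float = 0.80
    # LFP
    lfp_rate_hz: float = 1000.0
    lfp_noise_sd: float = 1.0
    spindles: SpindleSpec = field(default_factory=SpindleSpec)
    # units
    units: list[UnitSpec] = field(default_factory=list)
    # discontinuous (P8) gating: independent on/off telegraph on the baseline
    gate_on_mean_s: float = 3.0
    gate_off_mean_s: float = 2.0
    gate_off_factor: float = 0.05
    # pre/post experiment (burst suppression)
    drug: str = "urethane"  # | "saline" (control: post period stays P8-like)
    pre_duration_s: float = 1800.0
    post_duration_s: float = 1800.0
    injection_gap_s: float = 10.0
    burst_rate_hz: float = 8.0  # within-burst unit rate
    burst_duration_s: float = 0.5
    silence_min_s: float = 10.0
    silence_extra_mean_s: float = 8.0
    movement_suppression: float = 0.87  # fraction of movement removed post
    spindle_suppression: float = 0.90

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for k, v in self.state_dwell_means_s.items():
            if v <= 0:
                raise ValueError(f"dwell mean for {k} must be positive")
        if not self.units:
            self.units = default_units()


def default_units(
    n_per_area: int = 6, areas: tuple[str, ...] = ("M1", "M2"), responsive_frac: float = 0.5
) -> list[UnitSpec]:
    """Default population: ``n_per_area`` units per area, first half responsive."""
    units = []
    for area in areas:
        for i in range(n_per_area):
            units.append(
                UnitSpec(
                    unit_id=f"{area}_u{i:02d}",
                    area=area,
                    responsive=i < int(round(responsive_frac * n_per_area)),
                )
            )
    return units


@dataclass
class GroundTruth:
    """Sidecar recording what was injected into a synthetic session."""

    true_spindles: list  # (onset_s, offset_s, area)
    true_responsive_units: list
    true_rates: dict  # unit_id -> {state: rate_hz}
    true_movement_periods: EpochSet
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "true_spindles": [[a, b, lab] for a, b, lab in self.true_spindles],
            "true_responsive_units": sorted(self.true_responsive_units),
            "true_rates": self.true_rates,
            "true_movement_periods": list(self.true_movement_periods.intervals),
            "extras": self.extras,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# State sequence
# ---------------------------------------------------------------------------


def generate_state_sequence(params: SimParams) -> EpochSet:
    """Alternating renewal state sequence covering ``[0, duration_s)``.

    States cycle AS -> wake (-> quiescence) with exponential dwell times,
    so expected occupancy fractions equal the dwell means normalized by
    their sum. The last epoch is truncated at the session end.
    """
    rng = _rng(params.seed, "states")
    order = ["AS", "wake"] + (["quiescence"] if params.include_quiescence else [])
    means = params.state_dwell_means_s
    intervals = []
    t, i = 0.0, 0
    while t < params.duration_s:
        lab = order[i % len(order)]
        dwell = rng.exponential(means[lab])
        end = min(t + dwell, params.duration_s)
        intervals.append((t, end, lab))
        t = end
        i += 1
    if len(intervals) <= len(order):
        logger.warning(
            "session duration %.1f s shorter than one full state cycle", params.duration_s
        )
    return EpochSet(intervals)


# ---------------------------------------------------------------------------
# Behavior: movement trace, EMG, event series
# ---------------------------------------------------------------------------


def _poisson_onsets(
    rng: np.random.Generator, intervals, rate_hz: float, margin_s: float = 0.0
) -> np.ndarray:
    """Homogeneous Poisson onsets within intervals, keeping ``margin_s`` clear
    of each interval's end so an event's bump fits inside it."""
    onsets = []
    for a, b in intervals:
        usable = b - a - margin_s
        if usable <= 0 or rate_hz <= 0:
            continue
        n = rng.poisson(rate_hz * usable)
        onsets.extend(a + rng.uniform(0, usable, size=n))
    return np.sort(np.asarray(onsets))


def _add_bumps(samples, rate_hz, t0, onsets, height, dur_s) -> list[tuple[float, float]]:
    """Add rectangular bumps in place; return their (start, end) intervals."""
    spans = []
    for t in onsets:
        i0 = int(np.ceil((t - t0) * rate_hz - 1e-9))
        i1 = int(np.ceil((t + dur_s - t0) * rate_hz - 1e-9))
        i0, i1 = max(0, i0), min(len(samples), i1)
        if i1 > i0:
            samples[i0:i1] += height
            spans.append((t, t + dur_s))
    return spans


def _merge_spans(spans) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def stimulation_block(params: SimParams, start_s: float, rng) -> np.ndarray:
    """Onsets of the stimulation protocol: exactly ``n_stimulations`` events
    with inter-stimulation gaps drawn uniformly from ``stim_gap_range_s``."""
    gaps = rng.uniform(*params.stim_gap_range_s, size=params.n_stimulations)
    return start_s + params.stim_lead_in_s + np.cumsum(gaps)


def generate_behavior(
    states: EpochSet, params: SimParams
) -> tuple[SampledSignal, SampledSignal, dict[str, EventSeries], EpochSet]:
    """Movement trace, nuchal EMG, event series, and true movement periods.

    Twitches occur only inside active sleep, wake movements only inside
    wake; each adds a rectangular supra-threshold bump (default 5x the
    baseline level) to the movement trace. The EMG has high tone in wake,
    atonia in AS with brief spikes at twitches. The stimulation block is
    appended after the free-behavior period.
    """
    rng = _rng(params.seed, "behavior")
    stim = stimulation_block(params, params.duration_s, rng)
    total = stim[-1] + params.stim_lead_in_s if stim.size else params.duration_s

    fr = params.frame_rate_hz
    n = int(round(total * fr))
    movement = params.movement_baseline + rng.normal(0, params.movement_noise_sd, n)

    twitches = _poisson_onsets(
        rng, states.intervals_for("AS"), params.twitch_rate_hz, params.twitch_bump_dur_s
    )
    wakemoves = _poisson_onsets(
        rng, states.intervals_for("wake"), params.wake_move_rate_hz, params.wake_move_bump_dur_s
    )
    spans = _add_bumps(
        movement, fr, 0.0, twitches,
        params.twitch_bump_mult * params.movement_baseline, params.twitch_bump_dur_s,
    )
    spans += _add_bumps(
        movement, fr, 0.0, wakemoves,
        params.wake_move_bump_mult * params.movement_baseline, params.wake_move_bump_dur_s,
    )
    true_moves = _merge_spans(spans)
    move_eps = []
    prev = 0.0
    for a, b in true_moves:
        if a > prev:
            move_eps.append((prev, a, "no_movement"))
        move_eps.append((a, min(b, total), "movement"))
        prev = min(b, total)
    if prev < total:
        move_eps.append((prev, total, "no_movement"))

    # EMG: tone by state, atonia in AS with twitch spikes
    er = params.emg_rate_hz
    ne = int(round(total * er))
    emg = rng.normal(0, 0.3, ne)  # default (quiescence / stim period) tone
    t_emg = np.arange(ne) / er
    for a, b, lab in states.intervals:
        sd = {"AS": 0.1, "wake": 1.0, "quiescence": 0.3}.get(lab, 0.3)
        i0, i1 = int(a * er), min(ne, int(b * er))
        emg[i0:i1] = rng.normal(0, sd, max(0, i1 - i0))
    for t in twitches:
        i0, i1 = int(t * er), min(ne, int((t + 0.05) * er))
        emg[i0:i1] += rng.normal(0, 2.0, max(0, i1 - i0))
    del t_emg

    events = {
        "twitch": EventSeries("twitch", twitches),
        "wake_movement": EventSeries("wake_movement", wakemoves),
        "stimulation": EventSeries("stimulation", stim),
    }
    return (
        SampledSignal("movement", movement, fr, 0.0),
        SampledSignal("emg", emg, er, 0.0),
        events,
        EpochSet(move_eps),
    )


# ---------------------------------------------------------------------------
# LFP with embedded spindle bursts
# ---------------------------------------------------------------------------


def _pink_noise(rng, n: int, rate_hz: float, sd: float) -> np.ndarray:
    """Gaussian noise with 1/f-like amplitude spectrum (flat below 1 Hz),
    scaled to standard deviation ``sd``."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec * shaping, n)
    return x * (sd / x.std())


def generate_lfp(
    states: EpochSet,
    events: dict[str, EventSeries],
    params: SimParams,
    total_duration_s: float | None = None,
    area: str = "M1",
) -> tuple[SampledSignal, list[tuple[float, float, str]]]:
    """Background LFP plus Hann-windowed 10–20 Hz bursts at recorded times.

    Burst onsets follow state-dependent Poisson rates; a configurable
    fraction is instead placed 0–500 ms after a sensory event to create
    genuine spindle–event coupling. Overlapping bursts are merged in the
    ground truth (and logged). With ``amplitude_mult == 0`` the output is
    pure background and the truth list is empty.
    """
    rng = _rng(params.seed, "lfp")
    sp = params.spindles
    total = total_duration_s if total_duration_s is not None else states.span()[1]
    rate = params.lfp_rate_hz
    n = int(round(total * rate))
    lfp = _pink_noise(rng, n, rate, params.lfp_noise_sd)

    if sp.amplitude_mult == 0:
        return SampledSignal("lfp", lfp, rate, 0.0), []

    dur_lo, dur_hi = sp.duration_range_s
    bursts: list[tuple[float, float]] = []
    per_state = {"AS": sp.rate_as_per_min / 60.0, "wake": sp.rate_wake_per_min / 60.0}
    for a, b, lab in states.intervals:
        r = per_state.get(lab, 0.0)
        if r <= 0:
            continue
        for t in _poisson_onsets(rng, [(a, b)], r, dur_hi):
            bursts.append((t, t + rng.uniform(dur_lo, dur_hi)))

    if sp.coupled_fraction > 0:
        all_ev = np.sort(np.concatenate([e.onsets_s for e in events.values()]))
        if all_ev.size:
            n_extra = int(round(sp.coupled_fraction / (1 - sp.coupled_fraction) * len(bursts)))
            chosen = rng.choice(all_ev, size=n_extra, replace=True)
            delays = rng.uniform(*sp.coupled_delay_range_s, size=n_extra)
            for t in chosen + delays:
                if t + dur_hi < total:
                    bursts.append((t, t + rng.uniform(dur_lo, dur_hi)))

    merged = _merge_spans(bursts)
    if len(merged) < len(bursts):
        logger.info("merged %d overlapping bursts", len(bursts) - len(merged))

    amp = sp.amplitude_mult * params.lfp_noise_sd
    truth = []
    for a, b in merged:
        i0, i1 = int(round(a * rate)), min(n, int(round(b * rate)))
        if i1 - i0 < 2:
            continue
        m = i1 - i0
        tt = np.arange(m) / rate
        phase = rng.uniform(0, 2 * np.pi)
        lfp[i0:i1] += amp * np.hanning(m) * np.sin(2 * np.pi * sp.freq_hz * tt + phase)
        truth.append((a, b, area))
    return SampledSignal("lfp", lfp, rate, 0.0), truth


def embed_spindle_fixture(
    seed: int,
    duration_s: float = 600.0,
    n_bursts: int = 50,
    burst_duration_range_s: tuple[float, float] = (0.15, 0.40),
    amplitude_mult: float = 5.0,
    freq_hz: float = 15.0,
    rate_hz: float = 1000.0,
    noise_sd: float = 1.0,
    min_gap_s: float = 2.0,
) -> tuple[SampledSignal, list[tuple[float, float]]]:
    """Detector-validation fixture: exactly ``n_bursts`` Hann-windowed
    bursts at known times on 1/f-like background.

    Burst onsets are stratified across the record with uniform jitter so
    bursts never overlap; durations are drawn from
    ``burst_duration_range_s`` (which, unlike the session generator, may
    deliberately include sub-100 ms values to probe the duration rule).
    Returns the signal and the true (onset, offset) list.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    n = int(round(duration_s * rate_hz))
    lfp = _pink_noise(rng, n, rate_hz, noise_sd)
    dur_lo, dur_hi = burst_duration_range_s
    slot = duration_s / n_bursts
    if slot < dur_hi + min_gap_s:
        raise ValueError("too many bursts for the requested duration")
    truth = []
    amp = amplitude_mult * noise_sd
    for i in range(n_bursts):
        dur = rng.uniform(dur_lo, dur_hi)
        onset = i * slot + rng.uniform(0.5, slot - dur - 0.5)
        i0, i1 = int(round(onset * rate_hz)), int(round((onset + dur) * rate_hz))
        m = i1 - i0
        tt = np.arange(m) / rate_hz
        phase = rng.uniform(0, 2 * np.pi)
        lfp[i0:i1] += amp * np.hanning(m) * np.sin(2 * np.pi * freq_hz * tt + phase)
        truth.append((onset, onset + dur))
    return SampledSignal("lfp", lfp, rate_hz, 0.0), truth


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


def _state_rate_vector(unit: UnitSpec, states: EpochSet, edges: np.ndarray) -> np.ndarray:
    """Baseline rate per time bin from state occupancy (bin left edges)."""
    by_state = {
        "AS": unit.rate_as_hz,
        "wake": unit.rate_wake_hz,
        "quiescence": unit.rate_quiescence_hz,
    }
    # outside scored states (stimulation block): wake-like baseline
    rates = np.full(edges.size, unit.rate_wake_hz)
    for a, b, lab in states.intervals:
        i0 = np.searchsorted(edges, a, "left")
        i1 = np.searchsorted(edges, b, "left")
        rates[i0:i1] = by_state.get(lab, unit.rate_wake_hz)
    return rates


def _gate_vector(rng, n_bins: int, dt: float, params: SimParams) -> np.ndarray:
    """On/off telegraph multiplier emulating discontinuous (P8) activity."""
    gate = np.ones(n_bins)
    t, on = 0.0, True
    while t < n_bins * dt:
        dwell = rng.exponential(params.gate_on_mean_s if on else params.gate_off_mean_s)
        if not on:
            i0, i1 = int(t / dt), min(n_bins, int((t + dwell) / dt))
            gate[i0:i1] = params.gate_off_factor
        t += dwell
        on = not on
    return gate


def _sample_inhomogeneous(rng, rate_per_bin: np.ndarray, dt: float) -> np.ndarray:
    """Spike times from per-bin Poisson counts, uniform within the bin."""
    counts = rng.poisson(rate_per_bin * dt)
    idx = np.repeat(np.arange(counts.size), counts)
    times = (idx + rng.uniform(0, 1, idx.size)) * dt
    times = np.sort(times)
    if times.size > 1:  # enforce strict ascent (ties are measure-zero but cheap to guard)
        keep = np.concatenate([[True], np.diff(times) > 0])
        times = times[keep]
    return times


def generate_spikes(
    states: EpochSet,
    events: dict[str, EventSeries],
    params: SimParams,
    total_duration_s: float | None = None,
    dt: float = 0.001,
) -> tuple[list[SpikeTrain], dict]:
    """Inhomogeneous-Poisson spike trains for every configured unit.

    Baseline rate follows the behavioral state; responsive units add a
    causal boxcar kernel (``gain x AS baseline`` extra rate over
    ``[latency, latency + width)``) after each event they respond to. The
    ``p8_discontinuous`` regime multiplies the baseline by an independent
    on/off telegraph gate; ``urethane`` replaces baselines with shared
    population bursts separated by silences of at least ``silence_min_s``.
    """
    rng = _rng(params.seed, "spikes")
    total = total_duration_s if total_duration_s is not None else states.span()[1]
    n_bins = int(round(total / dt))
    edges = np.arange(n_bins) * dt

    if params.regime == "urethane":
        return _generate_burst_suppression(rng, params, total, dt)

    gate = None
    if params.regime == "p8_discontinuous":
        gate = _gate_vector(rng, n_bins, dt, params)

    trains = []
    truth_rates: dict[str, dict[str, float]] = {}
    for unit in params.units:
        rates = _state_rate_vector(unit, states, edges)
        if gate is not None:
            rates = rates * gate
        if unit.responsive and unit.response_gain > 0:
            add = unit.response_gain * unit.rate_as_hz
            for etype in unit.responds_to:
                ev = events.get(etype)
                if ev is None:
                    continue
                for t in ev.onsets_s:
                    i0 = int(np.ceil((t + unit.response_latency_s) / dt - 1e-9))
                    i1 = int(np.ceil((t + unit.response_latency_s + unit.response_width_s) / dt - 1e-9))
                    rates[max(0, i0):min(n_bins, i1)] += add
        times = _sample_inhomogeneous(rng, rates, dt)
        trains.append(SpikeTrain(unit.unit_id, unit.area, times))
        truth_rates[unit.unit_id] = {
            "AS": unit.rate_as_hz,
            "wake": unit.rate_wake_hz,
            "quiescence": unit.rate_quiescence_hz,
        }
    truth = {
        "rates": truth_rates,
        "responsive": [u.unit_id for u in params.units if u.responsive],
    }
    return trains, truth


def _generate_burst_suppression(rng, params: SimParams, total: float, dt: float):
    """Shared population bursts separated by silences >= silence_min_s."""
    windows = []
    t = rng.uniform(0, 2.0)
    while t + params.burst_duration_s < total:
        windows.append((t, t + params.burst_duration_s))
        t += params.burst_duration_s + params.silence_min_s + rng.exponential(
            params.silence_extra_mean_s
        )
    n_bins = int(round(total / dt))
    rates = np.zeros(n_bins)
    for a, b in windows:
        rates[int(a / dt):min(n_bins, int(b / dt))] = params.burst_rate_hz
    trains = []
    for unit in params.units:
        times = _sample_inhomogeneous(rng, rates, dt)
        trains.append(SpikeTrain(unit.unit_id, unit.area, times))
    truth = {"burst_windows": windows, "responsive": []}
    return trains, truth


# ---------------------------------------------------------------------------
# Whole-session assembly
# ---------------------------------------------------------------------------


def generate_session(params: SimParams) -> tuple[Session, GroundTruth]:
    """Free-behavior P8/P12-style session plus stimulation block."""
    states = generate_state_sequence(params)
    movement, emg, events, true_moves = generate_behavior(states, params)
    total = movement.duration_s
    lfp, true_spindles = generate_lfp(states, events, params, total_duration_s=total)
    trains, spike_truth = generate_spikes(states, events, params, total_duration_s=total)

    stim = events["stimulation"].onsets_s
    extra = {"true_movement_periods": true_moves}
    if stim.size:
        extra["stimulation_period"] = EpochSet([(params.duration_s, total, "stimulation")])
    session = Session(
        age_group="P8" if params.regime == "p8_discontinuous" else "P12",
        signals={"lfp": lfp, "emg": emg, "movement": movement},
        spiketrains=trains,
        states=states,
        events=list(events.values()),
        extra_epochs=extra,
        meta={"seed": params.seed, "regime": params.regime},
    )
    truth = GroundTruth(
        true_spindles=true_spindles,
        true_responsive_units=spike_truth["responsive"],
        true_rates=spike_truth["rates"],
        true_movement_periods=true_moves,
    )
    return session, truth


def generate_urethane_session(params: SimParams) -> tuple[Session, GroundTruth]:
    """Pre/post injection session for the anesthesia experiment.

    The pre-injection period is a P8-like cycling session. With
    ``drug="urethane"`` the post period switches to the burst-suppression
    regime, suppresses movement events by ``movement_suppression`` (default
    87%), renders the EMG atonic with occasional spasms, and suppresses the
    spindle rate. With ``drug="saline"`` the post period is another
    independent P8-like cycling block (the control arm).
    """
    rng = _rng(params.seed, "urethane")
    pre = SimParams(**{**asdict_shallow(params), "duration_s": params.pre_duration_s,
                       "regime": "p8_discontinuous", "n_stimulations": 0})
    pre_states = generate_state_sequence(pre)
    movement_pre, emg_pre, events_pre, moves_pre = generate_behavior(pre_states, pre)
    lfp_pre, spin_pre = generate_lfp(pre_states, events_pre, pre,
                                     total_duration_s=params.pre_duration_s)
    trains_pre, truth_pre = generate_spikes(pre_states, events_pre, pre,
                                            total_duration_s=params.pre_duration_s)

    t_post0 = params.pre_duration_s + params.injection_gap_s
    post_dur = params.post_duration_s
    fr, er = params.frame_rate_hz, params.emg_rate_hz
    # expected pre event rate from occupancy (used for the urethane thinning)
    means = params.state_dwell_means_s
    tot = sum(means[k] for k in (["AS", "wake", "quiescence"] if params.include_quiescence
                                 else ["AS", "wake"]))
    pre_event_rate = (params.twitch_rate_hz * means["AS"] / tot
                      + params.wake_move_rate_hz * means["wake"] / tot)

    extras: dict = {"drug": params.drug, "pre_event_rate_hz": pre_event_rate}
    post_events_shifted: list[EventSeries] = []
    post_states_shifted: list[tuple[float, float, str]] = []

    if params.drug == "urethane":
        n_mov = int(round(post_dur * fr))
        movement_post = params.movement_baseline + rng.normal(
            0, params.movement_noise_sd, n_mov)
        # the suppression factor applies to movement *quantity* (bump area
        # per second), the measure the pre/post analysis reports; post
        # spasms are twitch-like bumps, so convert quantity to spasm rate
        pre_quantity_rate = (
            events_pre["twitch"].n
            * params.twitch_bump_mult * params.twitch_bump_dur_s
            + events_pre["wake_movement"].n
            * params.wake_move_bump_mult * params.wake_move_bump_dur_s
        ) / params.pre_duration_s
        spasm_area = params.twitch_bump_mult * params.twitch_bump_dur_s
        spasm_rate = (1.0 - params.movement_suppression) * pre_quantity_rate / spasm_area
        spasms = _poisson_onsets(rng, [(0.0, post_dur)], spasm_rate,
                                 params.twitch_bump_dur_s)
        spans_post = _add_bumps(movement_post, fr, 0.0, spasms,
                                params.twitch_bump_mult * params.movement_baseline,
                                params.twitch_bump_dur_s)
        emg_post = rng.normal(0, 0.1, int(round(post_dur * er)))  # atonic + spasms
        for t in spasms:
            i0, i1 = int(t * er), min(emg_post.size, int((t + 0.05) * er))
            emg_post[i0:i1] += rng.normal(0, 1.5, max(0, i1 - i0))

        post_params = SimParams(**{**asdict_shallow(params), "regime": "urethane",
                                   "duration_s": post_dur, "n_stimulations": 0})
        post_params.spindles = SpindleSpec(
            rate_as_per_min=params.spindles.rate_as_per_min
            * (1 - params.spindle_suppression),
            rate_wake_per_min=0.0,
            freq_hz=params.spindles.freq_hz,
            duration_range_s=params.spindles.duration_range_s,
            amplitude_mult=params.spindles.amplitude_mult,
        )
        scaffold = EpochSet([(0.0, post_dur, "AS")])  # spindle placement only
        lfp_post, spin_post = generate_lfp(scaffold, {}, post_params,
                                           total_duration_s=post_dur)
        trains_post, truth_post = generate_spikes(scaffold, {}, post_params,
                                                  total_duration_s=post_dur)
        post_move_eps = _shift_moves(spans_post, t_post0, post_dur)
        extras.update({
            "movement_suppression": params.movement_suppression,
            "post_event_rate_hz": spasm_rate,
            "burst_windows": [(a + t_post0, b + t_post0)
                              for a, b in truth_post["burst_windows"]],
        })
    else:  # saline control: an independent P8-like block
        post_p = SimParams(**{**asdict_shallow(params),
                              "seed": (params.seed + 1_000_003) % (2**31),
                              "duration_s": post_dur,
                              "regime": "p8_discontinuous", "n_stimulations": 0})
        post_states = generate_state_sequence(post_p)
        mv_post, emg_post_sig, ev_post, moves_post = generate_behavior(post_states, post_p)
        lfp_post, spin_post = generate_lfp(post_states, ev_post, post_p,
                                           total_duration_s=post_dur)
        trains_post, _ = generate_spikes(post_states, ev_post, post_p,
                                         total_duration_s=post_dur)
        movement_post = mv_post.samples[: int(round(post_dur * fr))]
        emg_post = emg_post_sig.samples[: int(round(post_dur * er))]
        post_move_eps = [(a + t_post0, b + t_post0, lab)
                         for a, b, lab in moves_post.intervals]
        post_states_shifted = [(a + t_post0, b + t_post0, lab)
                               for a, b, lab in post_states.intervals]
        for ev in ev_post.values():
            post_events_shifted.append(
                EventSeries(ev.event_type, ev.onsets_s + t_post0))

    # --- stitch everything onto a common time axis ---
    gap_mov = params.movement_baseline + rng.normal(
        0, params.movement_noise_sd, int(round(params.injection_gap_s * fr)))
    movement = SampledSignal("movement", np.concatenate(
        [movement_pre.samples[: int(round(params.pre_duration_s * fr))], gap_mov,
         movement_post]), fr, 0.0)
    gap_emg = rng.normal(0, 0.2, int(round(params.injection_gap_s * er)))
    emg = SampledSignal("emg", np.concatenate(
        [emg_pre.samples[: int(round(params.pre_duration_s * er))], gap_emg, emg_post]),
        er, 0.0)
    lr = params.lfp_rate_hz
    gap_lfp = _pink_noise(rng, int(round(params.injection_gap_s * lr)), lr,
                          params.lfp_noise_sd)
    lfp = SampledSignal("lfp", np.concatenate(
        [lfp_pre.samples, gap_lfp, lfp_post.samples]), lr, 0.0)

    trains = []
    post_by_id = {t.unit_id: t for t in trains_post}
    for tr in trains_pre:
        post_times = post_by_id[tr.unit_id].times_s + t_post0
        trains.append(SpikeTrain(tr.unit_id, tr.area,
                                 np.concatenate([tr.times_s, post_times])))

    total = t_post0 + post_dur
    prepost = EpochSet([(0.0, params.pre_duration_s, "pre"), (t_post0, total, "post")])
    move_eps = EpochSet(
        moves_pre.intervals
        + [(params.pre_duration_s, t_post0, "no_movement")]
        + post_move_eps
    )
    true_spindles = spin_pre + [(a + t_post0, b + t_post0, lab) for a, b, lab in spin_post]

    # merge pre and (saline) post events of the same type
    merged_events = []
    for etype in ("twitch", "wake_movement"):
        onsets = [events_pre[etype].onsets_s]
        onsets += [e.onsets_s for e in post_events_shifted if e.event_type == etype]
        merged_events.append(EventSeries(etype, np.sort(np.concatenate(onsets))))

    session = Session(
        age_group="urethane_experiment",
        signals={"lfp": lfp, "emg": emg, "movement": movement},
        spiketrains=trains,
        # the anesthetized post period carries no AS/wake labels
        states=EpochSet(pre_states.intervals + post_states_shifted),
        events=merged_events,
        extra_epochs={"prepost": prepost, "true_movement_periods": move_eps},
        meta={"seed": params.seed, "regime": "urethane_experiment",
              "drug": params.drug},
    )
    truth = GroundTruth(
        true_spindles=true_spindles,
        true_responsive_units=truth_pre["responsive"],
        true_rates=truth_pre["rates"],
        true_movement_periods=move_eps,
        extras=extras,
    )
    return session, truth


def _shift_moves(spans, off: float, dur: float) -> list:
    out = []
    prev = 0.0
    for a, b in _merge_spans(spans):
        if a > prev:
            out.append((prev + off, a + off, "no_movement"))
        out.append((a + off, min(b, dur) + off, "movement"))
        prev = min(b, dur)
    if prev < dur:
        out.append((prev + off, dur + off, "no_movement"))
    return out


def asdict_shallow(params: SimParams) -> dict:
    """Field dict without recursing into nested dataclasses."""
    return {f: getattr(params, f) for f in params.__dataclass_fields__}


def write_session(session: Session, truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write the session directory plus ``ground_truth.json``."""
    from .io import save_session

    out = save_session(session, out_dir)
    (out / "ground_truth.json").write_text(truth.to_json())
    return out
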