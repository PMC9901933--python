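"""Shared data model for developmental cortical electrophysiology sessions.

A session bundles, on a single time axis in seconds:

* uniformly sampled channels (LFP, nuchal EMG, video-derived pixel-change
  movement traces),
* per-unit spike trains with a cortical-area label (M1, M2, mPFC),
* behavioral-state epochs (active sleep, wake, quiescence — or pre/post
  injection),
* typed sensory-event onset series (twitches, wake movements, forelimb
  stimulations).

All intervals are half-open ``[start, end)``: a time exactly at a boundary
belongs to the later interval, so any partition of the session into epochs
is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Labels of the three recorded cortical areas.
AREAS = ("M1", "M2", "mPFC")

#: Behavioral-state labels. Quiescence is carried but excluded from state
#: contrasts by default.
STATE_LABELS = ("AS", "wake", "quiescence")

EVENT_TYPES = ("twitch", "wake_movement", "stimulation")


class ValidationError(ValueError):
    """Raised when a session component violates a structural invariant."""


# ---------------------------------------------------------------------------
# Sampled signals
# ---------------------------------------------------------------------------


@dataclass
class SampledSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    label : str
        Channel role: ``"lfp"``, ``"emg"`` or ``"movement"`` (optionally
        suffixed, e.g. ``"movement_forelimb"``).
    samples : ndarray
        Real-valued samples. LFP amplitudes are treated as arbitrary,
        unit-agnostic values; movement traces are pixel-intensity change
        per video frame.
    rate_hz : float
        Sampling rate; must be positive.
    t0_s : float
        Time of the first sample, seconds.
    """

    label: str
    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"signal {self.label!r} contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        """Times of all samples: ``t0_s + i / rate_hz``."""
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Index of the sample covering time ``t_s`` (floor convention)."""
        return int(np.floor((t_s - self.t0_s) * self.rate_hz))

    def slice_time(self, start_s: float, end_s: float) -> "SampledSignal":
        """Samples whose timestamps fall in ``[start_s, end_s)``."""
        i0 = max(0, int(np.ceil((start_s - self.t0_s) * self.rate_hz - 1e-9)))
        i1 = min(self.n, int(np.ceil((end_s - self.t0_s) * self.rate_hz - 1e-9)))
        i1 = max(i0, i1)
        return SampledSignal(
            label=self.label,
            samples=self.samples[i0:i1],
            rate_hz=self.rate_hz,
            t0_s=self.t0_s + i0 / self.rate_hz,
        )


# ---------------------------------------------------------------------------
# Spike trains and events
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrain:
    """Ascending spike times for one unit (single- or multi-unit)."""

    unit_id: str
    area: str
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValidationError("times_s must be a 1-D vector")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not strictly increasing")

    @property
    def n(self) -> int:
        return self.times_s.size


@dataclass
class EventSeries:
    """Onset times of one type of sensory event."""

    event_type: str
    onsets_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.ndim != 1:
            raise ValidationError("onsets_s must be a 1-D vector")
        if self.onsets_s.size > 1 and np.any(np.diff(self.onsets_s) < 0):
            raise ValidationError(f"{self.event_type}: onsets not ascending")

    @property
    def n(self) -> int:
        return self.onsets_s.size


# ---------------------------------------------------------------------------
# Epoch sets and interval algebra
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Labeled, pairwise non-overlapping half-open intervals.

    One labeling scheme per set, e.g. behavioral states (AS / wake /
    quiescence), movement periods (movement / no_movement), or injection
    periods (pre / post).
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b), str(lab)) for a, b, lab in self.intervals]
        for a, b, lab in ivs:
            if not a < b:
                raise ValidationError(f"epoch ({a}, {b}, {lab!r}) has start >= end")
        ivs.sort()
        for (a0, b0, l0), (a1, b1, l1) in zip(ivs, ivs[1:]):
            if a1 < b0 - 1e-12:
                raise ValidationError(
                    f"epochs ({a0}, {b0}, {l0!r}) and ({a1}, {b1}, {l1!r}) overlap"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for _, _, lab in self.intervals:
            if lab not in seen:
                seen.append(lab)
        return seen

    def intervals_for(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.intervals if lab == label]

    def duration(self, label: str | None = None) -> float:
        """Total duration of intervals with ``label`` (or all intervals)."""
        return sum(b - a for a, b, lab in self.intervals if label is None or lab == label)

    def span(self) -> tuple[float, float]:
        if not self.intervals:
            raise ValidationError("empty EpochSet has no span")
        return self.intervals[0][0], self.intervals[-1][1]

    def label_at(self, t_s: float) -> str | None:
        """Label of the interval containing ``t_s`` (half-open), else None."""
        for a, b, lab in self.intervals:
            if a <= t_s < b:
                return lab
        return None

    def subset(self, labels: Iterable[str]) -> "EpochSet":
        keep = set(labels)
        return EpochSet([iv for iv in self.intervals if iv[2] in keep])

    def intersect(self, other: "EpochSet") -> "EpochSet":
        """Pairwise intersection; labels joined as ``"left&right"``."""
        out = []
        for a0, b0, l0 in self.intervals:
            for a1, b1, l1 in other.intervals:
                lo, hi = max(a0, a1), min(b0, b1)
                if lo < hi:
                    out.append((lo, hi, f"{l0}&{l1}"))
        return EpochSet(out)


def intersect_intervals(
    ivs_a: Sequence[tuple[float, float]], ivs_b: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Intersection of two unlabeled interval lists."""
    out = []
    for a0, b0 in ivs_a:
        for a1, b1 in ivs_b:
            lo, hi = max(a0, a1), min(b0, b1)
            if lo < hi:
                out.append((lo, hi))
    return sorted(out)


def restrict_times(
    times_s: np.ndarray, epochs: EpochSet, label: str | None = None
) -> tuple[np.ndarray, float]:
    """Keep point times falling in the labeled intervals (half-open).

    Returns the retained times and the total duration of the matching
    intervals. An absent label yields an empty result with zero duration
    (logged, not an error).
    """
    times_s = np.asarray(times_s, dtype=float)
    ivs = (
        [(a, b) for a, b, _ in epochs.intervals]
        if label is None
        else epochs.intervals_for(label)
    )
    if not ivs:
        if label is not None:
            logger.info("restrict_times: label %r absent; empty result", label)
        return np.empty(0), 0.0
    mask = np.zeros(times_s.shape, dtype=bool)
    for a, b in ivs:
        mask |= (times_s >= a) & (times_s < b)
    duration = sum(b - a for a, b in ivs)
    return times_s[mask], duration


def restrict_spiketrain(
    train: SpikeTrain, epochs: EpochSet, label: str | None = None
) -> tuple[SpikeTrain, float]:
    """Spike train restricted to labeled intervals, with retained duration."""
    kept, dur = restrict_times(train.times_s, epochs, label)
    return SpikeTrain(unit_id=train.unit_id, area=train.area, times_s=kept), dur


def restrict_signal(
    signal: SampledSignal, epochs: EpochSet, label: str | None = None
) -> tuple[np.ndarray, float]:
    """Concatenated samples whose timestamps fall in the labeled intervals."""
    ivs = (
        [(a, b) for a, b, _ in epochs.intervals]
        if label is None
        else epochs.intervals_for(label)
    )
    if not ivs:
        if label is not None:
            logger.info("restrict_signal: label %r absent; empty result", label)
        return np.empty(0), 0.0
    chunks = [signal.slice_time(a, b).samples for a, b in ivs]
    duration = sum(b - a for a, b in ivs)
    return np.concatenate(chunks) if chunks else np.empty(0), duration


# ---------------------------------------------------------------------------
# Session container
# ---------------------------------------------------------------------------


@dataclass
class Session:
    """All components of one recording on a common time axis.

    ``extra_epochs`` carries auxiliary interval sets keyed by name
    (``"movement_periods"``, ``"stimulation_period"``, ``"prepost"``).
    """

    age_group: str  # "P8" | "P12" | "urethane_experiment"
    signals: dict[str, SampledSignal] = field(default_factory=dict)
    spiketrains: list[SpikeTrain] = field(default_factory=list)
    states: EpochSet | None = None
    events: list[EventSeries] = field(default_factory=list)
    extra_epochs: dict[str, EpochSet] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        start, end = self.time_bounds()
        return end - start

    def time_bounds(self) -> tuple[float, float]:
        """Recorded extent: the union of signal spans and epoch spans.

        Spikes and events must lie inside this extent; they do not extend
        it (a stray timestamp past the recording is an error, not data).
        Falls back to spike/event extent when no signal or epoch exists.
        """
        starts, ends = [], []
        for sig in self.signals.values():
            starts.append(sig.t0_s)
            ends.append(sig.end_s)
        for eps in [self.states, *self.extra_epochs.values()]:
            if eps is not None and len(eps):
                a, b = eps.span()
                starts.append(a)
                ends.append(b)
        if not starts:
            for tr in self.spiketrains:
                if tr.n:
                    starts.append(tr.times_s[0])
                    ends.append(tr.times_s[-1])
            for ev in self.events:
                if ev.n:
                    starts.append(ev.onsets_s[0])
                    ends.append(ev.onsets_s[-1])
        if not starts:
            raise ValidationError("session has no timed content")
        return min(starts), max(ends)

    def events_of(self, event_type: str) -> EventSeries:
        for ev in self.events:
            if ev.event_type == event_type:
                return ev
        return EventSeries(event_type=event_type, onsets_s=np.empty(0))

    def trains_in(self, area: str) -> list[SpikeTrain]:
        return [t for t in self.spiketrains if t.area == area]

    def validate(self) -> None:
        """Check cross-component invariants; raise :class:`ValidationError`."""
        start, end = self.time_bounds()
        if not end > start:
            raise ValidationError("session duration must be positive")
        tol = 1e-9
        # spikes within the sampled/annotated extent
        for tr in self.spiketrains:
            if tr.n and (tr.times_s[0] < start - tol or tr.times_s[-1] > end + tol):
                raise ValidationError(
                    f"unit {tr.unit_id}: spike times outside session bounds "
                    f"[{start}, {end}]"
                )
        for ev in self.events:
            if ev.n and (ev.onsets_s[0] < start - tol or ev.onsets_s[-1] > end + tol):
                raise ValidationError(f"{ev.event_type} onsets outside session bounds")
        # twitches must fall inside AS when states are provided
        if self.states is not None and len(self.states):
            tw = self.events_of("twitch")
            for t in tw.onsets_s:
                lab = self.states.label_at(t)
                if lab is not None and lab != "AS":
                    raise ValidationError(
                        f"twitch at {t:.3f} s lies in state {lab!r}, expected AS"
                    )
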