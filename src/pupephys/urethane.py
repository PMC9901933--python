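"""Pre/post anesthesia comparisons: movement quantity, firing rates,
interspike-interval structure, and spindle rates.

The anesthetized (post-injection) state is characterized by suppressed
movement, firing-rate reductions, a burst-suppression spiking pattern with
inter-burst silences of 10 s or longer (visible as shoulders in ISI
survivor plots), and a collapse of spindle-burst activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EpochSet, SampledSignal, SpikeTrain, restrict_times
from .signal import SpindleBurst

logger = logging.getLogger(__name__)


@dataclass
class IsiSummary:
    """Survivor curve and bottom-fifth-percentile summary of ISIs."""

    isis_s: np.ndarray  # sorted
    p5_s: float
    n_isis: int

    def survivor(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t) = fraction of ISIs strictly greater than t."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        s = 1.0 - np.searchsorted(self.isis_s, t_arr, "right") / self.n_isis
        return s if np.ndim(t) else float(s[0])


def select_quiet_windows(
    movement: SampledSignal,
    n_windows: int = 5,
    window_s: float = 1.0,
    search_intervals: Sequence[tuple[float, float]] | None = None,
) -> list[tuple[float, float]]:
    """Auto-select ``n_windows`` non-overlapping 1-s no-movement windows —
    a stand-in for windows an experimenter would pick by eye.

    Candidates are restricted to ``search_intervals`` (e.g. detected
    no-movement periods) when given. Among candidates, windows whose
    rolling sum is closest to the candidate median are chosen: a *typical*
    quiet window, not an extreme one, so the resulting baseline estimate is
    unbiased (taking the global minima would systematically underestimate
    the quiet floor).
    """
    rate = movement.rate_hz
    w = int(round(window_s * rate))
    x = movement.samples
    sums = np.convolve(x, np.ones(w), mode="valid")  # rolling window sums
    valid = np.ones(sums.size, dtype=bool)
    if search_intervals is not None:
        valid[:] = False
        for a, b in search_intervals:
            i0 = max(0, int(np.ceil((a - movement.t0_s) * rate)))
            i1 = min(sums.size, int((b - movement.t0_s) * rate) - w + 1)
            if i1 > i0:
                valid[i0:i1] = True
    if not valid.any():
        raise ValueError("no candidate positions for quiet windows")
    med = np.median(sums[valid])
    score = np.where(valid, np.abs(sums - med), np.inf)
    chosen: list[int] = []
    order = np.argsort(score, kind="stable")
    for i in order:
        if not np.isfinite(score[i]):
            break
        if all(abs(i - j) >= w for j in chosen):
            chosen.append(int(i))
        if len(chosen) == n_windows:
            break
    if len(chosen) < n_windows:
        raise ValueError(f"could not place {n_windows} non-overlapping quiet windows")
    t0 = movement.t0_s
    return sorted((t0 + i / rate, t0 + i / rate + window_s) for i in chosen)


def movement_baseline(
    movement: SampledSignal, windows: Sequence[tuple[float, float]]
) -> float:
    """Mean pixel change across the supplied no-movement windows."""
    vals = [movement.slice_time(a, b).samples for a, b in windows]
    return float(np.concatenate(vals).mean())


def movement_quantity(
    movement: SampledSignal,
    windows: Sequence[tuple[float, float]],
    period: tuple[float, float],
    movement_periods: EpochSet | None = None,
    clip_negative: bool = False,
) -> float:
    """Normalized movement quantity over a period.

    Baseline = mean pixel change across five 1-s no-movement windows; the
    baseline-subtracted samples are summed over the period and divided by
    the period duration. Subtraction is signed by default: symmetric
    sensor noise then cancels in the sum, leaving an unbiased estimate of
    movement-related pixel change per second (zero-clipping each sample
    instead, available via ``clip_negative``, rectifies the noise and
    inflates both periods by the same offset, biasing the pre/post percent
    change toward zero). Warns if a supplied window overlaps a detected
    movement period.
    """
    if len(windows) != 5:
        logger.warning("expected five 1-s baseline windows, got %d", len(windows))
    if movement_periods is not None:
        for a, b in windows:
            for ma, mb, lab in movement_periods.intervals:
                if lab == "movement" and max(a, ma) < min(b, mb):
                    logger.warning(
                        "baseline window (%.2f, %.2f) overlaps a movement period", a, b
                    )
    base = movement_baseline(movement, windows)
    seg = movement.slice_time(*period)
    dur = period[1] - period[0]
    if dur <= 0:
        raise ValueError("period duration must be positive")
    diff = seg.samples - base
    if clip_negative:
        diff = np.clip(diff, 0, None)
    return float(diff.sum() / dur)


def percent_change(pre: float, post: float) -> float | None:
    """100 x (post - pre) / pre; None (undefined) when pre == 0."""
    if pre == 0:
        logger.info("percent change undefined for pre == 0")
        return None
    return 100.0 * (post - pre) / pre


def isi_summary(
    train: SpikeTrain,
    period: EpochSet | list[tuple[float, float]],
    label: str | None = None,
    min_isis: int = 20,
    percentile: float = 5.0,
) -> IsiSummary | None:
    """ISIs between consecutive spikes within the same period interval.

    Pairs spanning an interval boundary (e.g. the injection gap) are
    excluded. The bottom-fifth-percentile summary uses the
    interpolated-inverted-CDF convention (linear interpolation between
    order statistics at positions i/n). Returns None with fewer than
    ``min_isis`` intervals.
    """
    ivs = (
        period.intervals_for(label) if isinstance(period, EpochSet) and label
        else [(a, b) for a, b, _ in period.intervals] if isinstance(period, EpochSet)
        else list(period)
    )
    isis = []
    for a, b in ivs:
        seg = train.times_s[(train.times_s >= a) & (train.times_s < b)]
        if seg.size >= 2:
            isis.append(np.diff(seg))
    if not isis:
        logger.info("unit %s: no ISIs in period", train.unit_id)
        return None
    isis_arr = np.sort(np.concatenate(isis))
    if isis_arr.size < min_isis:
        logger.info("unit %s: only %d ISIs (< %d); omitted", train.unit_id, isis_arr.size, min_isis)
        return None
    p5 = float(np.percentile(isis_arr, percentile, method="interpolated_inverted_cdf"))
    return IsiSummary(isis_s=isis_arr, p5_s=p5, n_isis=int(isis_arr.size))


def pooled_isi_summary(
    trains: Sequence[SpikeTrain],
    period: EpochSet | list[tuple[float, float]],
    label: str | None = None,
    min_isis: int = 20,
) -> IsiSummary | None:
    """ISI summary pooling all units' per-train ISIs (survivor plots are
    shown on pooled ISIs)."""
    parts = []
    for tr in trains:
        s = isi_summary(tr, period, label=label, min_isis=0)
        if s is not None:
            parts.append(s.isis_s)
    if not parts:
        return None
    isis_arr = np.sort(np.concatenate(parts))
    if isis_arr.size < min_isis:
        return None
    p5 = float(np.percentile(isis_arr, 5.0, method="interpolated_inverted_cdf"))
    return IsiSummary(isis_s=isis_arr, p5_s=p5, n_isis=int(isis_arr.size))


def pre_post_rates(
    trains: Sequence[SpikeTrain], prepost: EpochSet
) -> pd.DataFrame:
    """Per-unit mean firing rate in the pre- and post-injection periods.

    Units silent in a period are included with rate 0.
    """
    rows = []
    for lab in ("pre", "post"):
        dur = prepost.duration(lab)
        if dur <= 0:
            raise ValueError(f"period {lab!r} is empty")
        for tr in trains:
            kept, _ = restrict_times(tr.times_s, prepost, lab)
            rows.append((tr.unit_id, tr.area, lab, kept.size, dur, kept.size / dur))
    return pd.DataFrame(
        rows, columns=["unit_id", "area", "condition", "n_spikes", "duration_s", "rate_hz"]
    )


def pre_post_spindle_rates(
    bursts: Sequence[SpindleBurst], prepost: EpochSet
) -> pd.DataFrame:
    """Spindle-burst rate (bursts/min) in the pre- and post-injection
    periods, burst assigned by onset."""
    onsets = np.array([b.onset_s for b in bursts], dtype=float)
    rows = []
    for lab in ("pre", "post"):
        dur = prepost.duration(lab)
        if dur <= 0:
            raise ValueError(f"period {lab!r} is empty")
        kept, _ = restrict_times(onsets, prepost, lab)
        rows.append((lab, kept.size, dur, kept.size / dur * 60.0))
    return pd.DataFrame(rows, columns=["condition", "n_bursts", "duration_s", "rate_per_min"])
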