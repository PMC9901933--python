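"""Spindle-burst / sensory-event coupling with a within-period shuffle null.

The observed coupling is the fraction of spindle bursts preceded by at
least one sensory event within the 500 ms before burst onset (half-open
window ``[onset - 0.5, onset)``: an event exactly at onset does not count
as preceding). The chance level is estimated by redrawing both onset sets
uniformly within the behavioral-state or stimulation period (counts
preserved) 100 times and averaging the resulting probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EpochSet


@dataclass
class CouplingResult:
    observed_p: float | None
    expected_p: float | None
    n_spindles: int
    n_events: int
    n_shuffles: int = 100
    event_type: str = ""
    area: str = ""
    shuffle_probs: np.ndarray = field(default_factory=lambda: np.empty(0))


def spindle_event_probability(
    spindle_onsets: np.ndarray, event_onsets: np.ndarray, window_s: float = 0.5
) -> float | None:
    """Fraction of spindles with >= 1 event in ``[onset - window, onset)``.

    Returns None (undefined) when there are no spindles.
    """
    spindle_onsets = np.sort(np.asarray(spindle_onsets, dtype=float))
    event_onsets = np.sort(np.asarray(event_onsets, dtype=float))
    if spindle_onsets.size == 0:
        return None
    if event_onsets.size == 0:
        return 0.0
    lo = np.searchsorted(event_onsets, spindle_onsets - window_s, "left")
    hi = np.searchsorted(event_onsets, spindle_onsets, "left")
    return float(np.mean(hi > lo))


def _uniform_in_intervals(
    rng: np.random.Generator, intervals: list[tuple[float, float]], n: int
) -> np.ndarray:
    lengths = np.array([b - a for a, b in intervals])
    starts = np.array([a for a, _ in intervals])
    which = rng.choice(lengths.size, size=n, p=lengths / lengths.sum())
    return starts[which] + rng.uniform(0, 1, n) * lengths[which]


def shuffle_expected_probability(
    spindle_onsets: np.ndarray,
    event_onsets: np.ndarray,
    period: EpochSet | list[tuple[float, float]],
    n_shuffles: int = 100,
    window_s: float = 0.5,
    seed: int | np.random.Generator = 0,
    mode: str = "both",
) -> tuple[float | None, np.ndarray]:
    """Mean coupling probability over uniform reshuffles within the period.

    ``mode="both"`` (default) redraws both onset sets; ``mode="events"``
    redraws only the events, keeping spindle onsets fixed — a sensitivity
    variant. Returns (mean probability, per-shuffle probabilities).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ivs = (
        [(a, b) for a, b, _ in period.intervals]
        if isinstance(period, EpochSet)
        else list(period)
    )
    total = sum(b - a for a, b in ivs)
    if total <= 0:
        raise ValueError("period duration must be positive")
    n_sp = int(np.asarray(spindle_onsets).size)
    n_ev = int(np.asarray(event_onsets).size)
    if n_sp == 0:
        return None, np.empty(0)
    probs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        sp = (
            _uniform_in_intervals(rng, ivs, n_sp)
            if mode == "both"
            else np.asarray(spindle_onsets, dtype=float)
        )
        ev = _uniform_in_intervals(rng, ivs, n_ev) if n_ev else np.empty(0)
        probs[i] = spindle_event_probability(sp, ev, window_s)
    return float(probs.mean()), probs


def coupling_test(observed: np.ndarray, expected: np.ndarray) -> dict:
    """Per-animal observed-vs-expected paired comparison on arcsine scale.

    Each entry is one animal's probability pair. With fewer than two
    animals only descriptive output is produced (no test statistic).
    """
    from .stats import arcsine_transform, paired_comparison

    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must be paired per animal")
    out = {
        "n_animals": int(observed.size),
        "mean_observed": float(observed.mean()) if observed.size else None,
        "mean_expected": float(expected.mean()) if expected.size else None,
        "stat": None,
    }
    if observed.size >= 2:
        obs_t = arcsine_transform(observed)
        exp_t = arcsine_transform(expected)
        out["stat"] = paired_comparison(obs_t, exp_t)
    return out
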