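"""State- and movement-conditioned firing-rate and spindle-rate summaries.

Rates are computed per unit over the pooled duration of each behavioral
state (active sleep vs wake, quiescence excluded by default), optionally
crossed with movement / no-movement periods. Aggregation follows the
hierarchy unit -> area-within-animal -> across animals.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EpochSet, SpikeTrain, restrict_times
from .signal import SpindleBurst

logger = logging.getLogger(__name__)

STATE_CONTRAST = ("AS", "wake")


def rate_by_state(
    spiketrains: Sequence[SpikeTrain],
    states: EpochSet,
    labels: Sequence[str] = STATE_CONTRAST,
) -> pd.DataFrame:
    """Per-unit mean firing rate over the pooled duration of each state.

    Returns a table with columns ``unit_id, area, condition, n_spikes,
    duration_s, rate_hz``. States with zero pooled duration are omitted
    (and logged).
    """
    rows = []
    for lab in labels:
        dur = states.duration(lab)
        if dur <= 0:
            logger.info("state %r has zero duration; omitted", lab)
            continue
        for tr in spiketrains:
            kept, _ = restrict_times(tr.times_s, states, lab)
            rows.append((tr.unit_id, tr.area, lab, kept.size, dur, kept.size / dur))
    return pd.DataFrame(
        rows, columns=["unit_id", "area", "condition", "n_spikes", "duration_s", "rate_hz"]
    )


def rate_by_state_and_movement(
    spiketrains: Sequence[SpikeTrain],
    states: EpochSet,
    movement_periods: EpochSet,
    state_labels: Sequence[str] = STATE_CONTRAST,
) -> pd.DataFrame:
    """Four-condition rates: {AS, wake} x {movement, no_movement}.

    Conditions are intersections of state intervals with movement-period
    intervals; empty intersections are omitted and logged.
    """
    rows = []
    for s_lab in state_labels:
        s_eps = states.subset([s_lab])
        for m_lab in ("movement", "no_movement"):
            m_eps = movement_periods.subset([m_lab])
            inter = s_eps.intersect(m_eps)
            dur = inter.duration()
            cond = f"{s_lab}&{m_lab}"
            if dur <= 0:
                logger.info("condition %r empty; omitted", cond)
                continue
            for tr in spiketrains:
                kept, _ = restrict_times(tr.times_s, inter)
                rows.append((tr.unit_id, tr.area, cond, kept.size, dur, kept.size / dur))
    return pd.DataFrame(
        rows, columns=["unit_id", "area", "condition", "n_spikes", "duration_s", "rate_hz"]
    )


def spindle_rate_by_state(
    bursts: Sequence[SpindleBurst],
    states: EpochSet,
    labels: Sequence[str] = STATE_CONTRAST,
) -> pd.DataFrame:
    """Spindle-burst rate (bursts/min) per state per area.

    A burst belongs to the state containing its onset (bursts may straddle
    state boundaries).
    """
    areas = sorted({b.area for b in bursts}) or [""]
    rows = []
    for lab in labels:
        dur = states.duration(lab)
        if dur <= 0:
            logger.info("state %r has zero duration; omitted", lab)
            continue
        for area in areas:
            onsets = np.array(
                [b.onset_s for b in bursts if b.area == area], dtype=float
            )
            kept, _ = restrict_times(onsets, states, lab)
            rows.append((area, lab, kept.size, dur, kept.size / dur * 60.0))
    return pd.DataFrame(
        rows, columns=["area", "condition", "n_bursts", "duration_s", "rate_per_min"]
    )


def area_means(table: pd.DataFrame, value: str = "rate_hz") -> pd.DataFrame:
    """Mean of ``value`` across units within each (area, condition) cell —
    the per-animal aggregate."""
    return (
        table.groupby(["area", "condition"], sort=True)[value]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": value, "count": "n_units"})
    )


def animal_means(per_animal: pd.DataFrame, value: str = "rate_hz") -> pd.DataFrame:
    """Across-animal mean ± SEM of per-animal area means.

    Expects a table with an ``animal_id`` column (one row per animal per
    area per condition, as produced by :func:`area_means` per session).
    """
    def sem(x):
        x = np.asarray(x, dtype=float)
        return x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else np.nan

    return (
        per_animal.groupby(["area", "condition"], sort=True)[value]
        .agg(["mean", sem, "count"])
        .reset_index()
        .rename(columns={"mean": value, "sem": "sem", "count": "n_animals"})
    )
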