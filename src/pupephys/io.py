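"""Session directory reader/writer.

Layout (all plain text, times in seconds):

* ``session.json`` — age group, channel metadata (label, rate_hz, t0_s,
  units, filename), free-form provenance.
* ``spikes.tsv`` — columns ``unit_id  area  time_s``, one row per spike.
* ``states.tsv`` — BED-like: ``start_s  end_s  label``.
* ``events.tsv`` — ``onset_s  event_type``.
* ``epochs_<name>.tsv`` — auxiliary interval sets (movement periods,
  stimulation period, pre/post), same columns as ``states.tsv``.
* one ``<channel>.csv`` per sampled signal (single column of samples).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochSet, EventSeries, SampledSignal, Session, SpikeTrain

_SESSION_JSON = "session.json"
_SPIKES = "spikes.tsv"
_STATES = "states.tsv"
_EVENTS = "events.tsv"


class SessionLoadError(IOError):
    """A required file is missing or unreadable."""


def save_session(session: Session, path: str | Path) -> Path:
    """Write a session directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    channels = {}
    for name, sig in session.signals.items():
        fname = f"{name}.csv"
        np.savetxt(path / fname, sig.samples, fmt="%.10g")
        channels[name] = {
            "label": sig.label,
            "rate_hz": sig.rate_hz,
            "t0_s": sig.t0_s,
            "file": fname,
        }
    meta = {
        "age_group": session.age_group,
        "channels": channels,
        "meta": session.meta,
        "extra_epochs": sorted(session.extra_epochs),
    }
    (path / _SESSION_JSON).write_text(json.dumps(meta, indent=2, sort_keys=True))

    rows = [
        (tr.unit_id, tr.area, t)
        for tr in session.spiketrains
        for t in tr.times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "area", "time_s"]).to_csv(
        path / _SPIKES, sep="\t", index=False, float_format="%.9f"
    )
    # keep empty trains discoverable
    units = [(tr.unit_id, tr.area) for tr in session.spiketrains]
    pd.DataFrame(units, columns=["unit_id", "area"]).to_csv(
        path / "units.tsv", sep="\t", index=False
    )

    _write_epochs(path / _STATES, session.states or EpochSet([]))
    for name, eps in session.extra_epochs.items():
        _write_epochs(path / f"epochs_{name}.tsv", eps)

    ev_rows = [
        (t, ev.event_type) for ev in session.events for t in ev.onsets_s
    ]
    pd.DataFrame(ev_rows, columns=["onset_s", "event_type"]).to_csv(
        path / _EVENTS, sep="\t", index=False, float_format="%.9f"
    )
    return path


def load_session(path: str | Path, validate: bool = True) -> Session:
    """Read a session directory written by :func:`save_session`.

    Raises :class:`SessionLoadError` naming any missing required file and
    :class:`~pupephys.core.ValidationError` on invariant violations.
    """
    path = Path(path)
    for required in (_SESSION_JSON, _SPIKES, _STATES, _EVENTS):
        if not (path / required).exists():
            raise SessionLoadError(f"missing required file: {path / required}")
    meta = json.loads((path / _SESSION_JSON).read_text())

    signals = {}
    for name, ch in meta.get("channels", {}).items():
        fpath = path / ch["file"]
        if not fpath.exists():
            raise SessionLoadError(f"missing signal file: {fpath}")
        samples = np.loadtxt(fpath, dtype=float, ndmin=1)
        signals[name] = SampledSignal(
            label=ch["label"], samples=samples, rate_hz=ch["rate_hz"], t0_s=ch["t0_s"]
        )

    spikes = pd.read_csv(path / _SPIKES, sep="\t")
    units_file = path / "units.tsv"
    if units_file.exists():
        units = pd.read_csv(units_file, sep="\t")
        unit_order = [(str(r.unit_id), str(r.area)) for r in units.itertuples()]
    else:
        unit_order = [
            (str(u), str(a))
            for u, a in spikes[["unit_id", "area"]].drop_duplicates().itertuples(index=False)
        ]
    trains = []
    grouped = {
        (str(u), str(a)): g["time_s"].to_numpy()
        for (u, a), g in spikes.groupby(["unit_id", "area"], sort=False)
    }
    for uid, area in unit_order:
        times = grouped.get((uid, area), np.empty(0))
        trains.append(SpikeTrain(unit_id=uid, area=area, times_s=np.sort(times)))

    states = _read_epochs(path / _STATES)
    extra = {}
    for name in meta.get("extra_epochs", []):
        extra[name] = _read_epochs(path / f"epochs_{name}.tsv")

    ev_df = pd.read_csv(path / _EVENTS, sep="\t")
    events = []
    for etype, g in ev_df.groupby("event_type", sort=True):
        events.append(
            EventSeries(event_type=str(etype), onsets_s=np.sort(g["onset_s"].to_numpy()))
        )

    session = Session(
        age_group=meta["age_group"],
        signals=signals,
        spiketrains=trains,
        states=states,
        events=events,
        extra_epochs=extra,
        meta=meta.get("meta", {}),
    )
    if validate:
        session.validate()
    return session


def _write_epochs(fpath: Path, epochs: EpochSet) -> None:
    pd.DataFrame(
        epochs.intervals, columns=["start_s", "end_s", "label"]
    ).to_csv(fpath, sep="\t", index=False, float_format="%.9f")


def _read_epochs(fpath: Path) -> EpochSet:
    if not fpath.exists():
        raise SessionLoadError(f"missing epoch file: {fpath}")
    df = pd.read_csv(fpath, sep="\t")
    return EpochSet(
        [(float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()]
    )
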