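"""End-to-end report assembly.

``run_pipeline`` executes every stage applicable to a session — movement
periods, spindle detection, state- and movement-conditioned rates,
responsiveness, activation, spindle–event coupling, or the pre/post
anesthesia battery — and writes TSV tables plus a deterministic JSON
summary. A fixed configuration and seed yield byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import sensory, state_metrics, urethane
from .core import EpochSet, Session
from .io import load_session
from .signal import DetectorParams, detect_spindles_in_lfp, extract_movement_periods
from .simulate import GroundTruth, SimParams, SpindleSpec, UnitSpec, generate_session, \
    generate_urethane_session

logger = logging.getLogger(__name__)


def sim_params_from_config(cfg: dict) -> SimParams:
    """Build :class:`SimParams` from a plain config mapping."""
    cfg = dict(cfg)
    spindles = cfg.pop("spindles", None)
    units = cfg.pop("units", None)
    valid = {f.name for f in dc_fields(SimParams)}
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    params = SimParams(**cfg)
    if spindles is not None:
        params.spindles = SpindleSpec(**spindles)
    if units is not None:
        params.units = [UnitSpec(**u) for u in units]
    return params


def _round(x, nd=9):
    if isinstance(x, float):
        return round(x, nd)
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (np.floating,)):
        return round(float(x), nd)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all applicable stages and write the report bundle.

    ``config`` carries ``mode`` ("p8" for a cycling session, "urethane"
    for a pre/post session), ``seed``, and either ``session`` (path to a
    session directory) or ``sim`` (generator overrides).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "p8")
    seed = int(config.get("seed", 0))

    truth: GroundTruth | None = None
    if "session" in config:
        session = load_session(config["session"])
    else:
        params = sim_params_from_config({"seed": seed, **config.get("sim", {})})
        if mode == "urethane":
            session, truth = generate_urethane_session(params)
        else:
            session, truth = generate_session(params)

    summary: dict = {"mode": mode, "seed": seed, "stages": {}}
    try:
        if mode == "urethane":
            _run_urethane_stages(session, summary, out)
        else:
            _run_cycling_stages(session, summary, out, seed)
    finally:
        payload = json.dumps(_round(summary), indent=2, sort_keys=True)
        (out / "summary.json").write_text(payload)
        (out / "run_log.json").write_text(json.dumps(
            {"seed": seed, "config": _round(config)}, indent=2, sort_keys=True, default=str))
    return summary


def _run_cycling_stages(session: Session, summary: dict, out: Path, seed: int) -> None:
    det = DetectorParams()
    states = session.states

    movement_periods = extract_movement_periods(session.signals["movement"], params=det)
    _write_eps(out / "movement_periods.tsv", movement_periods)
    summary["stages"]["movement_periods"] = {
        "n_periods": len(movement_periods.intervals_for("movement")),
        "movement_s": movement_periods.duration("movement"),
    }

    bursts = detect_spindles_in_lfp(session.signals["lfp"], params=det, area="M1")
    pd.DataFrame(
        [(b.onset_s, b.offset_s, b.peak_envelope, b.area) for b in bursts],
        columns=["start_s", "end_s", "peak", "label"],
    ).to_csv(out / "spindles.tsv", sep="\t", index=False)
    summary["stages"]["spindles"] = {"n_bursts": len(bursts)}

    state_rates = state_metrics.rate_by_state(session.spiketrains, states)
    state_rates.to_csv(out / "state_rates.tsv", sep="\t", index=False)
    cond_rates = state_metrics.rate_by_state_and_movement(
        session.spiketrains, states, movement_periods
    )
    cond_rates.to_csv(out / "state_movement_rates.tsv", sep="\t", index=False)
    spindle_rates = state_metrics.spindle_rate_by_state(bursts, states)
    spindle_rates.to_csv(out / "spindle_rates.tsv", sep="\t", index=False)
    summary["stages"]["state_rates"] = {
        f"{r.area}:{r.condition}": r.rate_hz
        for r in state_metrics.area_means(state_rates).itertuples()
    }
    summary["stages"]["spindle_rates"] = {
        f"{r.area}:{r.condition}": r.rate_per_min for r in spindle_rates.itertuples()
    }

    span = session.time_bounds()
    resp_rows = []
    responsive: dict[tuple[str, str], list] = {}
    for ev in session.events:
        if ev.n == 0:
            continue
        for area in sorted({t.area for t in session.spiketrains}):
            for tr in session.trains_in(area):
                peth = sensory.compute_peth(tr, ev, recording_span=span)
                res = sensory.classify_responsive(peth)
                resp_rows.append((tr.unit_id, area, ev.event_type, res.blw_mean,
                                  res.blw_sd, res.rw_mean, res.responsive))
                if res.responsive:
                    responsive.setdefault((area, ev.event_type), []).append(tr)
    resp_df = pd.DataFrame(resp_rows, columns=[
        "unit_id", "area", "event_type", "blw_mean", "blw_sd", "rw_mean", "responsive"])
    resp_df.to_csv(out / "responsiveness.tsv", sep="\t", index=False)
    summary["stages"]["responsiveness"] = {
        f"{a}:{e}": float(100 * g["responsive"].mean())
        for (a, e), g in resp_df.groupby(["area", "event_type"], sort=True)
    }

    activation = {}
    for ev in session.events:
        if ev.n == 0:
            continue
        for area in sorted({t.area for t in session.spiketrains}):
            act = sensory.event_activation(responsive.get((area, ev.event_type), []), ev)
            activation[f"{area}:{ev.event_type}"] = act.activation_rate
    summary["stages"]["activation"] = activation

    coupling_out = {}
    rng = np.random.default_rng([seed % (2**31), 97])
    spindle_onsets = np.array([b.onset_s for b in bursts])
    period_of = {
        "twitch": states.subset(["AS"]) if states else None,
        "wake_movement": states.subset(["wake"]) if states else None,
        "stimulation": session.extra_epochs.get("stimulation_period"),
    }
    for ev in session.events:
        period = period_of.get(ev.event_type)
        if ev.n == 0 or period is None or not len(period):
            continue
        from .core import restrict_times

        sp_in, _ = restrict_times(spindle_onsets, period)
        ev_in, _ = restrict_times(ev.onsets_s, period)
        obs = cpl.spindle_event_probability(sp_in, ev_in)
        exp, _probs = cpl.shuffle_expected_probability(sp_in, ev_in, period, seed=rng)
        coupling_out[ev.event_type] = {
            "observed_p": obs, "expected_p": exp,
            "n_spindles": int(sp_in.size), "n_events": int(ev_in.size),
        }
    summary["stages"]["coupling"] = coupling_out


def _run_urethane_stages(session: Session, summary: dict, out: Path) -> None:
    det = DetectorParams()
    prepost = session.extra_epochs["prepost"]
    (pre_a, pre_b) = prepost.intervals_for("pre")[0]
    (post_a, post_b) = prepost.intervals_for("post")[0]
    movement = session.signals["movement"]

    movement_periods = extract_movement_periods(movement, params=det)
    quiet = urethane.select_quiet_windows(
        movement, search_intervals=[(a, b) for a, b, lab in movement_periods.intervals
                                    if lab == "no_movement"])
    q_pre = urethane.movement_quantity(movement, quiet, (pre_a, pre_b), movement_periods)
    q_post = urethane.movement_quantity(movement, quiet, (post_a, post_b), movement_periods)
    summary["stages"]["movement"] = {
        "pre_quantity": q_pre, "post_quantity": q_post,
        "pct_change": urethane.percent_change(q_pre, q_post),
    }

    rates = urethane.pre_post_rates(session.spiketrains, prepost)
    rates.to_csv(out / "pre_post_rates.tsv", sep="\t", index=False)
    by = rates.pivot_table(index="unit_id", columns="condition", values="rate_hz")
    mean_pre, mean_post = float(by["pre"].mean()), float(by["post"].mean())
    summary["stages"]["firing"] = {
        "mean_pre_hz": mean_pre, "mean_post_hz": mean_post,
        "pct_change": urethane.percent_change(mean_pre, mean_post),
    }

    isi = {}
    for lab in ("pre", "post"):
        s = urethane.pooled_isi_summary(session.spiketrains, prepost, label=lab)
        if s is None:
            isi[lab] = None
            continue
        curve = pd.DataFrame({"isi_s": s.isis_s, "survivor": s.survivor(s.isis_s)})
        curve.to_csv(out / f"isi_survivor_{lab}.csv", index=False)
        isi[lab] = {"p5_s": s.p5_s, "n_isis": s.n_isis,
                    "survivor_at_10s": float(s.survivor(10.0)),
                    "max_isi_s": float(s.isis_s[-1])}
    summary["stages"]["isi"] = isi

    baseline_eps = EpochSet([(pre_a, pre_b, "pre")])
    bursts = detect_spindles_in_lfp(session.signals["lfp"], baseline=baseline_eps,
                                    params=det, area="M1")
    sp = urethane.pre_post_spindle_rates(bursts, prepost)
    sp.to_csv(out / "pre_post_spindle_rates.tsv", sep="\t", index=False)
    summary["stages"]["spindles"] = {
        r.condition: r.rate_per_min for r in sp.itertuples()
    }


def _write_eps(path: Path, eps: EpochSet) -> None:
    pd.DataFrame(eps.intervals, columns=["start_s", "end_s", "label"]).to_csv(
        path, sep="\t", index=False)
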