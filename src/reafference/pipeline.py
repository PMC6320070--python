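"""End-to-end orchestration: score -> fit -> classify -> reliability (+ extras).

``run_pipeline`` takes a Session (simulated or loaded) and an
AnalysisConfig and produces a JSON-serializable report: per-unit model fits
and classifications, a population table (unresponsive / wake / twitch /
both counts with event counts), trial-reliability columns, and — when the
session carries the needed inputs — summed shift-predictor correlograms per
region pair and a CSD sink location.  Stages whose prerequisites are missing
are skipped with an explicit log entry; the same config and session always
produce a byte-identical report.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, csd as csd_mod, psth as psth_mod, reliability, xcorr
from .config import AnalysisConfig
from .session_io import Session


def score_session(session: Session, config: AnalysisConfig):
    """EMG-based scoring: states, twitches per muscle, wake movements.

    The nuchal muscle (or the first channel) sets the sleep/wake states;
    wake movements are scored on the forelimb channel.
    """
    log = []
    state_muscle = "nuchal" if "nuchal" in session.emg else sorted(session.emg)[0]
    env_state = behavior.rectify_smooth(session.emg[state_muscle], config.wake_tau)
    states = behavior.classify_states(env_state, min_bout=config.min_bout)
    if states.unscorable:
        log.append(f"states: unscorable from {state_muscle} envelope")
        return states, {}, log
    log.append(f"states: scored from {state_muscle}")
    events = {}
    for muscle, ch in sorted(session.emg.items()):
        env_tw = behavior.rectify_smooth(ch, config.twitch_tau)
        events[f"twitch_{muscle}"] = behavior.detect_twitches(
            env_tw, states, config.twitch_mult, config.refractory
        )
    move_muscle = "forelimb" if "forelimb" in session.emg else state_muscle
    env_wk = behavior.rectify_smooth(session.emg[move_muscle], config.wake_tau)
    moves = behavior.detect_wake_movements(
        env_wk, states, config.wake_mult, config.sustain
    )
    events[f"wake_movement_{move_muscle}"] = moves.triggers
    events[f"wake_movement_scored_{move_muscle}"] = moves.scored
    log.append(
        "movements: "
        + ", ".join(f"{k}={len(v)}" for k, v in sorted(events.items()))
    )
    return states, events, log


def _pick_events(event_trains: dict, etype: str, muscle: str = "forelimb"):
    key = f"{etype}_{muscle}"
    if key in event_trains:
        return event_trains[key]
    for name, train in sorted(event_trains.items()):
        if train.type == etype and not name.startswith(f"{etype}_scored"):
            return train
    return None


def fit_units(session: Session, event_trains: dict, config: AnalysisConfig):
    """Per-unit PSTHs, model fits, classification, and trial reliability."""
    twitches = _pick_events(event_trains, "twitch")
    wakes = _pick_events(event_trains, "wake_movement")
    rows = []
    for train in session.spikes:
        row = {"unit": train.unit_id, "region": train.region}
        fit_tw = fit_wk = None
        if twitches is not None and len(twitches) and len(train):
            p_tw = psth_mod.build_psth(
                train, twitches, config.psth_window, config.psth_bin, "twitch"
            )
            fit_tw = psth_mod.fit_gaussian(p_tw)
            row.update(
                BL_twitch=fit_tw.BL, Rmax_twitch=fit_tw.R_max,
                tmax_twitch=fit_tw.t_max, HWHH_twitch=fit_tw.HWHH,
                r2_adj_twitch=fit_tw.r2_adj,
            )
        if wakes is not None and len(wakes) and len(train):
            p_wk = psth_mod.build_psth(
                train, wakes, config.psth_window, config.psth_bin, "wake_movement"
            )
            fit_wk = psth_mod.fit_gauss_exp(p_wk)
            row.update(
                BL_wake=fit_wk.BL, Rmax_wake=fit_wk.R_max,
                tmax_wake=fit_wk.t_max, HWHH_wake=fit_wk.HWHH,
                lambda_wake=fit_wk.lam, t_half_wake=fit_wk.t_half,
                r2_adj_wake=fit_wk.r2_adj,
            )
        cls = psth_mod.classify_neuron(fit_tw, fit_wk, config.r2_threshold)
        row["class"] = cls.label
        for label, fit, events in (("twitch", fit_tw, twitches), ("wake", fit_wk, wakes)):
            responsive = fit is not None and fit.r2_adj > config.r2_threshold
            if responsive:
                try:
                    rel = reliability.percent_trials_with_response(
                        train, events, fit, config.baseline_offset
                    )
                    row[f"P_raw_{label}"] = rel.P_raw
                    row[f"P_BL_{label}"] = rel.P_BL
                    row[f"percent_responding_{label}"] = rel.P_Rtrial
                except ValueError:
                    row[f"percent_responding_{label}"] = None
        rows.append((row, fit_tw, fit_wk))
    return rows


def region_pair_correlograms(session: Session, event_trains: dict,
                             config: AnalysisConfig, fits: dict,
                             max_pairings: Optional[int] = 20000):
    """Summed corrected correlograms for each (M1, partner-region) pair."""
    out = {}
    m1 = [t for t in session.spikes if t.region == "M1"]
    for region in ("S1", "ECN"):
        partners = [t for t in session.spikes if t.region == region]
        if not m1 or not partners:
            continue
        for etype in ("twitch", "wake_movement"):
            events = _pick_events(event_trains, etype)
            if events is None or len(events) < 2:
                continue
            pairs = []
            for ref in m1:
                for partner in partners:
                    if not (fits.get(ref.unit_id) and fits.get(partner.unit_id)):
                        continue
                    pairs.append(
                        xcorr.pair_correlogram(
                            partner, ref, events, config.band_p, config.ref_window,
                            max_pairings=max_pairings, seed=config.seed,
                        )
                    )
            if pairs:
                summed = xcorr.summed_pair_correlogram(pairs, config.band_p)
                out[f"M1-{region}:{etype}"] = summed
    return out


def run_pipeline(session: Session, config: Optional[AnalysisConfig] = None) -> dict:
    """Execute the full analysis on one session; returns the report dict."""
    config = config or AnalysisConfig()
    log = []
    report = {"config": config.to_dict(), "config_hash": config.digest(),
              "seed": config.seed}

    if session.emg:
        states, scored, stage_log = score_session(session, config)
        log.extend(stage_log)
        event_trains = dict(session.event_trains)
        if scored:
            event_trains.update(scored)
        else:
            log.append("behavior: scoring produced no events; using stored events")
    else:
        log.append("behavior: no EMG; stage skipped, using pre-scored events")
        event_trains = dict(session.event_trains)

    if not session.spikes:
        log.append("fit: no spike trains; stage skipped")
        report["log"] = log
        return report

    unit_rows = fit_units(session, event_trains, config)
    table = [row for row, _, _ in unit_rows]
    responsive = {
        row["unit"]: row["class"] != "unresponsive" for row, _, _ in unit_rows
    }
    summary = psth_mod.population_summary([row["class"] for row in table])
    twitches = _pick_events(event_trains, "twitch")
    wakes = _pick_events(event_trains, "wake_movement")
    report["units"] = table
    report["population"] = {
        "N_total": summary.N_total,
        "counts": summary.counts,
        "P_R_total": summary.P_R_total,
        "pct_among_responsive": summary.pct_among_responsive,
        "pct_twitch_inclusive": summary.pct_twitch_inclusive,
        "pct_wake_inclusive": summary.pct_wake_inclusive,
        "n_twitches": len(twitches) if twitches is not None else 0,
        "n_wake_movements": len(wakes) if wakes is not None else 0,
    }
    log.append(f"fit: {summary.N_total} units, {summary.counts}")

    xcors = region_pair_correlograms(session, event_trains, config, responsive)
    if xcors:
        report["xcorr"] = {
            name: {
                "peak_lag_s": xcorr.peak_lag(cset),
                "n_pairs": cset.n_pairs,
                "n_significant_bins": int(cset.significant.sum()),
            }
            for name, cset in sorted(xcors.items())
        }
        log.append(f"xcorr: {len(xcors)} region-pair correlograms")
    else:
        log.append("xcorr: no eligible region pairs; stage skipped")

    if session.lfp is not None and twitches is not None and len(twitches):
        evoked = csd_mod.evoked_potential(session.lfp, twitches)
        sink = csd_mod.locate_sink(csd_mod.compute_csd(evoked))
        report["csd"] = {
            "n_events": evoked.n_events,
            "sink_depth_um": None if sink is None else sink[0],
            "sink_time_s": None if sink is None else sink[1],
        }
        log.append("csd: sink localized" if sink else "csd: flat map")
    else:
        log.append("csd: no laminar LFP; stage skipped")

    report["log"] = log
    return report


def write_report(report: dict, json_path, csv_path=None) -> None:
    """Write the JSON report (sorted keys -> byte-stable) and unit CSV."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    if csv_path is not None and "units" in report:
        pd.DataFrame(report["units"]).to_csv(csv_path, index=False)
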