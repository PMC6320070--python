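"""Session storage: HDF5 session store, events CSV, and deposit adapters.

The session store keeps one recording per file, all times in seconds on the
session clock (0-based float64), intervals half-open:

    /meta            attrs: duration, plus free-form metadata
    /emg/<muscle>    dataset samples; attrs fs, t0
    /spikes/<unit>   dataset times;   attrs region, span, depth (optional)
    /events/<name>   dataset times;   attrs type, muscle
    /states          (n, 2) dataset;  attr labels (one state per row)
    /lfp             (sites, samples) dataset; attrs depths_um, fs
    /truth           attr json (generating parameters, when synthetic)

Events travel additionally as CSV with header ``time_s,type,muscle``
(UTF-8, '.' decimal).
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .types import EMGChannel, EventTrain, LaminarLFP, SpikeTrain, StateIntervals


@dataclass
class Session:
    """In-memory view of one session (simulated or loaded)."""

    duration: float
    emg: dict = field(default_factory=dict)  # muscle -> EMGChannel
    spikes: list = field(default_factory=list)  # of SpikeTrain
    event_trains: dict = field(default_factory=dict)  # name -> EventTrain
    states: Optional[StateIntervals] = None
    lfp: Optional[LaminarLFP] = None
    truth: Optional[dict] = None
    meta: dict = field(default_factory=dict)


def _bundle_to_session(bundle) -> Session:
    truth = None
    if bundle.truth is not None:
        truth = {
            "seed": bundle.truth.get("seed"),
            "neuron_params": [
                dataclasses.asdict(p) for p in bundle.truth.get("neuron_params", [])
            ],
        }
    return Session(
        duration=bundle.config.session_duration,
        emg=bundle.emg,
        spikes=bundle.spikes,
        event_trains=bundle.event_trains,
        states=bundle.states,
        lfp=bundle.lfp,
        truth=truth,
    )


def as_session(bundle) -> Session:
    """View a simulator bundle as a Session for the analysis pipeline."""
    return _bundle_to_session(bundle)


def write_session(session, path) -> None:
    """Write a Session (or a simulator bundle) to an HDF5 session store."""
    if not isinstance(session, Session):
        session = _bundle_to_session(session)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["duration"] = float(session.duration)
        for k, v in session.meta.items():
            meta.attrs[k] = v
        g = f.create_group("emg")
        for muscle, ch in session.emg.items():
            d = g.create_dataset(muscle, data=ch.samples)
            d.attrs["fs"] = ch.fs
            d.attrs["t0"] = ch.t0
        g = f.create_group("spikes")
        for train in session.spikes:
            d = g.create_dataset(train.unit_id, data=train.times)
            d.attrs["region"] = train.region
            d.attrs["span"] = [train.span[0], min(train.span[1], session.duration)]
            if train.depth is not None:
                d.attrs["depth"] = train.depth
        g = f.create_group("events")
        for name, train in session.event_trains.items():
            d = g.create_dataset(name, data=train.times)
            d.attrs["type"] = train.type
            d.attrs["muscle"] = train.muscle
        if session.states is not None:
            rows = np.array([(s, e) for s, e, _ in session.states.intervals])
            d = f.create_dataset("states", data=rows.reshape(-1, 2))
            d.attrs["labels"] = [st for _, _, st in session.states.intervals]
        if session.lfp is not None:
            d = f.create_dataset("lfp", data=session.lfp.series)
            d.attrs["depths_um"] = session.lfp.site_depths
            d.attrs["fs"] = session.lfp.fs
        if session.truth is not None:
            f.create_group("truth").attrs["json"] = json.dumps(session.truth)


def read_session(path) -> Session:
    with h5py.File(path, "r") as f:
        meta = dict(f["meta"].attrs)
        duration = float(meta.pop("duration"))
        session = Session(duration=duration, meta=meta)
        for muscle, d in f.get("emg", {}).items():
            session.emg[muscle] = EMGChannel(
                muscle, float(d.attrs["fs"]), d[...], float(d.attrs.get("t0", 0.0))
            )
        for unit, d in f.get("spikes", {}).items():
            depth = d.attrs.get("depth")
            span = tuple(d.attrs.get("span", (0.0, duration)))
            session.spikes.append(
                SpikeTrain(unit, d[...], str(d.attrs["region"]), span,
                           float(depth) if depth is not None else None)
            )
        session.spikes.sort(key=lambda s: s.unit_id)
        for name, d in f.get("events", {}).items():
            session.event_trains[name] = EventTrain(
                str(d.attrs["type"]), d[...], str(d.attrs.get("muscle", ""))
            )
        if "states" in f:
            rows = f["states"][...]
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["states"].attrs["labels"]
            ]
            session.states = StateIntervals(
                [(float(r[0]), float(r[1]), lab) for r, lab in zip(rows, labels)]
            )
        if "lfp" in f:
            d = f["lfp"]
            session.lfp = LaminarLFP(d.attrs["depths_um"][...], float(d.attrs["fs"]), d[...])
        if "truth" in f:
            session.truth = json.loads(f["truth"].attrs["json"])
    return session


# ---------------------------------------------------------------------------
# events CSV
# ---------------------------------------------------------------------------

def write_events_csv(event_trains, path) -> None:
    """Events CSV with header time_s,type,muscle, sorted by time."""
    trains = event_trains.values() if isinstance(event_trains, dict) else event_trains
    rows = []
    for train in trains:
        for t in train.times:
            rows.append((float(t), train.type, train.muscle))
    df = pd.DataFrame(rows, columns=["time_s", "type", "muscle"]).sort_values(
        ["time_s", "type"], kind="stable"
    )
    df.to_csv(path, index=False)


def read_events_csv(path) -> dict:
    """Events CSV back into {(type, muscle) name: EventTrain}."""
    df = pd.read_csv(path)
    missing = {"time_s", "type", "muscle"} - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    df["muscle"] = df["muscle"].fillna("")
    out = {}
    for (etype, muscle), grp in df.groupby(["type", "muscle"], sort=True):
        name = f"{etype}_{muscle}" if muscle else etype
        out[name] = EventTrain(etype, np.sort(grp["time_s"].to_numpy()), muscle)
    return out


# ---------------------------------------------------------------------------
# deposit adapter
# ---------------------------------------------------------------------------

def read_timecode_deposit(path) -> Session:
    """Adapter for a per-animal timecode deposit (spike and event CSVs).

    Accepts a directory of CSV files.  A file with a ``unit`` column is
    treated as spike timecodes (columns: unit, time_s, optional region);
    a file with a ``type`` column as behavioral event timecodes (columns:
    time_s, type, optional muscle).  Unrecognized files are logged and kept
    out of the session rather than dropped silently.  The layout is isolated
    behind this single function so only it changes once a real deposit's
    schema is inspected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"deposit path not found: {path}")
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no CSV files in deposit: {path}")
    spikes, events = [], {}
    duration = 0.0
    for fp in files:
        try:
            df = pd.read_csv(fp)
        except Exception as exc:  # pragma: no cover - defensive
            raise IOError(f"unreadable deposit file {fp.name}: {exc}") from exc
        if "time_s" not in df.columns:
            warnings.warn(f"deposit file {fp.name} has no time_s column; skipped")
            continue
        duration = max(duration, float(df["time_s"].max() or 0.0))
        if "unit" in df.columns:
            for unit, grp in df.groupby("unit", sort=True):
                region = str(grp["region"].iloc[0]) if "region" in grp else "M1"
                spikes.append(
                    SpikeTrain(str(unit), np.sort(grp["time_s"].to_numpy()), region)
                )
        elif "type" in df.columns:
            if "muscle" not in df.columns:
                df = df.assign(muscle="")
            for name, train in read_events_csv(fp).items():
                events[name] = train
        else:
            warnings.warn(f"deposit file {fp.name} not recognized; skipped")
    if not events:
        warnings.warn("deposit contains no behavioral event timecodes")
    return Session(
        duration=float(np.ceil(duration)), spikes=spikes, event_trains=events
    )
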