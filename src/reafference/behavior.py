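"""Behavioral state scoring and movement detection from EMG envelopes.

The scoring conventions: EMG is rectified and smoothed with a causal
exponential moving average (0.001 s for the twitch path, 0.01 s for the wake
path); sleep/wake is dichotomized on the nuchal envelope; twitches are
threshold crossings at 3x the atonia baseline with a 300 ms per-muscle
refractory; wake movements must stay above 5x the wake baseline for at least
300 ms after a period of low tone, and only the first movement of a wake
bout is used as a trigger.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import EMGChannel, Envelope, EventTrain, SpikeTrain, StateIntervals


def rectify_smooth(emg: EMGChannel, tau: float) -> Envelope:
    """Absolute value followed by a causal EMA with time constant ``tau``.

    The per-sample decay factor is exp(-1/(fs*tau)), the discrete analogue of
    a first-order RC smoother (Spike2-style "smooth" semantics).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.abs(emg.samples)
    if x.size == 0:
        return Envelope(emg.fs, x, tau, emg.t0, emg.muscle)
    from scipy.signal import lfilter

    decay = np.exp(-1.0 / (emg.fs * tau))
    alpha = 1.0 - decay
    # y[n] = decay*y[n-1] + alpha*x[n], seeded at the first rectified sample
    y = lfilter([alpha], [1.0, -decay], x, zi=[decay * x[0]])[0]
    return Envelope(emg.fs, y, tau, emg.t0, emg.muscle)


def _runs(mask: np.ndarray):
    """(start_idx, end_idx) of True runs, end exclusive."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts, ends))


def classify_states(
    envelope: Envelope,
    min_bout: float = 5.0,
    bimodality_ratio: float = 1.5,
    hysteresis: float = 0.10,
) -> StateIntervals:
    """Dichotomize muscle tone into wake (high tone) and active sleep (atonia).

    The threshold is the midpoint of the envelope's 20th and 80th percentiles,
    applied with +-``hysteresis`` hysteresis; runs shorter than ``min_bout``
    are merged into their neighbors.  A flat envelope (80th/20th percentile
    ratio below ``bimodality_ratio``) is unscorable.
    """
    v = envelope.values
    if v.size == 0:
        raise ValueError("envelope is empty")
    p20, p80 = np.percentile(v, [20, 80])
    if p20 <= 0 or p80 / p20 < bimodality_ratio:
        span = v.size / envelope.fs
        return StateIntervals(
            [(envelope.t0, envelope.t0 + span, "unscored")], unscorable=True
        )
    thr = 0.5 * (p20 + p80)
    hi, lo = thr * (1.0 + hysteresis), thr * (1.0 - hysteresis)

    # hysteresis state machine, vectorized as a forward fill of crossings
    marks = np.zeros(v.size, dtype=np.int8)
    marks[v >= hi] = 1
    marks[v <= lo] = -1
    nz = np.flatnonzero(marks)
    state = np.empty(v.size, dtype=np.int8)
    if nz.size == 0:
        state[:] = 1 if v[0] >= thr else -1
    else:
        # forward fill from the last decisive sample; backfill the leading gap
        pos = np.maximum.accumulate(np.where(marks != 0, np.arange(v.size), -1))
        state = np.where(pos >= 0, marks[np.maximum(pos, 0)], marks[nz[0]])

    wake = state > 0
    runs = [(s, e, bool(wake[s])) for s, e in _runs(wake)] + [
        (s, e, False) for s, e in _runs(~wake)
    ]
    runs.sort()
    # merge runs shorter than min_bout into the previous run (or next, at the start)
    min_n = int(round(min_bout * envelope.fs))
    merged = []
    for s, e, is_wake in runs:
        if merged and (e - s < min_n or merged[-1][2] == is_wake):
            ps, pe, pw = merged[-1]
            merged[-1] = (ps, e, pw)
        elif not merged and e - s < min_n and len(runs) > 1:
            # absorb a short leading run into the following one
            merged.append((s, e, runs[1][2]))
        else:
            merged.append((s, e, is_wake))
    # coalesce neighbors that ended up with the same state
    coalesced = []
    for s, e, w in merged:
        if coalesced and coalesced[-1][2] == w:
            coalesced[-1] = (coalesced[-1][0], e, w)
        else:
            coalesced.append([s, e, w])

    fs, t0 = envelope.fs, envelope.t0
    intervals = [
        (t0 + s / fs, t0 + e / fs, "wake" if w else "active_sleep")
        for s, e, w in coalesced
    ]
    return StateIntervals(intervals)


def detect_twitches(
    envelope: Envelope,
    states: StateIntervals,
    mult: float = 3.0,
    refractory: float = 0.3,
) -> EventTrain:
    """Twitch onsets: threshold crossings during active sleep.

    Baseline is the median envelope within active-sleep atonia (robust to the
    bursts themselves); the threshold is ``mult`` x baseline.  The event time
    is the first sample at which the envelope exceeds the threshold, and a
    subsequent event of the same muscle is accepted only if it occurs at
    least ``refractory`` later.
    """
    as_iv = states.of_state("active_sleep")
    if as_iv.size == 0:
        warnings.warn("no active-sleep intervals; returning empty twitch train")
        return EventTrain("twitch", np.empty(0), envelope.muscle)
    t = envelope.times
    v = envelope.values
    in_as = np.zeros(v.size, dtype=bool)
    for start, end in as_iv:
        i0, i1 = np.searchsorted(t, (start, end))
        in_as[i0:i1] = True
    baseline = float(np.median(v[in_as]))
    thr = mult * baseline
    above = v > thr
    crossings = np.flatnonzero(above & ~np.r_[False, above[:-1]] & in_as)
    kept = []
    last = -np.inf
    for i in crossings:
        ti = t[i]
        if ti - last >= refractory:
            kept.append(ti)
            last = ti
    return EventTrain("twitch", np.asarray(kept), envelope.muscle)


@dataclass
class WakeMovements:
    """Triggers (first movement per wake bout) plus all scored movements."""

    triggers: EventTrain
    scored: EventTrain
    baseline: float
    threshold: float


def detect_wake_movements(
    envelope: Envelope,
    states: StateIntervals,
    mult: float = 5.0,
    sustain: float = 0.3,
    quiescence: float = 1.0,
) -> WakeMovements:
    """Wake movements: sustained supra-threshold runs during wake.

    The wake baseline is the median wake-state envelope outside
    supra-threshold runs (computed iteratively once: a provisional median
    sets a provisional threshold, whose runs are excluded before the final
    median).  A scored movement is a run staying above threshold for at
    least ``sustain`` seconds during wake; its time is the first sample of
    the run.  Movements cluster into movement bouts, and only the first of
    a bout — a movement additionally preceded by at least ``quiescence``
    seconds of sub-threshold tone — is used as a trigger, so trigger counts
    underestimate scored counts.
    """
    wake_iv = states.of_state("wake")
    empty = EventTrain("wake_movement", np.empty(0), envelope.muscle)
    if wake_iv.size == 0:
        warnings.warn("no wake intervals; returning empty wake-movement train")
        return WakeMovements(empty, empty, np.nan, np.nan)
    t = envelope.times
    v = envelope.values
    in_wake = np.zeros(v.size, dtype=bool)
    for start, end in wake_iv:
        i0, i1 = np.searchsorted(t, (start, end))
        in_wake[i0:i1] = True

    prov_base = float(np.median(v[in_wake]))
    prov_thr = mult * prov_base
    quiet = in_wake & (v <= prov_thr)
    if not quiet.any():
        baseline = prov_base
    else:
        baseline = float(np.median(v[quiet]))
    thr = mult * baseline

    above = v > thr
    n_sustain = int(round(sustain * envelope.fs))
    n_quiet = int(round(quiescence * envelope.fs))
    scored_times, trigger_times = [], []
    for s, e in _runs(above):
        if e - s < n_sustain or not in_wake[s]:
            continue
        scored_times.append(t[s])
        # first movement of a movement bout: preceded by low tone
        q0 = s - n_quiet
        if q0 >= 0 and not np.any(above[q0:s]):
            trigger_times.append(t[s])
    scored = EventTrain("wake_movement", np.asarray(scored_times), envelope.muscle)
    triggers = EventTrain("wake_movement", np.asarray(trigger_times), envelope.muscle)
    return WakeMovements(triggers, scored, baseline, thr)


def mask_artifact_windows(
    spikes: SpikeTrain, burst_events, half_width: float = 0.1
):
    """Drop spikes within +-``half_width`` of any artifact burst.

    Returns (masked_train, n_removed).  Used after pharmacological
    disinhibition, where synchronized population bursts occasionally
    contaminate the recording.
    """
    bursts = np.asarray(burst_events, dtype=float).ravel()
    if bursts.size == 0 or len(spikes) == 0:
        return spikes, 0
    idx = np.searchsorted(bursts, spikes.times)
    near_prev = np.where(idx > 0, spikes.times - bursts[np.maximum(idx - 1, 0)], np.inf)
    near_next = np.where(
        idx < bursts.size, bursts[np.minimum(idx, bursts.size - 1)] - spikes.times, np.inf
    )
    masked = np.minimum(near_prev, near_next) <= half_width
    out = SpikeTrain(
        spikes.unit_id, spikes.times[~masked], spikes.region, spikes.span, spikes.depth
    )
    return out, int(masked.sum())
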