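"""Synthetic sleep-wake sessions with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: alternating active-sleep/wake bouts, myoclonic twitches during
atonia with a per-muscle 300 ms refractory, wake-movement bouts during high
tone, spike trains that are inhomogeneous Poisson with event-locked Gaussian
(twitch) or Gaussian-rise/exponential-decay (wake) rate kernels, EMG
envelopes whose bursts exceed the detection thresholds the scorer applies,
and laminar LFPs whose exact second spatial difference is a dipole.

Spike generation uses Lewis-Shedler thinning, so realized counts can be
checked against the integrated rate function.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import EMGChannel, EventTrain, LaminarLFP, SpikeTrain, StateIntervals

_SQ2LN2 = np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NeuronParams:
    """Generating parameters for one simulated unit.

    ``decay_time`` is the exponential decay time constant of the wake kernel
    in seconds (the kernel's rate constant is 1/decay_time).
    """

    BL: float  # sps
    R_max: float  # sps above baseline at the kernel peak
    t_max: float  # s, kernel peak latency after the event
    c: float  # s, Gaussian width (HWHH = sqrt(2 ln 2) * c)
    decay_time: float = 0.25  # s, wake-kernel decay constant
    response_type: str = "twitch"  # twitch | wake | both | none

    def __post_init__(self):
        if self.BL < 0 or self.R_max < 0:
            raise ValueError("BL and R_max must be nonnegative")
        if self.c <= 0 or self.decay_time <= 0:
            raise ValueError("c and decay_time must be positive")
        if self.response_type not in ("twitch", "wake", "both", "none"):
            raise ValueError(f"unknown response_type {self.response_type!r}")


@dataclass
class EMGParams:
    baseline: float = 1.0  # atonia envelope level, arbitrary units
    wake_tone_mult: float = 3.0  # tonic wake envelope as multiple of baseline
    twitch_burst_mult: float = 5.0  # twitch burst peak as multiple of baseline
    twitch_burst_dur: float = 0.075  # s
    wake_burst_mult: float = 6.0  # movement burst peak as multiple of wake tone
    wake_burst_dur: float = 0.4  # s
    noise_sd: float = 0.08  # envelope noise, fraction of baseline


@dataclass
class LFPParams:
    sink_depth: float = 800.0  # µm
    source_offset: float = 300.0  # µm, source lies at sink_depth + offset
    amplitude: float = 1.0  # dipole strength, arbitrary units
    temporal_width: float = 0.03  # s, Gaussian time course width
    peak_latency: float = 0.05  # s after the event
    noise_sd: float = 0.0


def _default_neurons() -> list:
    # Parameter scales follow the P8 medians of the in-vivo fit tables:
    # twitch responders BL 2.12 / R_max 3.86 / t_max 0.194 / HWHH 0.186;
    # wake responders BL 0.63 / R_max 6.70 / t_max 0.199 / HWHH 0.178 with a
    # 0.231 s decay constant.
    c_tw = 0.186 / _SQ2LN2
    c_wk = 0.178 / _SQ2LN2
    return [
        NeuronParams(2.12, 3.86, 0.194, c_tw, response_type="twitch"),
        NeuronParams(2.12, 3.86, 0.194, c_tw, response_type="twitch"),
        NeuronParams(0.63, 6.70, 0.199, c_wk, 0.231, response_type="wake"),
        NeuronParams(0.63, 6.70, 0.199, c_wk, 0.231, response_type="wake"),
        NeuronParams(1.5, 6.7, 0.15, c_wk, 0.231, response_type="both"),
        NeuronParams(2.12, 0.0, 0.194, c_tw, response_type="none"),
        NeuronParams(4.0, 0.0, 0.194, c_tw, response_type="none"),
    ]


@dataclass
class SimConfig:
    """Session-level generating parameters.

    Defaults target a 30 min session in which roughly two-thirds of the time
    is active sleep and the twitch train realizes ~300 events (the scale of
    the youngest-age in-vivo sessions), with ~70 scored wake movements.
    """

    session_duration: float = 1800.0  # s
    as_bout_mean: float = 60.0  # s
    wake_bout_mean: float = 30.0  # s
    min_bout: float = 5.0  # s, floor of the truncated-exponential bout law
    twitch_rate: float = 0.272  # events/s of active sleep, before thinning
    wake_move_rate: float = 0.12  # onsets/s of wake, before thinning
    refractory: float = 0.3  # s, per-muscle event refractory
    neuron_params: list = field(default_factory=_default_neurons)
    emg_params: EMGParams = field(default_factory=EMGParams)
    lfp_params: Optional[LFPParams] = None
    emg_fs: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.session_duration < 0:
            raise ValueError("session_duration must be >= 0")
        if self.twitch_rate < 0 or self.wake_move_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass
class SessionBundle:
    """A complete synthetic session plus the parameters that generated it."""

    config: SimConfig
    states: StateIntervals
    event_trains: dict  # name -> EventTrain
    emg: dict  # muscle -> EMGChannel
    spikes: list  # of SpikeTrain
    lfp: Optional[LaminarLFP]
    truth: dict


# ---------------------------------------------------------------------------
# states and events
# ---------------------------------------------------------------------------

def simulate_states(
    duration: float,
    as_bout_mean: float,
    wake_bout_mean: float,
    seed=None,
    min_bout: float = 5.0,
    start_state: str = "active_sleep",
) -> StateIntervals:
    """Alternating active-sleep/wake bouts tiling [0, duration).

    Bout lengths are ``min_bout`` plus an exponential with scale
    ``mean - min_bout`` (so the configured means are the realized means); the
    final bout is clipped at the session end.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    for m in (as_bout_mean, wake_bout_mean):
        if m <= min_bout:
            raise ValueError("mean bout duration must exceed the minimum bout")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    intervals = []
    t, state = 0.0, start_state
    while t < duration:
        mean = as_bout_mean if state == "active_sleep" else wake_bout_mean
        bout = min_bout + rng.exponential(mean - min_bout)
        end = min(t + bout, duration)
        intervals.append((t, end, state))
        t = end
        state = "wake" if state == "active_sleep" else "active_sleep"
    return StateIntervals(intervals)


def simulate_event_train(
    rate: float,
    intervals: np.ndarray,
    refractory: float = 0.3,
    seed=None,
    event_type: str = "twitch",
    muscle: str = "forelimb",
) -> EventTrain:
    """Homogeneous Poisson events restricted to intervals, refractory-thinned.

    Candidate events are drawn at ``rate`` within each [start, end) interval;
    a candidate is kept only if it falls at least ``refractory`` after the
    last kept event (greedy dead-time thinning), so realized counts fall
    below rate x total time.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    intervals = np.asarray(intervals, dtype=float).reshape(-1, 2)
    candidates = []
    for start, end in intervals:
        n = rng.poisson(rate * (end - start))
        if n:
            candidates.append(rng.uniform(start, end, size=n))
    if not candidates:
        return EventTrain(event_type, np.empty(0), muscle)
    times = np.sort(np.concatenate(candidates))
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            kept.append(t)
            last = t
    return EventTrain(event_type, np.asarray(kept), muscle)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def twitch_kernel(dt, R_max, t_max, c):
    dt = np.asarray(dt, dtype=float)
    return R_max * np.exp(-((dt - t_max) ** 2) / (2.0 * c * c))


def wake_kernel(dt, R_max, t_max, c, decay_time):
    dt = np.asarray(dt, dtype=float)
    rise = R_max * np.exp(-((dt - t_max) ** 2) / (2.0 * c * c))
    fall = R_max * np.exp(-(dt - t_max) / decay_time)
    return np.where(dt <= t_max, rise, fall)


def _kernel_support(params: NeuronParams, kind: str):
    lo = params.t_max - 5.0 * params.c
    if kind == "twitch":
        hi = params.t_max + 5.0 * params.c
    else:
        hi = params.t_max + 12.0 * params.decay_time
    return lo, hi


def rate_function(t, params: NeuronParams, twitch_times=None, wake_times=None):
    """lambda(t) = BL + sum of event-locked kernels; vectorized over sorted t."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(params.BL))
    jobs = []
    if params.response_type in ("twitch", "both") and twitch_times is not None:
        jobs.append(("twitch", np.asarray(twitch_times, dtype=float)))
    if params.response_type in ("wake", "both") and wake_times is not None:
        jobs.append(("wake", np.asarray(wake_times, dtype=float)))
    for kind, events in jobs:
        lo, hi = _kernel_support(params, kind)
        for te in events:
            i0, i1 = np.searchsorted(t, (te + lo, te + hi))
            if i1 <= i0:
                continue
            dt = t[i0:i1] - te
            if kind == "twitch":
                out[i0:i1] += twitch_kernel(dt, params.R_max, params.t_max, params.c)
            else:
                out[i0:i1] += wake_kernel(
                    dt, params.R_max, params.t_max, params.c, params.decay_time
                )
    return out


def _rate_bound(params: NeuronParams, refractory: float) -> float:
    """Upper bound on lambda(t) given the per-train event refractory."""
    bound = params.BL
    refractory = max(refractory, 1e-3)
    if params.response_type in ("twitch", "both"):
        lo, hi = _kernel_support(params, "twitch")
        bound += params.R_max * (np.floor((hi - lo) / refractory) + 1)
    if params.response_type in ("wake", "both"):
        lo, hi = _kernel_support(params, "wake")
        bound += params.R_max * (np.floor((hi - lo) / refractory) + 1)
    return float(bound)


def simulate_spike_train(
    params: NeuronParams,
    duration: float,
    twitch_times=None,
    wake_times=None,
    seed=None,
    unit_id: str = "u0",
    region: str = "M1",
    refractory: float = 0.3,
    depth: Optional[float] = None,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes via Lewis-Shedler thinning.

    Candidates are drawn homogeneously at an analytic upper bound on the rate
    and accepted with probability lambda(t)/bound, which makes the realized
    process exactly inhomogeneous Poisson with the event-locked rate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bound = _rate_bound(params, refractory)
    if bound <= 0 or duration <= 0:
        return SpikeTrain(unit_id, np.empty(0), region, (0.0, duration), depth)
    n = rng.poisson(bound * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    lam = rate_function(cand, params, twitch_times, wake_times)
    keep = rng.uniform(0.0, bound, size=n) < lam
    return SpikeTrain(unit_id, cand[keep], region, (0.0, duration), depth)


def integrated_rate(params: NeuronParams, duration, twitch_times=None, wake_times=None, dt=0.001):
    """Numerical integral of the rate function (oracle for count checks)."""
    grid = np.arange(0.0, duration, dt)
    return float(np.sum(rate_function(grid, params, twitch_times, wake_times)) * dt)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _add_burst(env, fs, onset, peak_add, dur, rise=0.005):
    """Additive burst: linear rise to peak_add, hold, linear fall."""
    n = env.size
    i0 = int(round(onset * fs))
    n_rise = max(int(round(rise * fs)), 1)
    n_hold = max(int(round(dur * fs)) - n_rise, 1)
    n_fall = n_rise
    shape = np.concatenate(
        [
            np.linspace(0.0, 1.0, n_rise, endpoint=False),
            np.ones(n_hold),
            np.linspace(1.0, 0.0, n_fall),
        ]
    )
    i1 = min(i0 + shape.size, n)
    if i0 < n:
        env[i0:i1] += peak_add * shape[: i1 - i0]


def simulate_emg(
    states: StateIntervals,
    duration: float,
    emg_params: EMGParams,
    fs: float = 1000.0,
    twitch_times=None,
    wake_move_times=None,
    seed=None,
    muscle: str = "forelimb",
) -> EMGChannel:
    """EMG modeled as its rectified envelope times a random sign.

    The envelope is baseline during atonia, tonically elevated during wake,
    with short twitch bursts (peak = twitch_burst_mult x baseline) and
    sustained movement bursts (peak = wake_burst_mult x wake tone, duration
    >= 300 ms).  Detection operates on envelopes, so raw-waveform realism is
    deliberately not modeled.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    p = emg_params
    env = np.full(n, p.baseline)
    t = np.arange(n) / fs
    for start, end, state in states.intervals:
        if state == "wake":
            i0, i1 = np.searchsorted(t, (start, end))
            env[i0:i1] = p.baseline * p.wake_tone_mult
    if twitch_times is not None:
        for te in np.asarray(twitch_times, dtype=float):
            _add_burst(env, fs, te, (p.twitch_burst_mult - 1.0) * p.baseline, p.twitch_burst_dur)
    if wake_move_times is not None:
        tone = p.baseline * p.wake_tone_mult
        for te in np.asarray(wake_move_times, dtype=float):
            _add_burst(env, fs, te, (p.wake_burst_mult - 1.0) * tone, p.wake_burst_dur)
    env = env + np.abs(rng.normal(0.0, p.noise_sd * p.baseline, size=n))
    signs = rng.choice((-1.0, 1.0), size=n)
    return EMGChannel(muscle, fs, env * signs)


# ---------------------------------------------------------------------------
# coupled pairs and laminar LFP
# ---------------------------------------------------------------------------

def simulate_coupled_pair(
    base_params: NeuronParams,
    duration: float,
    twitch_times=None,
    wake_times=None,
    lag: float = 0.015,
    coupling_prob: float = 0.3,
    jitter: float = 0.0005,
    seed=None,
    region_a: str = "M1",
    region_b: str = "S1",
):
    """Two trains sharing stimulus locking, with direct coupling from A to B.

    Train A is an event-locked inhomogeneous Poisson train.  Train B is an
    independent train with the same generating parameters, plus copies of A's
    spikes shifted by ``lag`` (B lags A for positive lag) with jitter,
    each retained with probability ``coupling_prob``.
    """
    if not 0.0 <= coupling_prob <= 1.0:
        raise ValueError("coupling_prob must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = simulate_spike_train(
        base_params, duration, twitch_times, wake_times, seed=rng, unit_id="A", region=region_a
    )
    b_own = simulate_spike_train(
        base_params, duration, twitch_times, wake_times, seed=rng, unit_id="B", region=region_b
    )
    times_b = b_own.times
    if coupling_prob > 0 and len(a):
        keep = rng.uniform(size=len(a)) < coupling_prob
        copies = a.times[keep] + lag + rng.uniform(-jitter, jitter, size=int(keep.sum()))
        copies = copies[(copies >= 0) & (copies <= duration)]
        times_b = np.sort(np.concatenate([times_b, copies]))
    b = SpikeTrain("B", times_b, region_b, (0.0, duration))
    return a, b


def simulate_laminar_lfp(
    lfp_params: LFPParams,
    events,
    duration: float,
    n_sites: int = 16,
    spacing: float = 100.0,
    fs: float = 1000.0,
    seed=None,
    depth0: float = 100.0,
) -> LaminarLFP:
    """Laminar LFP whose exact second spatial difference is a dipole.

    A delta dipole (sink at ``sink_depth``, source at sink + offset) is
    imposed as the discrete CSD profile; the potential profile is recovered
    by solving the padded discrete Poisson equation, so the downstream CSD
    operator reproduces the dipole exactly in the noiseless case.  Each event
    contributes a Gaussian time course peaking ``peak_latency`` after it.
    """
    if n_sites < 3:
        raise ValueError("n_sites must be >= 3")
    p = lfp_params
    depths = depth0 + spacing * np.arange(n_sites)
    if not (depths[0] <= p.sink_depth <= depths[-1]):
        raise ValueError("sink depth outside probe span")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    sink_site = int(np.argmin(np.abs(depths - p.sink_depth)))
    source_site = int(np.argmin(np.abs(depths - (p.sink_depth + p.source_offset))))
    if source_site == sink_site:
        source_site = min(sink_site + 1, n_sites - 1)
    c_profile = np.zeros(n_sites)
    c_profile[sink_site] = -p.amplitude
    c_profile[source_site] += p.amplitude

    # CSD_i = -(V[i-1] - 2 V[i] + V[i+1]) / dz^2 with duplicated end sites;
    # invert that operator (singular up to a constant -> least squares).
    dz2 = spacing * spacing
    lap = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        for j, w in ((i - 1, 1.0), (i, -2.0), (i + 1, 1.0)):
            lap[i, min(max(j, 0), n_sites - 1)] += w
    v_profile, *_ = np.linalg.lstsq(-lap / dz2, c_profile, rcond=None)
    v_profile -= v_profile.mean()

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    drive = np.zeros(n)
    for te in np.asarray(events, dtype=float):
        center = te + p.peak_latency
        i0, i1 = np.searchsorted(t, (center - 5 * p.temporal_width, center + 5 * p.temporal_width))
        drive[i0:i1] += np.exp(-((t[i0:i1] - center) ** 2) / (2.0 * p.temporal_width**2))
    series = np.outer(v_profile, drive)
    if p.noise_sd > 0:
        series = series + rng.normal(0.0, p.noise_sd, size=series.shape)
    return LaminarLFP(depths, fs, series)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def first_event_per_bout(events: EventTrain, bouts: np.ndarray) -> EventTrain:
    """Keep the first event falling in each [start, end) bout."""
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    kept = []
    for start, end in bouts:
        in_bout = events.times[(events.times >= start) & (events.times < end)]
        if in_bout.size:
            kept.append(in_bout[0])
    return EventTrain(events.type, np.asarray(kept), events.muscle)


def simulate_session(config: SimConfig) -> SessionBundle:
    """Generate a full session: states, events, EMG, spikes, optional LFP."""
    rng = np.random.default_rng(config.seed)
    duration = config.session_duration
    states = simulate_states(
        duration, config.as_bout_mean, config.wake_bout_mean, seed=rng, min_bout=config.min_bout
    )
    as_iv = states.of_state("active_sleep")
    wake_iv = states.of_state("wake")

    twitch_fl = simulate_event_train(
        config.twitch_rate, as_iv, config.refractory, rng, "twitch", "forelimb"
    )
    twitch_nu = simulate_event_train(
        config.twitch_rate * 0.7, as_iv, config.refractory, rng, "twitch", "nuchal"
    )
    # movement onsets separated enough that each opens its own movement bout
    # (>= 1 s of low tone before the burst), so every onset is a trigger
    move_gap = config.emg_params.wake_burst_dur + 1.5
    moves = simulate_event_train(
        config.wake_move_rate, wake_iv, move_gap, rng, "wake_movement", "forelimb"
    )
    triggers = moves

    emg = {
        "nuchal": simulate_emg(
            states, duration, config.emg_params, config.emg_fs,
            twitch_times=twitch_nu.times, seed=rng, muscle="nuchal",
        ),
        "forelimb": simulate_emg(
            states, duration, config.emg_params, config.emg_fs,
            twitch_times=twitch_fl.times, wake_move_times=moves.times,
            seed=rng, muscle="forelimb",
        ),
    }

    spikes = []
    for i, params in enumerate(config.neuron_params):
        spikes.append(
            simulate_spike_train(
                params, duration,
                twitch_times=twitch_fl.times, wake_times=triggers.times,
                seed=rng, unit_id=f"u{i}", region="M1", refractory=config.refractory,
            )
        )

    lfp = None
    if config.lfp_params is not None:
        lfp = simulate_laminar_lfp(
            config.lfp_params, twitch_fl.times, duration, fs=config.emg_fs, seed=rng
        )

    event_trains = {
        "twitch_forelimb": twitch_fl,
        "twitch_nuchal": twitch_nu,
        "wake_movement_forelimb": triggers,
        "wake_movement_scored_forelimb": moves,
    }
    truth = {
        "neuron_params": list(config.neuron_params),
        "seed": config.seed,
    }
    return SessionBundle(config, states, event_trains, emg, spikes, lfp, truth)
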