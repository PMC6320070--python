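"""Core containers shared across the pipeline.

All times are seconds on the session clock (0-based, float64); intervals are
half-open ``[start, end)``.  Containers are plain dataclasses holding numpy
arrays: cheap to construct, easy to serialize, and explicit about invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EVENT_TYPES = ("twitch", "wake_movement", "exafferent_stim", "burst_artifact")
STATES = ("active_sleep", "wake", "unscored")
REGIONS = ("M1", "S1", "ECN")


def _as_times(x) -> np.ndarray:
    t = np.asarray(x, dtype=float).ravel()
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    return t


@dataclass
class EMGChannel:
    """Raw EMG voltage trace for one muscle."""

    muscle: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Envelope:
    """Rectified, smoothed EMG (nonnegative), with the smoothing constant kept."""

    fs: float
    values: np.ndarray
    tau: float
    t0: float = 0.0
    muscle: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size and self.values.min() < 0:
            raise ValueError("envelope values must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class StateIntervals:
    """Ordered, non-overlapping behavioral-state intervals."""

    intervals: list  # of (start, end, state)
    unscorable: bool = False

    def __post_init__(self):
        prev_end = -np.inf
        for start, end, state in self.intervals:
            if not start < end:
                raise ValueError("interval start must precede end")
            if start < prev_end:
                raise ValueError("intervals must be ordered and non-overlapping")
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            prev_end = end

    def of_state(self, state: str) -> np.ndarray:
        """(n, 2) array of [start, end) for one state."""
        rows = [(s, e) for s, e, st in self.intervals if st == state]
        return np.asarray(rows, dtype=float).reshape(-1, 2)

    def total(self, state: str) -> float:
        iv = self.of_state(state)
        return float(np.sum(iv[:, 1] - iv[:, 0])) if iv.size else 0.0

    def state_at(self, times) -> np.ndarray:
        """State label for each query time ('unscored' outside any interval)."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, "unscored", dtype=object)
        for start, end, state in self.intervals:
            out[(times >= start) & (times < end)] = state
        return out.astype(str)


@dataclass
class EventTrain:
    """Timestamped behavioral events of a single type for one muscle."""

    type: str
    times: np.ndarray
    muscle: str = ""

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        self.times = _as_times(self.times)

    def __len__(self):
        return self.times.size

    def min_gap(self) -> float:
        return float(np.min(np.diff(self.times))) if len(self) > 1 else np.inf


@dataclass
class SpikeTrain:
    """Sorted spike times of one isolated unit."""

    unit_id: str
    times: np.ndarray
    region: str = "M1"
    span: tuple = (0.0, np.inf)
    depth: Optional[float] = None  # µm, for laminar recordings

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        self.times = _as_times(self.times)
        lo, hi = self.span
        if self.times.size and (self.times[0] < lo or self.times[-1] > hi):
            raise ValueError("spike times outside recording span")

    def __len__(self):
        return self.times.size

    @property
    def rate(self) -> float:
        lo, hi = self.span
        dur = hi - lo
        return len(self) / dur if np.isfinite(dur) and dur > 0 else np.nan


@dataclass
class Psth:
    """Perievent histogram: mean firing rate (sps) on a fixed bin grid.

    The default grid is the analysis convention: a 2 s window centered on the
    event, 10 ms bins, i.e. 201 edges spanning [-1.0, +1.0).
    """

    bin_edges: np.ndarray
    rates: np.ndarray
    n_events: int
    event_type: str = "twitch"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.size != self.bin_edges.size - 1:
            raise ValueError("rates must have one entry per bin")
        if self.rates.size and self.rates.min() < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ResponseFit:
    """Fitted perievent response model with fit-quality bookkeeping.

    ``model`` is 'gaussian' (symmetric response, 4 parameters) or 'gauss_exp'
    (Gaussian rise, exponential fall, 5 parameters).  Derived widths:
    HWHH = sqrt(2 ln 2) * c and t_half = ln 2 / lam.
    """

    model: str
    BL: float
    R_max: float
    t_max: float
    c: float
    lam: Optional[float]  # 1/s; gauss_exp only
    SSE: float
    SST: float
    n: int
    p: int
    r2_adj: float
    degenerate: bool = False

    @property
    def HWHH(self) -> float:
        return float(np.sqrt(2.0 * np.log(2.0)) * self.c)

    @property
    def t_half(self) -> Optional[float]:
        if self.lam is None:
            return None
        return float(np.log(2.0) / self.lam)

    def predict(self, t) -> np.ndarray:
        from .psth import gaussian_model, gauss_exp_model

        t = np.asarray(t, dtype=float)
        if self.model == "gaussian":
            return gaussian_model(t, self.BL, self.R_max, self.t_max, self.c)
        return gauss_exp_model(t, self.BL, self.R_max, self.t_max, self.c, self.lam)


@dataclass
class NeuronClass:
    """Four-way responsivity classification of one unit."""

    r2_twitch: float
    r2_wake: float
    threshold: float = 0.35
    # class label in {unresponsive, twitch, wake, twitch_and_wake}
    label: str = field(init=False)

    def __post_init__(self):
        tw = self.r2_twitch > self.threshold
        wk = self.r2_wake > self.threshold
        self.label = {
            (False, False): "unresponsive",
            (True, False): "twitch",
            (False, True): "wake",
            (True, True): "twitch_and_wake",
        }[(tw, wk)]


@dataclass
class PopulationSummary:
    N_total: int
    counts: dict  # label -> count
    P_R_total: float  # % responsive of all neurons
    pct_among_responsive: dict  # exclusive label -> % of responsive
    pct_twitch_inclusive: float  # (twitch + both) / responsive, %
    pct_wake_inclusive: float


@dataclass
class ResponseWindow:
    """Model-derived response window relative to the event."""

    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def t_response(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TrialReliability:
    """Per-trial response counts and the baseline-corrected percentage."""

    R_trial: np.ndarray
    R_BL: np.ndarray
    P_raw: float
    P_BL: float
    P_Rtrial: Optional[float]  # %, None when P_BL == 1 (undefined correction)
    n_trials: int
    n_dropped: int  # events lacking 2 s of prior recording


@dataclass
class CorrelogramSet:
    """Raw, shift-predictor, and corrected cross-correlograms on one lag grid."""

    lags: np.ndarray  # bin centers, s
    raw: np.ndarray
    shift_predictor: np.ndarray
    corrected: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_pairs: int = 1
    n_reference_spikes: int = 0

    @property
    def significant(self) -> np.ndarray:
        half = self.band_high - self.shift_predictor
        return np.abs(self.corrected) > half


@dataclass
class LaminarLFP:
    """Voltage series from a single-shank laminar probe."""

    site_depths: np.ndarray  # µm, strictly increasing, uniform spacing
    fs: float
    series: np.ndarray  # (n_sites, n_samples)

    def __post_init__(self):
        self.site_depths = np.asarray(self.site_depths, dtype=float)
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        d = np.diff(self.site_depths)
        if self.site_depths.size >= 2 and (
            np.any(d <= 0) or not np.allclose(d, d[0])
        ):
            raise ValueError("site depths must be strictly increasing and uniform")
        if self.series.shape[0] != self.site_depths.size:
            raise ValueError("one series per site required")

    @property
    def spacing(self) -> float:
        return float(self.site_depths[1] - self.site_depths[0])


@dataclass
class EvokedPotential:
    times: np.ndarray  # s relative to event
    site_depths: np.ndarray
    mean: np.ndarray  # (n_sites, n_times)
    n_events: int
    event_type: str = "twitch"


@dataclass
class CsdMap:
    """Second-spatial-difference map; sinks are negative by convention."""

    times: np.ndarray
    site_depths: np.ndarray
    csd: np.ndarray  # (n_sites, n_times), at probe resolution
    interp_depths: np.ndarray  # 10 µm grid
    csd_interp: np.ndarray  # (n_interp_depths, n_times)
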