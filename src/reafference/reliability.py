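"""Baseline-corrected percentage of movements with a neural response.

For a responsive unit, the fitted model defines a response window per event:
the times at which the model crosses half of its maximum response
(BL + R_max/2).  Per trial, the spike count in that window (R_trial) is
compared with the count expected at baseline (BL * t_response); the same
comparison is run on a matched-duration baseline window starting 2 s before
the movement (R_BL).  The baseline-corrected percentage is

    P(R_trial) = (P_raw - P_BL) / (1 - P_BL) * 100,

which is ~0 for a unit firing homogeneously at baseline and 100 when every
trial (and no baseline window) exceeds the baseline expectation.
"""
from __future__ import annotations

import numpy as np

from .types import ResponseFit, ResponseWindow, SpikeTrain, TrialReliability


def response_window(fit: ResponseFit) -> ResponseWindow:
    """Half-maximum crossing times of the fitted model, relative to the event.

    Gaussian: t_max -+ HWHH.  Gaussian-exponential: the rise crosses at
    t_max - HWHH and the exponential fall at t_max + t_half.
    """
    if fit.R_max <= 0 or fit.degenerate:
        raise ValueError("response window requires a non-degenerate responsive fit")
    if fit.model == "gaussian":
        return ResponseWindow(fit.t_max - fit.HWHH, fit.t_max + fit.HWHH)
    return ResponseWindow(fit.t_max - fit.HWHH, fit.t_max + fit.t_half)


def percent_trials_with_response(
    spikes: SpikeTrain,
    events,
    fit: ResponseFit,
    baseline_offset: float = 2.0,
) -> TrialReliability:
    """Per-trial response counts and the baseline-corrected percentage.

    Events with less than ``baseline_offset`` seconds of preceding recording
    are dropped (the baseline window [-2, -2 + t_response] would be
    unobservable); the dropped count is reported.  All comparisons are
    strict (>).  When every baseline window exceeds expectation (P_BL = 1)
    the correction is undefined and P_Rtrial is reported as missing.
    """
    times = getattr(events, "times", events)
    times = np.asarray(times, dtype=float)
    win = response_window(fit)
    t_resp = win.t_response

    span_start = spikes.span[0] if np.isfinite(spikes.span[0]) else 0.0
    usable = times[times - span_start >= baseline_offset]
    n_dropped = times.size - usable.size
    if usable.size == 0:
        raise ValueError("no usable trials: all events lack 2 s of prior recording")

    r_trial = np.array(
        [
            np.searchsorted(spikes.times, te + win.t_end, side="right")
            - np.searchsorted(spikes.times, te + win.t_start, side="left")
            for te in usable
        ]
    )
    r_bl = np.array(
        [
            np.searchsorted(spikes.times, te - baseline_offset + t_resp, side="right")
            - np.searchsorted(spikes.times, te - baseline_offset, side="left")
            for te in usable
        ]
    )
    expected = fit.BL * t_resp
    p_raw = float(np.mean(r_trial > expected))
    p_bl = float(np.mean(r_bl > expected))
    if p_bl == 1.0:
        p_rtrial = None
    else:
        p_rtrial = (p_raw - p_bl) / (1.0 - p_bl) * 100.0
    return TrialReliability(
        r_trial, r_bl, p_raw, p_bl, p_rtrial, int(usable.size), int(n_dropped)
    )
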