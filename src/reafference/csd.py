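"""Event-triggered evoked potentials and one-dimensional current source density.

Raw laminar waveforms are smoothed (tau = 1 ms) and downsampled to 1 kHz,
averaged across events into sensory evoked potentials, and differentiated
twice across depth:

    CSD_i(t) = -(V_{i-1}(t) - 2 V_i(t) + V_{i+1}(t)) / dz^2

with Vaknin padding (end sites duplicated) so the map covers all sites, and
cubic interpolation to a 10 um depth grid.  Sinks (net inward current,
synaptic input) are negative by convention; conductivity is omitted, so maps
are in arbitrary units.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .types import CsdMap, EvokedPotential, LaminarLFP


def preprocess_lfp(raw: LaminarLFP, tau: float = 0.001, fs_out: float = 1000.0) -> LaminarLFP:
    """Causal exponential smoothing (time constant tau) then decimation."""
    if raw.fs < fs_out:
        raise ValueError("raw sampling rate must be >= target rate")
    from scipy.signal import lfilter

    decay = np.exp(-1.0 / (raw.fs * tau))
    alpha = 1.0 - decay
    smoothed = np.empty_like(raw.series)
    for i, row in enumerate(raw.series):
        zi = [decay * row[0]] if row.size else [0.0]
        smoothed[i] = lfilter([alpha], [1.0, -decay], row, zi=zi)[0]
    step = int(round(raw.fs / fs_out))
    return LaminarLFP(raw.site_depths, raw.fs / step, smoothed[:, ::step])


def evoked_potential(
    lfp: LaminarLFP,
    events,
    pre: float = 0.25,
    post: float = 0.75,
    event_type: str = "twitch",
) -> EvokedPotential:
    """Per-site mean of event-aligned LFP segments on [-pre, +post)."""
    times = np.asarray(getattr(events, "times", events), dtype=float)
    n_samples = lfp.series.shape[1]
    n_pre = int(round(pre * lfp.fs))
    n_post = int(round(post * lfp.fs))
    seg_len = n_pre + n_post
    segments = []
    for te in times:
        i0 = int(round(te * lfp.fs)) - n_pre
        if i0 < 0 or i0 + seg_len > n_samples:
            continue
        segments.append(lfp.series[:, i0 : i0 + seg_len])
    if not segments:
        raise ValueError("no usable events within the recording span")
    mean = np.mean(segments, axis=0)
    t_rel = (np.arange(seg_len) - n_pre) / lfp.fs
    return EvokedPotential(t_rel, lfp.site_depths, mean, len(segments), event_type)


def compute_csd(
    evoked: EvokedPotential,
    spacing: Optional[float] = None,
    interp_step: float = 10.0,
) -> CsdMap:
    """Second spatial difference of the evoked potential, sinks negative.

    Boundary rows use Vaknin padding (duplicate the first and last site) so
    the CSD is defined at every site; the map is then cubic-interpolated to
    ``interp_step`` um in depth.
    """
    v = evoked.mean
    depths = np.asarray(evoked.site_depths, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("CSD requires at least 3 sites")
    if spacing is None:
        spacing = float(depths[1] - depths[0])
    padded = np.vstack([v[0], v, v[-1]])
    csd = -(padded[:-2] - 2.0 * padded[1:-1] + padded[2:]) / (spacing * spacing)
    spline = CubicSpline(depths, csd, axis=0)
    interp_depths = np.arange(depths[0], depths[-1] + interp_step / 2.0, interp_step)
    csd_interp = spline(interp_depths)
    return CsdMap(evoked.times, depths, csd, interp_depths, csd_interp)


def locate_sink(csd_map: CsdMap):
    """(depth um, time s) of the most negative interpolated CSD value.

    Ties break toward the smaller depth (then earlier time); an all-zero map
    yields None.
    """
    m = csd_map.csd_interp
    if m.size == 0 or np.all(m == 0):
        return None
    flat = np.argmin(m)  # row-major: first (smallest-depth) minimum wins ties
    i, j = np.unravel_index(flat, m.shape)
    return float(csd_map.interp_depths[i]), float(csd_map.times[j])
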