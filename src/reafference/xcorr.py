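"""Shift-predictor-corrected cross-correlation around movement events.

A raw cross-correlogram between two simultaneously recorded units mixes two
sources of correlation: shared locking to the movement (stimulus) and direct
neuron-neuron interaction.  The shift predictor isolates the stimulus
component: it is the mean cross-correlogram over all noncongruent event
pairings (the reference unit's spikes around event i against the partner
unit's spikes around event j != i).  Subtracting it leaves the interaction
component; per-bin confidence bands assume the predictor count in each bin
is Poisson (sigma = sqrt(count)).

Lag grid: +-250 ms in 1 ms bins (501 bins); positive lag means the partner
fires after the reference.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .types import CorrelogramSet, SpikeTrain

LAG_HALF = 0.250
LAG_BIN = 0.001
REF_WINDOW = 0.200


def lag_grid(lag_half: float = LAG_HALF, lag_bin: float = LAG_BIN):
    """(edges, centers) of the symmetric lag grid (odd bin count, 0-centered)."""
    n_half = int(round(lag_half / lag_bin))
    edges = (np.arange(-n_half, n_half + 2) - 0.5) * lag_bin
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def reference_spikes(train: SpikeTrain, events, window: float = REF_WINDOW) -> np.ndarray:
    """Reference-unit spikes within +-window of any event (each spike once)."""
    times = getattr(events, "times", events)
    times = np.asarray(times, dtype=float)
    if times.size == 0 or len(train) == 0:
        return np.empty(0)
    idx = np.searchsorted(times, train.times)
    prev = np.where(idx > 0, train.times - times[np.maximum(idx - 1, 0)], np.inf)
    nxt = np.where(idx < times.size, times[np.minimum(idx, times.size - 1)] - train.times, np.inf)
    return train.times[np.minimum(prev, nxt) <= window]


def raw_crosscorr(partner: SpikeTrain, ref_spikes, lag_half: float = LAG_HALF,
                  lag_bin: float = LAG_BIN) -> np.ndarray:
    """Histogram of (partner spike - reference spike) lags, counts per bin."""
    edges, centers = lag_grid(lag_half, lag_bin)
    ref_spikes = np.asarray(ref_spikes, dtype=float)
    counts = np.zeros(centers.size)
    if ref_spikes.size == 0 or len(partner) == 0:
        return counts
    for rs in ref_spikes:
        i0, i1 = np.searchsorted(partner.times, (rs + edges[0], rs + edges[-1]))
        if i1 > i0:
            counts += np.histogram(partner.times[i0:i1] - rs, bins=edges)[0]
    return counts


def _segments(train_times, event_times, half):
    """Per-event spike times relative to the event, with event indices."""
    rel, idx = [], []
    for k, te in enumerate(event_times):
        i0, i1 = np.searchsorted(train_times, (te - half, te + half))
        seg = train_times[i0:i1] - te
        rel.append(seg)
        idx.append(np.full(seg.size, k))
    if rel:
        return np.concatenate(rel), np.concatenate(idx)
    return np.empty(0), np.empty(0, dtype=int)


def event_correlograms(
    partner: SpikeTrain,
    reference: SpikeTrain,
    events,
    ref_window: float = REF_WINDOW,
    lag_half: float = LAG_HALF,
    lag_bin: float = LAG_BIN,
    max_pairings: int = None,
    seed=None,
):
    """(raw, shift_predictor, n_ref_spikes) on the common lag grid.

    Reference spikes are those within +-ref_window of an event, each
    attributed to its nearest event.  The raw correlogram pairs reference and
    partner activity around the same event (congruent); the shift predictor
    averages the correlogram over all ordered noncongruent event pairings,
    normalized per reference event so both are on the same scale and
    corrected = raw - predictor cancels pure stimulus locking.

    With n events the exact predictor costs O(n^2) segment pairings; when
    ``max_pairings`` is set and n(n-1) exceeds it, a seeded subsample of at
    least that many pairings is used instead (documented approximation).
    """
    times = np.asarray(getattr(events, "times", events), dtype=float)
    n_ev = times.size
    if n_ev < 2:
        raise ValueError("shift predictor requires at least 2 events")
    edges, centers = lag_grid(lag_half, lag_bin)
    seg_half = ref_window + lag_half + lag_bin  # partner segments cover all lags

    a_rel, a_idx = _segments(reference.times, times, ref_window)
    # keep each reference spike once: nearest event only
    if a_rel.size:
        order = np.argsort(np.abs(a_rel), kind="stable")
        seen = set()
        keep = np.zeros(a_rel.size, dtype=bool)
        abs_t = np.round((a_rel + times[a_idx]) / 1e-9).astype(np.int64)
        for i in order:
            if abs_t[i] not in seen:
                seen.add(abs_t[i])
                keep[i] = True
        a_rel, a_idx = a_rel[keep], a_idx[keep]
    b_rel, b_idx = _segments(partner.times, times, seg_half)

    raw = np.zeros(centers.size)
    pred = np.zeros(centers.size)
    n_ref = int(a_rel.size)
    if a_rel.size == 0 or b_rel.size == 0:
        return raw, pred, n_ref

    # all cross differences at once; congruent pairs give the raw correlogram
    diffs = b_rel[None, :] - a_rel[:, None]
    congruent = b_idx[None, :] == a_idx[:, None]
    in_range = (diffs >= edges[0]) & (diffs < edges[-1])
    raw = np.histogram(diffs[congruent & in_range], bins=edges)[0].astype(float)

    if max_pairings is not None and n_ev * (n_ev - 1) > max_pairings:
        rng = np.random.default_rng(seed)
        n_sub = max(max_pairings, 200)
        ii = rng.integers(0, n_ev, size=2 * n_sub)
        jj = rng.integers(0, n_ev, size=2 * n_sub)
        ok = ii != jj
        pairs = np.stack([ii[ok][:n_sub], jj[ok][:n_sub]], axis=1)
        acc = np.zeros(centers.size)
        for i, j in pairs:
            ai = a_rel[a_idx == i]
            bj = b_rel[b_idx == j]
            if ai.size and bj.size:
                d = (bj[None, :] - ai[:, None]).ravel()
                acc += np.histogram(d, bins=edges)[0]
        # mean correlogram of one pairing, summed over the n reference events
        pred = acc / pairs.shape[0] * n_ev
    else:
        all_hist = np.histogram(diffs[in_range], bins=edges)[0].astype(float)
        # noncongruent total / (n-1) = mean over the n-1 shifts, summed over events
        pred = (all_hist - raw) / (n_ev - 1)
    return raw, pred, n_ref


def corrected_with_bands(
    raw: np.ndarray,
    shift_predictor: np.ndarray,
    p: float = 0.01,
    lags: np.ndarray = None,
    n_pairs: int = 1,
    n_reference_spikes: int = 0,
) -> CorrelogramSet:
    """corrected = raw - predictor with Poisson confidence bands.

    Per-bin sigma = sqrt(predictor count); the band is +- z_{1-p/2} sigma
    around the predictor (two-sided, z ~ 2.576 at p = 0.01).
    """
    raw = np.asarray(raw, dtype=float)
    pred = np.asarray(shift_predictor, dtype=float)
    if raw.shape != pred.shape:
        raise ValueError("raw and predictor must share the lag grid")
    if lags is None:
        _, lags = lag_grid()
        if lags.size != raw.size:
            lags = np.arange(raw.size, dtype=float)
    z = norm.ppf(1.0 - p / 2.0)
    sigma = np.sqrt(np.maximum(pred, 0.0))
    corrected = raw - pred
    return CorrelogramSet(
        np.asarray(lags, dtype=float), raw, pred, corrected,
        pred - z * sigma, pred + z * sigma, n_pairs, n_reference_spikes,
    )


def pair_correlogram(
    partner: SpikeTrain,
    reference: SpikeTrain,
    events,
    p: float = 0.01,
    ref_window: float = REF_WINDOW,
    max_pairings: int = None,
    seed=None,
) -> CorrelogramSet:
    """Full shift-predictor-corrected correlogram for one unit pair."""
    raw, pred, n_ref = event_correlograms(
        partner, reference, events, ref_window, max_pairings=max_pairings, seed=seed
    )
    _, centers = lag_grid()
    return corrected_with_bands(raw, pred, p, centers, 1, n_ref)


def summed_pair_correlogram(pair_results, p: float = 0.01) -> CorrelogramSet:
    """Bin-wise sum of corrected correlograms across unit pairs.

    Bands recombine as z * sqrt(sum of predictor counts), treating the
    summed predictor as Poisson.
    """
    pair_results = list(pair_results)
    if not pair_results:
        raise ValueError("no pairs to sum")
    lags = pair_results[0].lags
    for r in pair_results[1:]:
        if r.lags.shape != lags.shape or not np.allclose(r.lags, lags):
            raise ValueError("lag grid mismatch across pairs")
    raw = np.sum([r.raw for r in pair_results], axis=0)
    pred = np.sum([r.shift_predictor for r in pair_results], axis=0)
    n_ref = int(np.sum([r.n_reference_spikes for r in pair_results]))
    return corrected_with_bands(raw, pred, p, lags, len(pair_results), n_ref)


def peak_lag(correlogram: CorrelogramSet):
    """Lag of the maximum significant corrected bin (ties -> smallest |lag|).

    Returns None when no bin is significant.
    """
    sig = correlogram.significant
    if not sig.any():
        return None
    corr = np.where(sig, correlogram.corrected, -np.inf)
    best = corr.max()
    candidates = np.flatnonzero(corr == best)
    lags = correlogram.lags[candidates]
    return float(lags[np.argmin(np.abs(lags))])
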