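"""Perievent histograms, response-model fitting, and classification.

Each unit's perievent histogram (2 s window centered on the event, 10 ms
bins) is fit to two idealized response models:

* a symmetric Gaussian, R(t) = BL + R_max * exp(-(t - t_max)^2 / (2 c^2)),
  for twitches (discrete movements), and
* a Gaussian rise with exponential fall for wake movements,
  R(t) = BL + R_max * exp(-lam (t - t_max)) for t > t_max.

The adjusted coefficient of determination,
r2_adj = 1 - ((n - 1)/(n - p)) * SSE/SST, penalizes the extra parameter of
the asymmetric model and serves as a responsivity index: a unit is
responsive to a movement type when r2_adj > 0.35 (strict inequality).
Derived widths: HWHH = sqrt(2 ln 2) * c and t_half = ln 2 / lam.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .types import NeuronClass, PopulationSummary, Psth, ResponseFit, SpikeTrain

_SQ2LN2 = np.sqrt(2.0 * np.log(2.0))

BOUNDS_GAUSS = {
    "BL": (0.0, np.inf),
    "R_max": (0.0, np.inf),
    "t_max": (-0.5, 0.75),
    "c": (0.005, 0.5),
}
BOUNDS_LAM = (0.5, 200.0)
C_STARTS = (0.02, 0.05, 0.15)
LAM_STARTS = (2.0, 10.0, 50.0)


def gaussian_model(t, BL, R_max, t_max, c):
    t = np.asarray(t, dtype=float)
    return BL + R_max * np.exp(-((t - t_max) ** 2) / (2.0 * c * c))


def gauss_exp_model(t, BL, R_max, t_max, c, lam):
    t = np.asarray(t, dtype=float)
    rise = BL + R_max * np.exp(-((t - t_max) ** 2) / (2.0 * c * c))
    fall = BL + R_max * np.exp(-lam * (t - t_max))
    return np.where(t <= t_max, rise, fall)


def build_psth(
    spikes: SpikeTrain,
    events,
    window: float = 2.0,
    bin_width: float = 0.010,
    event_type: str = "twitch",
) -> Psth:
    """Mean perievent firing rate on a window centered at the event.

    rate(bin) = pooled spike count / (n_events * bin_width); the default
    grid is 200 bins spanning [-1, +1) s.
    """
    times = getattr(events, "times", events)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no triggers: at least one event is required")
    half = window / 2.0
    n_bins = int(round(window / bin_width))
    if not np.isclose(n_bins * bin_width, window):
        raise ValueError("bin width must divide the window")
    edges = -half + bin_width * np.arange(n_bins + 1)
    deltas = []
    for te in times:
        i0, i1 = np.searchsorted(spikes.times, (te - half, te + half))
        deltas.append(spikes.times[i0:i1] - te)
    pooled = np.concatenate(deltas) if deltas else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    rates = counts / (times.size * bin_width)
    return Psth(edges, rates, int(times.size), event_type)


def adjusted_r2(observed, predicted, p: int):
    """r2_adj = 1 - ((n-1)/(n-p)) * SSE/SST.

    Returns (r2_adj, flagged): SST = 0 makes the statistic undefined, which
    is reported as 0.0 with ``flagged`` True so such fits are never
    classified as responsive.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = observed.size
    if n <= p:
        raise ValueError("need more observations than parameters")
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        return 0.0, True
    return 1.0 - (n - 1) / (n - p) * sse / sst, False


def _fit_once(model, t, y, p0, lower, upper):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, _ = curve_fit(
                model, t, y, p0=p0, bounds=(lower, upper), method="trf", maxfev=2000
            )
        except (RuntimeError, ValueError):
            return None, np.inf
    sse = float(np.sum((y - model(t, *popt)) ** 2))
    return popt, sse


def _starts(t, y):
    i_peak = int(np.argmax(y))
    t_max0 = float(np.clip(t[i_peak], *BOUNDS_GAUSS["t_max"]))
    bl0 = float(np.percentile(y, 10))
    r0 = max(float(y[i_peak] - bl0), 1e-6)
    return t_max0, bl0, r0


def fit_gaussian(psth: Psth) -> ResponseFit:
    """Bounded least-squares fit of the 4-parameter Gaussian model.

    Deterministic multi-start: t_max at the peak bin, BL at the 10th
    percentile rate, R_max at peak minus BL, and c in {0.02, 0.05, 0.15} s;
    the start with the lowest SSE wins, so the fit is reproducible
    bit-for-bit on fixed input.
    """
    t, y = psth.bin_centers, psth.rates
    n = y.size
    if not np.any(y > 0):
        return ResponseFit("gaussian", 0.0, 0.0, 0.0, 0.005, None,
                           0.0, 0.0, n, 4, 0.0, degenerate=True)
    t_max0, bl0, r0 = _starts(t, y)
    lower = [BOUNDS_GAUSS[k][0] for k in ("BL", "R_max", "t_max", "c")]
    upper = [BOUNDS_GAUSS[k][1] for k in ("BL", "R_max", "t_max", "c")]
    best, best_sse = None, np.inf
    for c0 in C_STARTS:
        popt, sse = _fit_once(gaussian_model, t, y, [bl0, r0, t_max0, c0], lower, upper)
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        return ResponseFit("gaussian", float(y.mean()), 0.0, 0.0, 0.005, None,
                           0.0, 0.0, n, 4, 0.0, degenerate=True)
    bl, r_max, t_max, c = (float(v) for v in best)
    pred = gaussian_model(t, *best)
    r2, flagged = adjusted_r2(y, pred, 4)
    sst = float(np.sum((y - y.mean()) ** 2))
    return ResponseFit("gaussian", bl, r_max, t_max, c, None,
                       best_sse, sst, n, 4, r2, degenerate=flagged)


def fit_gauss_exp(psth: Psth) -> ResponseFit:
    """Bounded least-squares fit of the 5-parameter Gaussian-exponential model.

    Same deterministic multi-start as the Gaussian fit, crossed with decay
    rates lam in {2, 10, 50} 1/s.
    """
    t, y = psth.bin_centers, psth.rates
    n = y.size
    if not np.any(y > 0):
        return ResponseFit("gauss_exp", 0.0, 0.0, 0.0, 0.005, 1.0,
                           0.0, 0.0, n, 5, 0.0, degenerate=True)
    t_max0, bl0, r0 = _starts(t, y)
    lower = [BOUNDS_GAUSS[k][0] for k in ("BL", "R_max", "t_max", "c")] + [BOUNDS_LAM[0]]
    upper = [BOUNDS_GAUSS[k][1] for k in ("BL", "R_max", "t_max", "c")] + [BOUNDS_LAM[1]]
    best, best_sse = None, np.inf
    for c0 in C_STARTS:
        for lam0 in LAM_STARTS:
            popt, sse = _fit_once(
                gauss_exp_model, t, y, [bl0, r0, t_max0, c0, lam0], lower, upper
            )
            if sse < best_sse:
                best, best_sse = popt, sse
    if best is None:
        return ResponseFit("gauss_exp", float(y.mean()), 0.0, 0.0, 0.005, 1.0,
                           0.0, 0.0, n, 5, 0.0, degenerate=True)
    bl, r_max, t_max, c, lam = (float(v) for v in best)
    pred = gauss_exp_model(t, *best)
    r2, flagged = adjusted_r2(y, pred, 5)
    sst = float(np.sum((y - y.mean()) ** 2))
    return ResponseFit("gauss_exp", bl, r_max, t_max, c, lam,
                       best_sse, sst, n, 5, r2, degenerate=flagged)


def derive_widths(fit: ResponseFit):
    """(HWHH, t_half): half-width at half-height and decay half-life."""
    return fit.HWHH, fit.t_half


def classify_neuron(
    fit_twitch: Optional[ResponseFit],
    fit_wake: Optional[ResponseFit],
    threshold: float = 0.35,
) -> NeuronClass:
    """Four-way classification by strict r2_adj > threshold per movement type."""
    r2_tw = fit_twitch.r2_adj if fit_twitch is not None else 0.0
    r2_wk = fit_wake.r2_adj if fit_wake is not None else 0.0
    return NeuronClass(r2_tw, r2_wk, threshold)


CLASS_LABELS = ("unresponsive", "twitch", "wake", "twitch_and_wake")


def population_summary(classes: Iterable) -> PopulationSummary:
    """Population percentages from per-unit classifications (or labels).

    P(R_total) is the percentage of all units that are responsive.  Among
    responsive units, the three exclusive classes are reported separately
    and "twitch-responsive" is also reported inclusively (exclusive-twitch
    plus twitch-and-wake), the convention used when quoting the fraction of
    responsive neurons that respond to twitches.
    """
    labels = [c.label if isinstance(c, NeuronClass) else str(c) for c in classes]
    if not labels:
        raise ValueError("population is empty")
    for lab in labels:
        if lab not in CLASS_LABELS:
            raise ValueError(f"unknown class label {lab!r}")
    counts = {lab: labels.count(lab) for lab in CLASS_LABELS}
    n = len(labels)
    n_resp = n - counts["unresponsive"]
    p_total = 100.0 * n_resp / n
    if n_resp:
        among = {
            lab: 100.0 * counts[lab] / n_resp
            for lab in ("twitch", "wake", "twitch_and_wake")
        }
        tw_incl = 100.0 * (counts["twitch"] + counts["twitch_and_wake"]) / n_resp
        wk_incl = 100.0 * (counts["wake"] + counts["twitch_and_wake"]) / n_resp
    else:
        among = {lab: 0.0 for lab in ("twitch", "wake", "twitch_and_wake")}
        tw_incl = wk_incl = 0.0
    return PopulationSummary(n, counts, p_total, among, tw_incl, wk_incl)


def summary_from_counts(
    unresponsive: int, wake: int, twitch: int, both: int
) -> PopulationSummary:
    """Population summary directly from classification counts."""
    labels = (
        ["unresponsive"] * unresponsive
        + ["wake"] * wake
        + ["twitch"] * twitch
        + ["twitch_and_wake"] * both
    )
    return population_summary(labels)


def threshold_sensitivity(
    fits: Sequence,  # of (fit_twitch, fit_wake)
    psths: Optional[Sequence] = None,  # of (psth_twitch, psth_wake), optional
    thresholds=None,
):
    """Classification counts (and mean rate change) across a threshold grid.

    For each threshold in 0.20..0.50 (step 0.05, anchored at 0.35) the 4-way
    class counts are tabulated; when PSTHs are supplied, the mean
    peak-window rate change relative to fitted baseline is reported per
    class, the quantity the threshold choice was originally based on.
    """
    from .reliability import response_window

    if thresholds is None:
        thresholds = np.round(np.arange(0.20, 0.501, 0.05), 2)
    rows = []
    for thr in thresholds:
        labels = [
            classify_neuron(ftw, fwk, threshold=float(thr)).label for ftw, fwk in fits
        ]
        row = {"threshold": float(thr)}
        row.update({lab: labels.count(lab) for lab in CLASS_LABELS})
        if psths is not None:
            deltas = {lab: [] for lab in CLASS_LABELS}
            for (ftw, fwk), (ptw, pwk), lab in zip(fits, psths, labels):
                changes = []
                for fit, psth in ((ftw, ptw), (fwk, pwk)):
                    if fit is None or psth is None or fit.R_max <= 0:
                        continue
                    try:
                        win = response_window(fit)
                    except ValueError:
                        continue
                    sel = (psth.bin_centers >= win.t_start) & (
                        psth.bin_centers <= win.t_end
                    )
                    if sel.any():
                        changes.append(float(psth.rates[sel].max() - fit.BL))
                if changes:
                    deltas[lab].append(max(changes))
            row.update(
                {
                    f"mean_delta_{lab}": (
                        float(np.mean(deltas[lab])) if deltas[lab] else np.nan
                    )
                    for lab in CLASS_LABELS
                }
            )
        rows.append(row)
    return rows


def depth_response_profile(spike_trains: Sequence[SpikeTrain], events, model: str = "gaussian"):
    """Normalized response strength per electrode site.

    For each unit with a known depth, (peak PSTH rate - BL) / BL from the
    appropriate model fit; units without spikes or with BL = 0 are flagged
    and excluded from the profile.
    """
    fit_fn = fit_gaussian if model == "gaussian" else fit_gauss_exp
    rows, flagged = [], []
    for train in spike_trains:
        if train.depth is None:
            raise ValueError(f"unit {train.unit_id} has no site depth")
        if len(train) == 0:
            flagged.append(train.unit_id)
            continue
        psth = build_psth(train, events)
        fit = fit_fn(psth)
        if fit.BL <= 0 or fit.degenerate:
            flagged.append(train.unit_id)
            continue
        peak = float(psth.rates.max())
        rows.append((float(train.depth), (peak - fit.BL) / fit.BL))
    if rows:
        depths = sorted({d for d, _ in rows})
        profile = [
            (d, float(np.mean([v for dd, v in rows if dd == d]))) for d in depths
        ]
    else:
        profile = []
    return profile, flagged
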