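import numpy as np
import pytest

import reafference as rf
from reafference.session_io import _bundle_to_session


@pytest.fixture(scope="session")
def session_bundle():
    """One 30 min synthetic session shared by the heavier tests."""
    return rf.simulate_session(rf.SimConfig(session_duration=1800.0, seed=11))


@pytest.fixture(scope="session")
def session(session_bundle):
    return _bundle_to_session(session_bundle)


def match_events(true_times, detected_times, tol=0.05):
    """Greedy one-to-one matching; returns (n_hits, n_true, n_detected)."""
    true_times = np.asarray(true_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    used = np.zeros(detected_times.size, dtype=bool)
    hits = 0
    for t in true_times:
        if detected_times.size == 0:
            break
        d = np.abs(detected_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            hits += 1
    return hits, true_times.size, detected_times.size


def grid_oracle_sse(psth, model="gaussian"):
    """Independent brute-force SSE minimum for the response models.

    Grids (t_max, c[, lam]) coarsely over the full bounds, solves (BL, R_max)
    in closed form per shape (linear-in-amplitude model, nonnegativity by
    clipping), then refines at 0.001 resolution around the coarse optimum.
    """
    t = psth.bin_centers
    y = psth.rates

    def sse_for(tmaxs, cs, lams=None):
        if lams is None:
            tm, c = np.meshgrid(tmaxs, cs, indexing="ij")
            tm, c = tm.ravel(), c.ravel()
            la = np.full(tm.size, np.nan)
        else:
            tm, c, la = np.meshgrid(tmaxs, cs, lams, indexing="ij")
            tm, c, la = tm.ravel(), c.ravel(), la.ravel()
        n = t.size
        sy = y.sum()
        syy = float((y * y).sum())
        best, args = np.inf, None
        for i0 in range(0, tm.size, 4000):
            sl = slice(i0, i0 + 4000)
            dt = t[None, :] - tm[sl, None]
            k = np.exp(-(dt**2) / (2 * c[sl, None] ** 2))
            if lams is not None:
                k = np.where(dt <= 0, k, np.exp(-la[sl, None] * dt))
            sk = k.sum(axis=1)
            skk = np.einsum("ij,ij->i", k, k)
            sky = k @ y
            det = n * skk - sk * sk
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(det > 1e-12, (n * sky - sk * sy) / det, 0.0)
                bl = np.where(det > 1e-12, (sy - r * sk) / n, sy / n)
                neg_r = r < 0
                r = np.where(neg_r, 0.0, r)
                bl = np.where(neg_r, sy / n, bl)
                neg_bl = bl < 0
                bl = np.where(neg_bl, 0.0, bl)
                r = np.where(neg_bl, np.maximum(sky / skk, 0.0), r)
            sse = (
                syy - 2 * (bl * sy + r * sky) + n * bl * bl
                + 2 * bl * r * sk + r * r * skk
            )
            j = int(np.argmin(sse))
            if sse[j] < best:
                best = float(sse[j])
                args = (tm[sl][j], c[sl][j], None if lams is None else la[sl][j])
        return best, args

    tmaxs = np.arange(-0.5, 0.7501, 0.01)
    cs = np.geomspace(0.005, 0.5, 40)
    lams = None if model == "gaussian" else np.geomspace(0.5, 200.0, 25)
    _, (tm0, c0, la0) = sse_for(tmaxs, cs, lams)
    tmaxs = np.arange(tm0 - 0.01, tm0 + 0.0101, 0.001)
    cs = np.arange(max(c0 - 0.005, 0.005), c0 + 0.0051, 0.001)
    lams = None if la0 is None else np.geomspace(la0 / 1.5, la0 * 1.5, 25)
    best, _ = sse_for(tmaxs, cs, lams)
    return best
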