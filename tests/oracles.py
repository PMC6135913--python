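"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results with the most literal possible
formulations (explicit loops, closed-form algebra, direct least-squares
projections) so they stay independent of the library's vectorized
implementations.
"""

import math
from itertools import combinations

import numpy as np


def brute_force_saccades(t, x, y, valid, lam=6.0, window=5, min_run=1):
    """Literal per-sample velocity-threshold detection.

    Returns a list of (onset_index, offset_index) event boundaries.
    """
    n = len(t)
    h = (window - 1) // 2
    dt_s = float(np.median(np.diff(t))) / 1000.0
    vx = [None] * n
    vy = [None] * n
    for i in range(n):
        if i - h < 0 or i + h >= n:
            continue
        if not all(valid[i - h:i + h + 1]):
            continue
        sx = 0.0
        sy = 0.0
        for k in range(1, h + 1):
            sx += x[i + k] - x[i - k]
            sy += y[i + k] - y[i - k]
        vx[i] = sx / (h * (h + 1) * dt_s)
        vy[i] = sy / (h * (h + 1) * dt_s)

    defined = [v is not None for v in vx]
    if not any(defined):
        return []

    def sigma(vs):
        arr = np.array([v for v in vs if v is not None])
        med = float(np.median(arr))
        s2 = float(np.median(arr ** 2)) - med ** 2
        return math.sqrt(max(s2, 0.0))

    sig_x = sigma(vx)
    sig_y = sigma(vy)

    def term(v, s):
        if s > 0:
            return (v / (lam * s)) ** 2
        return math.inf if v != 0 else 0.0

    saccadic = []
    for i in range(n):
        if vx[i] is None:
            saccadic.append(False)
        else:
            saccadic.append(term(vx[i], sig_x) + term(vy[i], sig_y) > 1.0)

    events = []
    i = 0
    while i < n:
        if saccadic[i]:
            j = i
            while j + 1 < n and saccadic[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                events.append((i, j))
            i = j + 1
        else:
            i += 1
    return events


def _sum_code(values, levels):
    k = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    X = np.zeros((len(values), k - 1))
    for r, v in enumerate(values):
        i = idx[v]
        if i < k - 1:
            X[r, i] = 1.0
        else:
            X[r, :] = -1.0
    return X


def anova_ss_by_projection(df, dv, factors):
    """Type III sums of squares by explicit design-matrix least squares.

    Each term's SS is the increase in residual sum of squares when that
    term's sum-coded columns are removed from the full crossed model.
    Keys use the library's " × " interaction naming plus an "Error" entry.
    """
    vals = {f: df[f].astype(str).tolist() for f in factors}
    levels = {f: sorted(set(vals[f])) for f in factors}
    mains = {f: _sum_code(vals[f], levels[f]) for f in factors}
    n = len(df)

    terms = {}
    for r in range(1, len(factors) + 1):
        for combo in combinations(factors, r):
            X = mains[combo[0]]
            for f in combo[1:]:
                X = np.einsum("ij,ik->ijk", X, mains[f]).reshape(n, -1)
            terms[" × ".join(combo)] = X

    y = df[dv].to_numpy(dtype=float)
    ones = np.ones((n, 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(np.hstack([ones] + list(terms.values())))
    out = {}
    for name in terms:
        blocks = [ones] + [X for key, X in terms.items() if key != name]
        out[name] = rss(np.hstack(blocks)) - rss_full
    out["Error"] = rss_full
    return out


def blend_overlap_channel(alpha_front, alpha_back, i_front, i_back, w):
    """Scalar per-channel evaluation of the two-layer blend."""
    i_back_prime = alpha_back * i_back + (1.0 - alpha_back) * w
    return alpha_front * i_front + (1.0 - alpha_front) * i_back_prime
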