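"""Independent brute-force reference implementations used by the tests.

Every oracle here is written as a plain per-sample / per-frame loop, kept
deliberately separate from the library's vectorized implementations.
"""

import numpy as np


def sliding_mean_loop(x, half):
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def dff_loop(f, half):
    out = np.empty(len(f))
    for i in range(len(f)):
        lo, hi = max(0, i - half), min(len(f), i + half + 1)
        m = f[lo:hi].mean()
        out[i] = (f[i] - m) / m * 100.0
    return out


def ols_closed_form(x, y):
    slope = np.mean((x - x.mean()) * (y - y.mean())) / np.mean((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


def detect_transients_loop(x, rate, k=2.0, window_s=60.0):
    """Explicit two-pass sliding median/MAD detector; returns peak indices."""
    n = len(x)
    half = int(round(window_s * rate / 2))

    def med_mad(mask):
        med = np.empty(n)
        mad = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            sel = x[lo:hi][mask[lo:hi]]
            if sel.size == 0:
                med[i] = np.nan
                mad[i] = np.nan
            else:
                m = np.median(sel)
                med[i] = m
                mad[i] = np.median(np.abs(sel - m))
        return med, mad

    m1, s1 = med_mad(np.ones(n, bool))
    flagged = x > m1 + k * s1
    m2, s2 = med_mad(~flagged)
    with np.errstate(invalid="ignore"):
        above = (x > m2 + k * s2) & np.isfinite(m2)
    peaks = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            peaks.append(i + int(np.argmax(x[i:j])))
            i = j
        else:
            i += 1
    return np.array(peaks, dtype=int)


def maps_loop(x, y, values, bin_size, x0, y0, nx, ny):
    occ = np.zeros((ny, nx))
    cum = np.zeros((ny, nx))
    for xi, yi, v in zip(x, y, values):
        if not (np.isfinite(xi) and np.isfinite(yi) and np.isfinite(v)):
            continue
        ix = min(max(int((xi - x0) // bin_size), 0), nx - 1)
        iy = min(max(int((yi - y0) // bin_size), 0), ny - 1)
        occ[iy, ix] += 1
        cum[iy, ix] += v
    return occ, cum


def fraction_loop(data, threshold):
    count = 0
    for v in data.ravel():
        if v > threshold:
            count += 1
    return count / data.size


def f1_score(detected, truth, tol=0.1):
    """Greedy one-to-one matching of detected peak times to truth times."""
    used = np.zeros(len(truth), bool)
    tp = 0
    for d in detected:
        cand = np.flatnonzero(~used & (np.abs(truth - d) <= tol))
        if len(cand):
            used[cand[np.argmin(np.abs(truth[cand] - d))]] = True
            tp += 1
    prec = tp / len(detected) if len(detected) else 0.0
    rec = tp / len(truth) if len(truth) else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0
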