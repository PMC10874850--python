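"""Independent literal-definition oracles used to validate the vectorized
implementations. Written deliberately in plain, loop-based style from the
documented metric definitions, without sharing code with the package."""

from __future__ import annotations

import math

import numpy as np


def zscore(x):
    x = np.asarray(x, float)
    mu = sum(x) / len(x)
    var = sum((v - mu) ** 2 for v in x) / (len(x) - 1)
    return (x - mu) / math.sqrt(var)


def sample_sd(x):
    mu = sum(x) / len(x)
    return math.sqrt(sum((v - mu) ** 2 for v in x) / (len(x) - 1))


def acf_naive(z, max_lag):
    """Biased sample autocorrelation of a z-scored series, direct sums."""
    n = len(z)
    denom = sum(v * v for v in z)
    out = []
    for k in range(max_lag + 1):
        out.append(sum(z[t] * z[t + k] for t in range(n - k)) / denom)
    return np.array(out)


def periodogram_naive(z):
    """One-sided PSD by explicit DFT, matching a single-segment rectangular
    Welch estimate with fs = 1; DC excluded by the caller."""
    n = len(z)
    k_max = n // 2
    freqs = np.arange(k_max + 1) / n
    psd = np.empty(k_max + 1)
    t = np.arange(n)
    for k in range(k_max + 1):
        c = np.sum(z * np.exp(-2j * np.pi * k * t / n))
        p = (abs(c) ** 2) / n
        if k != 0 and not (n % 2 == 0 and k == k_max):
            p *= 2.0
        psd[k] = p
    return freqs, psd


def first_below_naive(vals, level):
    for k in range(1, len(vals)):
        if vals[k] < level:
            return float(k)
    return float(len(vals) - 1)


def first_local_min_naive(vals):
    for k in range(1, len(vals) - 1):
        if vals[k] < vals[k + 1]:
            return float(k)
    return float(len(vals) - 1)


def hist_ami_naive(z, lag, n_bins=5):
    """AMI at a lag from a 5x5 even-width joint histogram, direct counting."""
    a = z[:-lag]
    b = z[lag:]
    lo, hi = min(z), max(z) + 1e-12
    width = (hi - lo) / n_bins
    joint = np.zeros((n_bins, n_bins))
    for x, y in zip(a, b):
        i = min(int((x - lo) / width), n_bins - 1)
        j = min(int((y - lo) / width), n_bins - 1)
        joint[i, j] += 1
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if joint[i, j] > 0:
                total += joint[i, j] * math.log(joint[i, j] / (pa[i] * pb[j]))
    return total


def fluct_prop_naive(z, kind):
    """Two-regime fluctuation analysis, loop version."""
    y = np.cumsum(z)
    n = len(y)
    taus = sorted(
        set(
            int(round(v))
            for v in np.logspace(np.log10(5), np.log10(n // 2), 50)
        )
    )
    taus = [t for t in taus if t >= 5]
    fl = []
    for tau in taus:
        k = n // tau
        vals = []
        for w in range(k):
            seg = y[w * tau : (w + 1) * tau]
            t = np.arange(tau, dtype=float)
            # OLS line fit
            tm = t - t.mean()
            slope = float(np.sum(tm * seg) / np.sum(tm * tm))
            resid = seg - seg.mean() - slope * tm
            if kind == "rsrange":
                vals.append(resid.max() - resid.min())
            else:
                vals.append(np.mean(resid**2))
        if kind == "rsrange":
            fl.append(float(np.mean(vals)))
        else:
            fl.append(math.sqrt(float(np.mean(vals))))
    lt = [math.log(t) for t, f in zip(taus, fl) if f > 0]
    lf = [math.log(f) for f in fl if f > 0]
    m = len(lt)
    if m < 4:
        return float("nan")

    def sse(xs, ys):
        if len(xs) < 2:
            return 0.0
        xb = sum(xs) / len(xs)
        yb = sum(ys) / len(ys)
        den = sum((x - xb) ** 2 for x in xs)
        b = sum((x - xb) * (y - yb) for x, y in zip(xs, ys)) / den if den else 0.0
        return sum((y - yb - b * (x - xb)) ** 2 for x, y in zip(xs, ys))

    best, best_k = float("inf"), None
    for k in range(2, m - 1):
        s = sse(lt[:k], lf[:k]) + sse(lt[k:], lf[k:])
        if s < best:
            best, best_k = s, k
    return best_k / m


def pam_naive(x):
    mu = sum(x) / len(x)
    best = run = 0
    for v in x:
        if v > mu:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return float(best)


def ses_naive(z):
    counts, _ = np.histogram(z, bins=10)
    p = counts / counts.sum()
    h = 0.0
    for v in p:
        if v > 0:
            h -= v * math.log(v)
    return h


def hist_mode_naive(z, n_bins):
    counts, edges = np.histogram(z, bins=n_bins)
    best = int(np.argmax(counts))
    return 0.5 * (edges[best] + edges[best + 1])


def trs_naive(z):
    d = [(z[t + 1] - z[t]) ** 3 for t in range(len(z) - 1)]
    return sum(d) / len(d)


def pde_naive(x):
    sd = sample_sd(x)
    count = 0
    for t in range(len(x) - 1):
        if abs(x[t + 1] - x[t]) > 0.04 * sd:
            count += 1
    return count / (len(x) - 1)


def tea_naive(z):
    events = [i for i, v in enumerate(z) if v > 1.0]
    if len(events) < 2:
        return float("nan")
    gaps = [b - a for a, b in zip(events[:-1], events[1:])]
    return sum(gaps) / len(gaps)


def mef_naive(z):
    resid = []
    for t in range(3, len(z)):
        pred = (z[t - 1] + z[t - 2] + z[t - 3]) / 3.0
        resid.append(z[t] - pred)
    return sample_sd(resid)


def ccd_naive(z):
    dz = np.diff(z)
    zd = zscore(dz)
    a1 = acf_naive(zd, len(zd) // 2)
    a0 = acf_naive(z, len(z) // 2)
    return first_below_naive(a1, 0.0) / first_below_naive(a0, 0.0)


def tct_naive(z):
    a0 = acf_naive(z, len(z) // 2)
    stride = max(int(first_below_naive(a0, 0.0)), 1)
    zs = z[::stride]
    if len(zs) < 5:
        return float("nan")
    q1, q2 = np.quantile(zs, [1 / 3, 2 / 3])
    sym = [0 if v <= q1 else (1 if v <= q2 else 2) for v in zs]
    trans = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        trans[a, b] += 1
    trans /= trans.sum()
    return float(np.trace(np.cov(trans.T)))


def efd_naive(z):
    a0 = acf_naive(z, len(z) // 2)
    tau = max(int(first_below_naive(a0, 1.0 / math.e)), 1)
    pts = [(z[t], z[t + tau]) for t in range(len(z) - tau)]
    d = [
        math.hypot(b[0] - a[0], b[1] - a[1])
        for a, b in zip(pts[:-1], pts[1:])
    ]
    d = [v for v in d if v > 0]
    if len(d) < 10:
        return float("nan")
    lam = 1.0 / (sum(d) / len(d))
    edges = np.linspace(0, max(d), 11)
    dens, _ = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    diffs = [abs(dv - lam * math.exp(-lam * c)) for dv, c in zip(dens, centers)]
    return sum(diffs) / len(diffs)


def rft_naive(z):
    w = len(z) // 5
    peaks = []
    for i in range(5):
        seg = z[i * w : (i + 1) * w]
        f, p = periodogram_naive(np.asarray(seg))
        k = 1 + int(np.argmax(p[1:]))
        peaks.append(f[k])
    idx = list(range(5))
    ly = [math.log(pk + 1e-3) for pk in peaks]
    xb = sum(idx) / 5
    yb = sum(ly) / 5
    return sum((x - xb) * (y - yb) for x, y in zip(idx, ly)) / sum(
        (x - xb) ** 2 for x in idx
    )


def sttc_naive(a, b, duration, dt):
    """Literal tiling-formula STTC with brute-force interval arithmetic."""

    def tiled(times):
        grid = 0.0
        intervals = []
        for t in times:
            intervals.append((max(t - dt, 0.0), min(t + dt, duration)))
        intervals.sort()
        merged = []
        for lo, hi in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            grid += hi - lo
        return grid / duration

    def prop(x, y):
        if len(x) == 0 or len(y) == 0:
            return 0.0
        hits = 0
        for t in x:
            if any(abs(t - s) <= dt for s in y):
                hits += 1
        return hits / len(x)

    ta, tb = tiled(a), tiled(b)
    pa, pb = prop(a, b), prop(b, a)
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))
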