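"""Canonical time-series features on binned spike-count series.

Twenty-two metrics summarizing distributional, autocorrelation, spectral,
scaling, symbolic and forecasting properties of a (typically 100-ms-binned)
activity series. The set follows the canonical time-series-classification
feature collections; metrics are keyed by short abbreviations:

========  ==============================================================
RF        Peak frequency of the power spectrum (cycles/bin)
RM        Spectral power at RF
EAF       First lag at which the autocorrelation falls below 1/e
AMI       Automutual information at lag 1 (5x5 even-width histogram, nats)
SFR       Proportion of scales in the slow regime of rescaled-range
          fluctuation analysis (two-regime log-log fit)
LPF       Proportion of spectral power in the lowest fifth of frequencies
MEF       Standard deviation of residuals of a rolling 3-sample mean
          forecast
PAM       Longest run of consecutive values above the series mean (bins)
EFD       Mean absolute difference between the histogram of successive
          2-D embedding distances and an exponential fit
CCD       Ratio of correlation lengths (first zero-crossing lag of the
          ACF) after versus before first differencing
TCT       Trace of the covariance of the 3-symbol transition matrix
          (tercile coding at the correlation-length stride)
SES       Shannon entropy (nats) of a 10-bin histogram of the z-scored
          series
CFS       Power-weighted spectral centroid (cycles/bin)
SFD       As SFR but with detrended-fluctuation (RMS residual) scaling
MD5       Mode of the z-scored distribution (5-bin histogram)
MD10      Mode of the z-scored distribution (10-bin histogram)
FMA       First local minimum of the autocorrelation function (lag)
FMI       First local minimum of the automutual-information function (lag)
TRS       Time-reversibility statistic, mean of cubed successive
          differences of the z-scored series
TEA       Mean interval between successive extreme events (z > 1) (bins)
RFT       Exponential rate fitted to the sequence of per-window spectral
          peak frequencies (5 windows)
PDE       Proportion of successive differences exceeding 0.04 sd
========  ==============================================================

All metrics that depend on the z-scored series return NaN (the
not-available marker) for constant input. Sample (n-1) standard deviations
are used throughout. Spectra are full-length rectangular-window
periodograms (Welch with a single segment); frequencies are in cycles per
bin; lags in bins.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np
from scipy import signal

__all__ = [
    "TIMESERIES_FEATURE_NAMES",
    "extract_timeseries_features",
    "timeseries_registry",
]

TIMESERIES_FEATURE_NAMES = [
    "RF", "RM", "EAF", "AMI", "SFR", "LPF", "MEF", "PAM", "EFD", "CCD",
    "TCT", "SES", "CFS", "SFD", "MD5", "MD10", "FMA", "FMI", "TRS", "TEA",
    "RFT", "PDE",
]

MIN_LENGTH = 50


class _Context:
    """Shared intermediates: z-scored series, ACF, periodogram."""

    def __init__(self, x: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        n = self.x.size
        self.sd = float(np.std(self.x, ddof=1))
        self.constant = self.sd == 0.0 or not np.isfinite(self.sd)
        if not self.constant:
            self.z = (self.x - self.x.mean()) / self.sd
            self.acf = _acf(self.z, n // 2)
            f, p = signal.welch(
                self.z, fs=1.0, window="boxcar", nperseg=n, noverlap=0,
                detrend=False,
            )
            self.freqs, self.psd = f[1:], p[1:]  # drop DC
        else:
            self.z = np.zeros(n)
            self.acf = np.array([1.0])
            self.freqs = self.psd = np.array([])


def _acf(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation of an already z-scored series, lags
    0..max_lag, via FFT."""
    n = z.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fz = np.fft.rfft(z, nfft)
    ac = np.fft.irfft(fz * np.conj(fz))[: max_lag + 1]
    return ac / ac[0]


def _first_below(values: np.ndarray, level: float) -> float:
    """Smallest positive lag where values[lag] < level; last lag if none."""
    idx = np.nonzero(values[1:] < level)[0]
    return float(idx[0] + 1) if idx.size else float(values.size - 1)


def _first_zero_crossing(acf: np.ndarray) -> float:
    return _first_below(acf, 0.0)


def _first_local_min(values: np.ndarray) -> float:
    """Smallest lag k >= 1 with values[k] < values[k+1]; last lag if none."""
    for k in range(1, values.size - 1):
        if values[k] < values[k + 1]:
            return float(k)
    return float(values.size - 1)


def _hist_ami(z: np.ndarray, lag: int, n_bins: int = 5) -> float:
    """Automutual information (nats) at the given lag from an even-width
    n_bins x n_bins joint histogram of (z_t, z_{t+lag})."""
    if lag >= z.size:
        return np.nan
    a, b = z[:-lag], z[lag:]
    edges = np.linspace(z.min(), z.max(), n_bins + 1)
    edges[-1] += 1e-12
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


def _fluct_props(z: np.ndarray, kind: str) -> float:
    """Two-regime fluctuation analysis on the cumulative sum.

    Window sizes are 50 log-spaced scales in [5, n/2]. Per scale, the
    profile is cut into non-overlapping windows, each linearly detrended;
    the fluctuation is the mean residual range ("rsrange") or the RMS
    residual ("dfa"). A two-segment linear fit in log-log coordinates picks
    the split minimizing total squared error; the returned value is the
    proportion of scales in the first (slow-timescale) regime.
    """
    y = np.cumsum(z)
    n = y.size
    taus = np.unique(
        np.round(np.logspace(np.log10(5), np.log10(n // 2), 50)).astype(int)
    )
    taus = taus[taus >= 5]
    fl = []
    for tau in taus:
        k = n // tau
        seg = y[: k * tau].reshape(k, tau)
        t = np.arange(tau)
        # per-window linear detrend (closed-form OLS)
        tm = t - t.mean()
        denom = np.sum(tm**2)
        slope = seg @ tm / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - np.outer(slope, tm)
        if kind == "rsrange":
            f = np.mean(resid.max(axis=1) - resid.min(axis=1))
        else:  # dfa
            f = np.sqrt(np.mean(resid**2))
        fl.append(f)
    fl = np.asarray(fl)
    ok = fl > 0
    lt, lf = np.log(taus[ok].astype(float)), np.log(fl[ok])
    m = lt.size
    if m < 4:
        return np.nan
    best_sse, best_k = np.inf, None
    for k in range(2, m - 1):  # >= 2 points per segment
        sse = _ols_sse(lt[:k], lf[:k]) + _ols_sse(lt[k:], lf[k:])
        if sse < best_sse:
            best_sse, best_k = sse, k
    return float(best_k) / m


def _ols_sse(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sum(xm**2)
    if denom == 0:
        return float(np.sum(ym**2))
    b = np.sum(xm * ym) / denom
    return float(np.sum((ym - b * xm) ** 2))


# ---------------------------------------------------------------- metrics


def _rf(c: _Context) -> float:
    return float(c.freqs[np.argmax(c.psd)])


def _rm(c: _Context) -> float:
    return float(np.max(c.psd))


def _eaf(c: _Context) -> float:
    return _first_below(c.acf, 1.0 / np.e)


def _ami(c: _Context) -> float:
    return _hist_ami(c.z, lag=1)


def _sfr(c: _Context) -> float:
    return _fluct_props(c.z, "rsrange")


def _lpf(c: _Context) -> float:
    cutoff = c.freqs[-1] / 5.0
    return float(np.sum(c.psd[c.freqs <= cutoff]) / np.sum(c.psd))


def _mef(c: _Context) -> float:
    z = c.z
    if z.size < 10:
        return np.nan
    pred = (z[2:-1] + z[1:-2] + z[:-3]) / 3.0
    resid = z[3:] - pred
    return float(np.std(resid, ddof=1))


def _pam(c: _Context) -> float:
    above = c.x > c.x.mean()
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return float(best)


def _efd(c: _Context) -> float:
    tau = max(int(_eaf(c)), 1)
    z = c.z
    if z.size <= tau + 2:
        return np.nan
    pts = np.column_stack([z[:-tau], z[tau:]])
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    d = d[d > 0]
    if d.size < 10:
        return np.nan
    lam = 1.0 / np.mean(d)
    edges = np.linspace(0, d.max(), 11)
    dens, _ = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(np.mean(np.abs(dens - lam * np.exp(-lam * centers))))


def _ccd(c: _Context) -> float:
    dz = np.diff(c.z)
    sd = np.std(dz, ddof=1)
    if sd == 0:
        return np.nan
    acf_d = _acf((dz - dz.mean()) / sd, dz.size // 2)
    return _first_zero_crossing(acf_d) / _first_zero_crossing(c.acf)


def _tct(c: _Context) -> float:
    stride = max(int(_first_zero_crossing(c.acf)), 1)
    zs = c.z[::stride]
    if zs.size < 5:
        return np.nan
    terc = np.quantile(zs, [1 / 3, 2 / 3])
    sym = np.digitize(zs, terc, right=True)  # 0,1,2; boundaries fall low
    trans = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        trans[a, b] += 1
    trans /= trans.sum()
    return float(np.trace(np.cov(trans.T)))


def _ses(c: _Context) -> float:
    counts, _ = np.histogram(c.z, bins=10)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _cfs(c: _Context) -> float:
    return float(np.sum(c.freqs * c.psd) / np.sum(c.psd))


def _sfd(c: _Context) -> float:
    return _fluct_props(c.z, "dfa")


def _hist_mode(z: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(z, bins=n_bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _md5(c: _Context) -> float:
    return _hist_mode(c.z, 5)


def _md10(c: _Context) -> float:
    return _hist_mode(c.z, 10)


def _fma(c: _Context) -> float:
    return _first_local_min(c.acf)


def _fmi(c: _Context) -> float:
    max_lag = min(40, c.z.size - 2)
    ami = np.array([_hist_ami(c.z, k) for k in range(1, max_lag + 1)])
    for k in range(ami.size - 1):
        if ami[k] < ami[k + 1]:
            return float(k + 1)
    return float(ami.size)


def _trs(c: _Context) -> float:
    return float(np.mean(np.diff(c.z) ** 3))


def _tea(c: _Context) -> float:
    events = np.nonzero(c.z > 1.0)[0]
    if events.size < 2:
        return np.nan
    return float(np.mean(np.diff(events)))


def _rft(c: _Context) -> float:
    z = c.z
    w = z.size // 5
    if w < 8:
        return np.nan
    peaks = []
    for i in range(5):
        seg = z[i * w : (i + 1) * w]
        f, p = signal.welch(
            seg, fs=1.0, window="boxcar", nperseg=seg.size, noverlap=0,
            detrend=False,
        )
        peaks.append(f[1:][np.argmax(p[1:])])
    peaks = np.asarray(peaks)
    eps = 1e-3
    idx = np.arange(5, dtype=float)
    ly = np.log(peaks + eps)
    b = np.sum((idx - idx.mean()) * (ly - ly.mean())) / np.sum(
        (idx - idx.mean()) ** 2
    )
    return float(b)


def _pde(c: _Context) -> float:
    thr = 0.04 * c.sd
    return float(np.mean(np.abs(np.diff(c.x)) > thr))


_REGISTRY: Dict[str, Callable[[_Context], float]] = {
    "RF": _rf, "RM": _rm, "EAF": _eaf, "AMI": _ami, "SFR": _sfr,
    "LPF": _lpf, "MEF": _mef, "PAM": _pam, "EFD": _efd, "CCD": _ccd,
    "TCT": _tct, "SES": _ses, "CFS": _cfs, "SFD": _sfd, "MD5": _md5,
    "MD10": _md10, "FMA": _fma, "FMI": _fmi, "TRS": _trs, "TEA": _tea,
    "RFT": _rft, "PDE": _pde,
}

# Metrics well-defined even for constant input.
_CONSTANT_OK = {"PAM", "PDE"}


def timeseries_registry() -> Dict[str, Callable]:
    """The metric registry (name -> function of the internal context);
    users may add or substitute entries before extraction."""
    return _REGISTRY


def extract_timeseries_features(
    binned: np.ndarray, bin_s: float = 0.1
) -> Dict[str, float]:
    """Compute all registered time-series metrics on a binned count series.

    Requires at least 50 bins. Frequencies are reported in cycles per bin
    and lags in bins; ``bin_s`` is accepted for interface symmetry and
    recorded by callers, not used in the metric formulas.
    """
    x = np.asarray(binned, dtype=float)
    if x.size < MIN_LENGTH:
        raise ValueError(f"series must have >= {MIN_LENGTH} bins, got {x.size}")
    ctx = _Context(x)
    out: Dict[str, float] = {}
    for name, fn in _REGISTRY.items():
        if ctx.constant and name not in _CONSTANT_OK:
            out[name] = np.nan
        else:
            out[name] = fn(ctx)
    return out
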