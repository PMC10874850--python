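"""Spike-train timing features and binning helpers.

Four per-unit metrics describe spike-train dynamics: the mean inter-spike
interval (MIS), the coefficient of variation of the ISI distribution (CVI,
a regularity measure: ~1 for Poisson firing, 0 for clock-like), the overall
firing rate, and the lag-1 partial autocorrelation of the ISI sequence
(serial dependence between successive intervals).

Metrics that cannot be computed (too few spikes) are returned as NaN — the
not-available marker used throughout the package — never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from statsmodels.tsa.stattools import pacf

__all__ = [
    "SpikeTimeFeatures",
    "extract_spike_time_features",
    "bin_spike_counts",
    "SPIKE_TIME_FEATURE_NAMES",
]


@dataclass
class SpikeTimeFeatures:
    MIS: float  # mean inter-spike interval, s
    CVI: float  # sd(ISI)/mean(ISI), sample sd
    firing_rate_hz: float
    isi_pacf1: float  # partial autocorrelation of the ISI sequence at lag 1

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


SPIKE_TIME_FEATURE_NAMES = [f.name for f in fields(SpikeTimeFeatures)]


def extract_spike_time_features(
    spike_times_s: np.ndarray, duration_s: float
) -> SpikeTimeFeatures:
    """Compute MIS, CVI, firing rate and lag-1 ISI PACF for one unit.

    Requires >= 2 spikes for the ISI metrics and >= 5 for the PACF.
    """
    st = np.asarray(spike_times_s, dtype=float)
    fr = st.size / duration_s
    if st.size < 2:
        return SpikeTimeFeatures(np.nan, np.nan, fr, np.nan)
    isi = np.diff(st)
    mis = float(np.mean(isi))
    cvi = float(np.std(isi, ddof=1) / mis) if mis > 0 else np.nan
    pac1 = np.nan
    if st.size >= 5 and np.std(isi) > 0:
        try:
            pac1 = float(pacf(isi, nlags=1, method="ywm")[1])
        except Exception:
            pac1 = np.nan
    return SpikeTimeFeatures(mis, cvi, fr, pac1)


def bin_spike_counts(
    spike_times_s: np.ndarray, duration_s: float, bin_s: float = 0.1
) -> np.ndarray:
    """Left-closed, right-open bins anchored at t=0; final partial bin dropped."""
    n_bins = int(np.floor(duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(spike_times_s, bins=edges)
    return counts.astype(float)
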