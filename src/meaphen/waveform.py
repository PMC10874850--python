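"""Action-potential waveform features from multi-electrode templates.

Features are computed on the electrode with the largest negative template
amplitude (the peak electrode of the unit's electrical footprint). The eight
metrics are the standard extracellular set: trough amplitude, post-trough
peak amplitude, trough-to-peak latency, spike half-width, pre/post peak
asymmetry, repolarization slope (trough to post-peak), recovery slope (after
the post-peak), and the peak/trough amplitude ratio. Times are in
milliseconds relative to the trough; amplitudes in uV.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .core import NoSignal, Unit

__all__ = ["WaveformFeatures", "extract_waveform_features", "WAVEFORM_FEATURE_NAMES"]


@dataclass
class WaveformFeatures:
    trough_amplitude_uV: float
    peak_amplitude_uV: float
    trough_to_peak_ms: float
    half_width_ms: float
    asymmetry: float
    repolarization_slope_uV_per_ms: float
    recovery_slope_uV_per_ms: float
    peak_trough_ratio: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


WAVEFORM_FEATURE_NAMES = [f.name for f in fields(WaveformFeatures)]


def _crossing_width(wave: np.ndarray, level: float, center: int, fs: float) -> float:
    """Width (ms) of the interval around ``center`` where wave <= level,
    with linear interpolation at the crossings."""
    below = wave <= level
    if not below[center]:
        return 0.0
    left = center
    while left > 0 and below[left - 1]:
        left -= 1
    right = center
    while right < wave.size - 1 and below[right + 1]:
        right += 1
    # fractional refinement at both edges
    lpos = float(left)
    if left > 0:
        lpos = left - (level - wave[left]) / (wave[left - 1] - wave[left])
    rpos = float(right)
    if right < wave.size - 1:
        rpos = right + (level - wave[right]) / (wave[right + 1] - wave[right])
    return (rpos - lpos) / fs * 1e3


def _slope(wave: np.ndarray, i0: int, i1: int, fs: float) -> float:
    """Least-squares slope of wave[i0:i1+1] in uV/ms."""
    if i1 <= i0:
        return np.nan
    t_ms = np.arange(i0, i1 + 1) / fs * 1e3
    return float(np.polyfit(t_ms, wave[i0 : i1 + 1], 1)[0])


def extract_waveform_features(unit: Unit) -> WaveformFeatures:
    """Compute the eight waveform metrics on the unit's peak electrode.

    Raises NoSignal for flat or all-zero templates.
    """
    tpl = unit.template
    if tpl.size == 0 or np.allclose(tpl, tpl.ravel()[0]):
        raise NoSignal(f"unit {unit.unit_id}: flat template")
    fs = unit.sampling_rate_hz
    elec = int(np.argmin(tpl.min(axis=1)))
    wave = tpl[elec].astype(float)

    trough = int(np.argmin(wave))
    trough_amp = float(wave[trough])
    post = wave[trough + 1 :]
    if post.size == 0:
        raise NoSignal(f"unit {unit.unit_id}: trough at template edge")
    peak_post_rel = int(np.argmax(post))
    peak_idx = trough + 1 + peak_post_rel
    peak_amp = float(wave[peak_idx])
    # positive deflection amplitudes; 0 when a lobe is absent keeps the
    # asymmetry bounded in [-1, 1] instead of blowing up near a zero sum
    peak_pre = max(float(np.max(wave[:trough])) if trough > 0 else 0.0, 0.0)
    peak_post_pos = max(peak_amp, 0.0)

    t2p_ms = (peak_idx - trough) / fs * 1e3
    half_width = _crossing_width(wave, trough_amp / 2.0, trough, fs)
    denom = peak_post_pos + peak_pre
    asym = (peak_post_pos - peak_pre) / denom if denom != 0 else np.nan

    repol = _slope(wave, trough, peak_idx, fs)
    rec_end = min(peak_idx + int(round(0.7e-3 * fs)), wave.size - 1)
    recov = _slope(wave, peak_idx, rec_end, fs)
    ratio = abs(peak_amp) / abs(trough_amp) if trough_amp != 0 else np.nan

    return WaveformFeatures(
        trough_amplitude_uV=trough_amp,
        peak_amplitude_uV=peak_amp,
        trough_to_peak_ms=t2p_ms,
        half_width_ms=half_width,
        asymmetry=asym,
        repolarization_slope_uV_per_ms=repol,
        recovery_slope_uV_per_ms=recov,
        peak_trough_ratio=ratio,
    )
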