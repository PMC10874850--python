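"""Unit quality control.

Spike-sorted units are screened on three criteria before any feature
extraction: overall activity (firing rate above ``fr_min``), refractory-period
violations (fraction of inter-spike intervals shorter than ``refractory_ms``
below ``viol_max``), and waveform shape. The waveform check requires the
template's peak-electrode trough to reach ``amp_min`` uV and to precede the
largest subsequent positive deflection — a biphasic, spike-like shape; it can
be disabled wholesale with ``check_waveform=False``.

Units with fewer than 2 spikes are removed with a distinct reason code
(no inter-spike interval exists, so the refractory criterion is undefined).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .core import (
    QC_LOW_RATE,
    QC_REFRACTORY,
    QC_TOO_FEW_SPIKES,
    QC_WAVEFORM,
    QCReport,
    SortedRecording,
    Unit,
)

__all__ = ["run_quality_control", "refractory_violation_fraction", "waveform_is_ok"]


def refractory_violation_fraction(unit: Unit, refractory_ms: float) -> float:
    """Fraction of ISIs shorter than the refractory period."""
    isis = unit.isis()
    if isis.size == 0:
        return np.nan
    return float(np.mean(isis < refractory_ms / 1000.0))


def waveform_is_ok(unit: Unit, amp_min_uv: float = 10.0) -> bool:
    """Template sanity check on the peak (largest-trough) electrode.

    Requires trough depth >= ``amp_min_uv`` and the trough to precede the
    largest positive peak that follows it (biphasic shape).
    """
    if unit.template.size == 0 or not np.any(unit.template):
        return False
    elec = int(np.argmin(unit.template.min(axis=1)))
    wave = unit.template[elec]
    trough_idx = int(np.argmin(wave))
    if -wave[trough_idx] < amp_min_uv:
        return False
    post = wave[trough_idx + 1 :]
    if post.size == 0 or np.max(post) <= 0:
        return False
    return True


def run_quality_control(
    rec: SortedRecording,
    fr_min: float = 0.01,
    refractory_ms: float = 2.0,
    viol_max: float = 0.02,
    amp_min_uv: float = 10.0,
    check_waveform: bool = True,
) -> Tuple[SortedRecording, QCReport]:
    """Filter units on activity, refractory violations, and waveform shape.

    Parameters
    ----------
    fr_min
        Minimum firing rate in Hz; units must exceed this (strict).
    refractory_ms
        Refractory period used to count ISI violations.
    viol_max
        Maximum tolerated violation fraction (strict upper bound).
    amp_min_uv
        Minimum trough amplitude for the waveform check.
    check_waveform
        Disable the waveform criterion entirely when False.

    Returns
    -------
    (filtered recording, QCReport). Removing every unit is not an error:
    the report's ``all_removed`` flag is set and an empty recording returned.
    """
    if refractory_ms <= 0:
        raise ValueError("refractory_ms must be positive")

    n = rec.n_units
    unit_ids = np.array([u.unit_id for u in rec.units], dtype=int)
    rates = np.array([u.firing_rate(rec.duration_s) for u in rec.units])
    viols = np.array(
        [refractory_violation_fraction(u, refractory_ms) for u in rec.units]
    )
    wf_ok = np.array(
        [waveform_is_ok(u, amp_min_uv) if check_waveform else True for u in rec.units],
        dtype=bool,
    )

    passed = np.zeros(n, dtype=bool)
    reasons: list = []
    kept = []
    for i, u in enumerate(rec.units):
        why = []
        if u.n_spikes < 2:
            why.append(QC_TOO_FEW_SPIKES)
        else:
            if not rates[i] > fr_min:
                why.append(QC_LOW_RATE)
            if not viols[i] < viol_max:
                why.append(QC_REFRACTORY)
            if not wf_ok[i]:
                why.append(QC_WAVEFORM)
        reasons.append(why)
        if not why:
            passed[i] = True
            kept.append(u)

    report = QCReport(
        unit_ids=unit_ids,
        firing_rate_hz=rates,
        refractory_violation_fraction=viols,
        waveform_ok=wf_ok,
        passed=passed,
        reasons=reasons,
        n_input=n,
        n_passed=len(kept),
        all_removed=(n > 0 and not kept),
    )
    return rec.with_units(kept), report
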