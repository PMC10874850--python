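"""Core data model for spike-sorted HD-MEA recordings.

A *unit* is a putative single neuron isolated by spike sorting: a vector of
spike times plus a mean multi-electrode waveform template (its electrical
footprint). A *SortedRecording* bundles the units recorded from one culture
at one time point together with the culture metadata (genotype group,
treatment, batch, age in days in vitro).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Unit",
    "SortedRecording",
    "QCReport",
    "MissingInput",
    "CorruptInput",
    "MetadataError",
    "NoSignal",
    "DegenerateConfig",
    "InvalidParameter",
    "InvalidLabels",
    "InvalidSelection",
    "SchemaError",
    "EmptyInput",
]


class MissingInput(FileNotFoundError):
    """A required input file is absent."""


class CorruptInput(ValueError):
    """Input arrays are mutually inconsistent (e.g. mismatched lengths)."""


class MetadataError(ValueError):
    """Required recording metadata is missing or invalid."""


class NoSignal(ValueError):
    """A waveform template carries no usable signal (flat / all-zero)."""


class DegenerateConfig(ValueError):
    """A simulation configuration that cannot produce any spikes."""


class InvalidParameter(ValueError):
    """A parameter outside its documented domain."""


class InvalidLabels(ValueError):
    """Labels unusable for the requested task (e.g. a single class)."""


class InvalidSelection(ValueError):
    """An empty or unknown feature/week selection."""


class SchemaError(ValueError):
    """Feature columns do not match a trained model's schema."""

    def __init__(self, message: str, missing: Optional[list] = None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class EmptyInput(ValueError):
    """An operation received an empty collection where data is required."""


@dataclass
class Unit:
    """A spike-sorted unit.

    Parameters
    ----------
    unit_id
        Identifier, unique within a recording.
    spike_times_s
        Sorted, non-decreasing spike times in seconds.
    template
        Mean spike-triggered waveform, shape (n_electrodes, n_samples), in uV.
    electrode_positions
        Electrode coordinates, shape (n_electrodes, 2), in um.
    sampling_rate_hz
        Sampling rate of the template waveform.
    """

    unit_id: int
    spike_times_s: np.ndarray
    template: np.ndarray
    electrode_positions: np.ndarray
    sampling_rate_hz: float = 20_000.0

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.template = np.atleast_2d(np.asarray(self.template, dtype=float))
        self.electrode_positions = np.atleast_2d(
            np.asarray(self.electrode_positions, dtype=float)
        )
        if np.any(np.diff(self.spike_times_s) < 0):
            raise CorruptInput(f"unit {self.unit_id}: spike times not sorted")
        if self.template.shape[0] != self.electrode_positions.shape[0]:
            raise CorruptInput(
                f"unit {self.unit_id}: template has {self.template.shape[0]} "
                f"electrodes but positions has {self.electrode_positions.shape[0]}"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def firing_rate(self, duration_s: float) -> float:
        return self.n_spikes / duration_s

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times_s)


@dataclass
class SortedRecording:
    """All units recorded from one culture at one time point."""

    culture_id: str
    group: str
    treatment: str
    batch: str
    age_days: int
    duration_s: float
    sampling_rate_hz: float
    units: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise MetadataError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise MetadataError("sampling_rate_hz must be positive")
        if self.age_days < 0:
            raise MetadataError("age_days must be non-negative")
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise CorruptInput("duplicate unit IDs within recording")
        for u in self.units:
            if u.n_spikes and (
                u.spike_times_s[0] < 0 or u.spike_times_s[-1] > self.duration_s
            ):
                raise CorruptInput(
                    f"unit {u.unit_id}: spike times outside [0, duration_s]"
                )

    @property
    def age_week(self) -> int:
        """Week in vitro, floor(age_days / 7)."""
        return int(self.age_days) // 7

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_by_id(self, unit_id: int) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def with_units(self, units: list) -> "SortedRecording":
        return replace(self, units=list(units))


# Reason codes attached to QC failures.
QC_TOO_FEW_SPIKES = "too_few_spikes"
QC_LOW_RATE = "low_firing_rate"
QC_REFRACTORY = "refractory_violations"
QC_WAVEFORM = "waveform_irregular"


@dataclass
class QCReport:
    """Per-unit quality-control outcome for one recording."""

    unit_ids: np.ndarray
    firing_rate_hz: np.ndarray
    refractory_violation_fraction: np.ndarray
    waveform_ok: np.ndarray
    passed: np.ndarray
    reasons: list  # list of list[str], failure reason codes per unit
    n_input: int = 0
    n_passed: int = 0
    all_removed: bool = False

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "all_removed": self.all_removed,
            "units": [
                {
                    "unit_id": int(uid),
                    "firing_rate_hz": float(fr),
                    "refractory_violation_fraction": float(rv),
                    "waveform_ok": bool(w),
                    "passed": bool(p),
                    "reasons": list(r),
                }
                for uid, fr, rv, w, p, r in zip(
                    self.unit_ids,
                    self.firing_rate_hz,
                    self.refractory_violation_fraction,
                    self.waveform_ok,
                    self.passed,
                    self.reasons,
                )
            ],
        }
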