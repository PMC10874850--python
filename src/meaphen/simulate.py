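"""Synthetic spike-sorted cultures with known ground truth.

The generator emulates the statistical structure of developing neuronal
cultures on high-density MEAs:

* per-unit firing as a **gamma-renewal process** whose shape parameter is set
  by a ``regularity`` knob (0 = Poisson ISIs, approaching 1 = clock-like;
  the ISI coefficient of variation is ~ sqrt(1 - regularity)),
* culture-wide **network bursts**: a shared multiplicative rate envelope with
  an exponential rise and decay around burst onsets drawn from a gamma
  inter-burst-interval process,
* **group effects** (additive parameter offsets per genotype), **batch
  effects** (multiplicative rate noise shared within a batch),
  **developmental trends** (per-parameter slope versus age in days), and
  per-culture random factors so that repeated weekly recordings of one
  culture are correlated,
* parameterized **biphasic waveform templates** (difference of two Gaussians
  in time, exponential spatial attenuation across the electrode array) drawn
  from a small set of unit archetypes, enabling ground-truth cell typing,
* optional acute **perturbation**: responder units' trains are binomially
  thinned, mimicking a firing-rate reduction after agonist application.

All randomness flows from one seeded :class:`numpy.random.SeedSequence`; the
same configuration and seed reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import DegenerateConfig, InvalidParameter, SortedRecording, Unit

__all__ = [
    "SimulationConfig",
    "WaveformArchetype",
    "GroundTruth",
    "simulate_culture_series",
    "simulate_perturbation",
    "burst_envelope",
]

_ENVELOPE_DT = 1e-3  # s, grid for envelope integration / time warping


@dataclass
class WaveformArchetype:
    """Generating parameters for one unit archetype's template."""

    name: str
    trough_uv: float = -60.0  # mean trough amplitude (negative)
    trough_uv_sd: float = 8.0
    trough_to_peak_ms: float = 0.7
    trough_to_peak_ms_sd: float = 0.05
    peak_ratio: float = 0.35  # positive peak amplitude / |trough|
    spatial_decay_um: float = 30.0
    responder_prob: float = 0.5  # probability a unit of this type responds to QP


@dataclass
class SimulationConfig:
    """Study design and generating parameters for a simulated experiment.

    Defaults describe a two-genotype, two-batch study with weekly 15-minute
    recordings over five weeks, moderate baseline firing, and pronounced
    network bursting. The mutant group fires less regularly and bursts less
    often; activity and bursting increase with age.
    """

    seed: int = 0
    groups: Tuple[str, ...] = ("WT", "A53T")
    n_cultures_per_group: int = 10
    weeks: Tuple[int, ...] = (1, 2, 3, 4, 5)
    batches: Tuple[str, ...] = ("b1", "b2")
    n_units: int = 20
    duration_s: float = 900.0
    sampling_rate_hz: float = 20_000.0
    baseline_rate_hz: float = 1.5
    burst_rate_per_min: float = 4.0
    burst_rise_s: float = 0.1
    burst_decay_s: float = 0.5
    burst_gain: float = 8.0
    regularity: float = 0.2
    group_effects: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "WT": {},
            "A53T": {
                "regularity": -0.15,
                "burst_rate_per_min": -1.5,
                "burst_decay_s": 0.25,
                "baseline_rate_hz": -0.4,
            },
        }
    )
    batch_effect_sd: float = 0.1  # lognormal sigma on rates, shared per batch
    developmental_trend: Dict[str, float] = field(
        default_factory=lambda: {
            "baseline_rate_hz": 0.03,  # Hz per day
            "burst_rate_per_min": 0.08,
            "regularity": 0.004,
        }
    )
    unit_rate_sd: float = 0.25  # lognormal sigma across units
    culture_rate_sd: float = 0.15  # lognormal sigma, per-culture random factor
    archetypes: Tuple[WaveformArchetype, ...] = (
        WaveformArchetype(
            "broad", trough_uv=-80.0, trough_to_peak_ms=0.9, responder_prob=0.3
        ),
        WaveformArchetype(
            "narrow", trough_uv=-45.0, trough_to_peak_ms=0.35, responder_prob=0.6
        ),
    )
    archetype_probs: Tuple[float, ...] = (0.6, 0.4)

    def __post_init__(self) -> None:
        if not 0.0 <= self.regularity < 1.0:
            raise InvalidParameter("regularity must be in [0, 1)")
        if self.burst_gain < 1.0:
            raise InvalidParameter("burst_gain must be >= 1")
        if self.burst_rate_per_min < 0 or self.baseline_rate_hz < 0:
            raise InvalidParameter("rates must be non-negative")


@dataclass
class GroundTruth:
    """Generating truth for a simulated experiment.

    ``burst_windows`` maps (culture_id, age_days) to an array of
    (start_s, peak_s, end_s) rows; ``unit_archetype`` maps culture_id to a
    {unit_id: archetype index} dict; ``responders`` marks the units that
    respond to an acute perturbation; ``params`` records the effective
    generating parameters per recording.
    """

    burst_windows: Dict[Tuple[str, int], np.ndarray] = field(default_factory=dict)
    unit_archetype: Dict[str, Dict[int, int]] = field(default_factory=dict)
    responders: Dict[str, Dict[int, bool]] = field(default_factory=dict)
    params: Dict[Tuple[str, int], dict] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "burst_windows": {
                f"{cid}|{age}": win.tolist()
                for (cid, age), win in self.burst_windows.items()
            },
            "unit_archetype": {
                cid: {str(k): int(v) for k, v in d.items()}
                for cid, d in self.unit_archetype.items()
            },
            "responders": {
                cid: {str(k): bool(v) for k, v in d.items()}
                for cid, d in self.responders.items()
            },
            "params": {f"{cid}|{age}": p for (cid, age), p in self.params.items()},
        }


def burst_envelope(
    duration_s: float,
    onsets_s: np.ndarray,
    rise_s: float,
    decay_s: float,
    gain: float,
    dt: float = _ENVELOPE_DT,
) -> Tuple[np.ndarray, np.ndarray]:
    """Multiplicative rate envelope: 1 plus double-exponential burst bumps.

    Each burst contributes ``(gain - 1) * f(t - t0)`` where
    ``f(t) = (exp(-t/decay) - exp(-t/rise)) / f_max`` is normalized to unit
    peak. Returns (time grid, envelope values).
    """
    t = np.arange(0.0, duration_s, dt)
    env = np.ones_like(t)
    if gain > 1.0 and onsets_s.size:
        r, d = float(rise_s), float(decay_s)
        if d <= r:  # shape needs decay slower than rise
            d = r * 1.001
        t_pk = (d * r / (d - r)) * np.log(d / r)
        f_max = np.exp(-t_pk / d) - np.exp(-t_pk / r)
        for t0 in onsets_s:
            tau = t - t0
            m = tau >= 0
            env[m] += (gain - 1.0) * (
                np.exp(-tau[m] / d) - np.exp(-tau[m] / r)
            ) / f_max
    return t, env


def _burst_onsets(
    rng: np.random.Generator,
    duration_s: float,
    rate_per_min: float,
    rise_s: float,
    decay_s: float,
) -> np.ndarray:
    """Burst onset times from a gamma inter-burst-interval process (shape 4)."""
    if rate_per_min <= 0:
        return np.array([])
    mean_ibi = 60.0 / rate_per_min
    min_gap = rise_s + 3.0 * decay_s + 0.2  # keep truth windows disjoint
    shape = 4.0
    onsets = []
    t = float(rng.uniform(0, mean_ibi))
    while t < duration_s:
        if t + rise_s + 3.0 * decay_s < duration_s:
            onsets.append(t)
        t += max(float(rng.gamma(shape, mean_ibi / shape)), min_gap)
    return np.asarray(onsets)


def _burst_windows(
    onsets_s: np.ndarray, rise_s: float, decay_s: float, duration_s: float
) -> np.ndarray:
    """Truth windows (start, peak, end) per burst; end = peak + 3*decay."""
    if onsets_s.size == 0:
        return np.empty((0, 3))
    r, d = float(rise_s), float(decay_s)
    if d <= r:
        d = r * 1.001
    t_pk = (d * r / (d - r)) * np.log(d / r)
    starts = onsets_s
    peaks = onsets_s + t_pk
    ends = np.minimum(peaks + 3.0 * d, duration_s)
    return np.column_stack([starts, peaks, ends])


def _gamma_renewal_train(
    rng: np.random.Generator,
    rate_hz: float,
    regularity: float,
    warp_t: np.ndarray,
    warp_cum: np.ndarray,
) -> np.ndarray:
    """Spike times of a rate-modulated gamma renewal process.

    The process is homogeneous with rate ``rate_hz`` in warped (operational)
    time ``Lambda(t)``; spike times are mapped back through the inverse warp.
    Shape k = 1/(1 - regularity) gives CV ~ sqrt(1/k).
    """
    if rate_hz <= 0:
        return np.array([])
    total_warped = warp_cum[-1]
    k = 1.0 / max(1.0 - regularity, 1e-6)
    n_expect = rate_hz * total_warped
    n_draw = int(n_expect + 6.0 * np.sqrt(n_expect) + 20)
    isis = rng.gamma(k, 1.0 / (k * rate_hz), size=n_draw)
    tau = np.cumsum(isis)
    while tau.size and tau[-1] < total_warped:
        more = rng.gamma(k, 1.0 / (k * rate_hz), size=n_draw)
        tau = np.concatenate([tau, tau[-1] + np.cumsum(more)])
    tau = tau[tau < total_warped]
    return np.interp(tau, warp_cum, warp_t)


def _make_template(
    rng: np.random.Generator,
    arch: WaveformArchetype,
    fs: float,
    positions: np.ndarray,
) -> np.ndarray:
    """Biphasic template: difference of Gaussians in time, exponential
    spatial decay from a randomly chosen peak electrode. The realized trough
    equals the drawn amplitude exactly (rescaled after construction)."""
    n_samp = int(round(3e-3 * fs))  # 3 ms cutout
    t_ms = np.arange(n_samp) / fs * 1e3
    trough_ms = 1.0
    amp = -abs(rng.normal(arch.trough_uv, arch.trough_uv_sd))
    t2p = max(float(rng.normal(arch.trough_to_peak_ms, arch.trough_to_peak_ms_sd)), 0.15)
    sigma_neg, sigma_pos = 0.08, 0.15  # ms; narrow lobes keep t2p recoverable
    wave = -np.exp(-((t_ms - trough_ms) ** 2) / (2 * sigma_neg**2))
    wave += arch.peak_ratio * np.exp(
        -((t_ms - trough_ms - t2p) ** 2) / (2 * sigma_pos**2)
    )
    wave *= abs(amp) / abs(wave.min())
    peak_elec = int(rng.integers(positions.shape[0]))
    dist = np.linalg.norm(positions - positions[peak_elec], axis=1)
    atten = np.exp(-dist / arch.spatial_decay_um)
    return atten[:, None] * wave[None, :]


def _effective_params(cfg: SimulationConfig, group: str, age_days: int) -> dict:
    p = {
        "baseline_rate_hz": cfg.baseline_rate_hz,
        "burst_rate_per_min": cfg.burst_rate_per_min,
        "burst_rise_s": cfg.burst_rise_s,
        "burst_decay_s": cfg.burst_decay_s,
        "burst_gain": cfg.burst_gain,
        "regularity": cfg.regularity,
    }
    for key, off in cfg.group_effects.get(group, {}).items():
        p[key] = p.get(key, 0.0) + off
    ref_age = min(cfg.weeks) * 7
    for key, slope in cfg.developmental_trend.items():
        p[key] = p.get(key, 0.0) + slope * (age_days - ref_age)
    p["baseline_rate_hz"] = max(p["baseline_rate_hz"], 0.0)
    p["burst_rate_per_min"] = max(p["burst_rate_per_min"], 0.0)
    p["regularity"] = float(np.clip(p["regularity"], 0.0, 0.95))
    p["burst_gain"] = max(p["burst_gain"], 1.0)
    p["burst_rise_s"] = max(p["burst_rise_s"], 1e-3)
    p["burst_decay_s"] = max(p["burst_decay_s"], 2e-3)
    return p


def _electrode_grid(pitch_um: float = 17.5) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(4), np.arange(2))
    return np.column_stack([xx.ravel() * pitch_um, yy.ravel() * pitch_um]).astype(float)


def simulate_culture_series(
    cfg: SimulationConfig,
) -> Tuple[List[SortedRecording], GroundTruth]:
    """Simulate every culture of the configured study across all weeks.

    Returns one SortedRecording per culture x week plus the GroundTruth.
    Raises DegenerateConfig when the expected spike count is ~0 everywhere.
    """
    max_rate = max(
        _effective_params(cfg, g, w * 7)["baseline_rate_hz"]
        for g in cfg.groups
        for w in cfg.weeks
    )
    if max_rate * cfg.duration_s < 1.0:
        raise DegenerateConfig("expected spike count < 1 for every unit")

    ss = np.random.SeedSequence(cfg.seed)
    batch_rng = np.random.default_rng(ss.spawn(1)[0])
    batch_factor = {
        b: float(np.exp(batch_rng.normal(0.0, cfg.batch_effect_sd)))
        for b in cfg.batches
    }
    positions = _electrode_grid()
    probs = np.asarray(cfg.archetype_probs, dtype=float)
    probs = probs / probs.sum()

    truth = GroundTruth()
    recordings: List[SortedRecording] = []
    culture_seeds = ss.spawn(len(cfg.groups) * cfg.n_cultures_per_group)

    idx = 0
    for gi, group in enumerate(cfg.groups):
        for ci in range(cfg.n_cultures_per_group):
            culture_id = f"{group}_{ci:02d}"
            batch = cfg.batches[(gi * cfg.n_cultures_per_group + ci) % len(cfg.batches)]
            crng = np.random.default_rng(culture_seeds[idx])
            idx += 1
            culture_factor = float(np.exp(crng.normal(0.0, cfg.culture_rate_sd)))
            unit_factors = np.exp(crng.normal(0.0, cfg.unit_rate_sd, cfg.n_units))
            # designed composition: archetype counts follow the configured
            # proportions exactly (largest-remainder rounding), shuffled
            counts = np.floor(probs * cfg.n_units).astype(int)
            rem = probs * cfg.n_units - counts
            for k in np.argsort(-rem)[: cfg.n_units - counts.sum()]:
                counts[k] += 1
            arch_idx = crng.permutation(np.repeat(np.arange(len(probs)), counts))
            templates = [
                _make_template(
                    crng, cfg.archetypes[a], cfg.sampling_rate_hz, positions
                )
                for a in arch_idx
            ]
            responders = {
                uid: bool(crng.random() < cfg.archetypes[a].responder_prob)
                for uid, a in enumerate(arch_idx)
            }
            truth.unit_archetype[culture_id] = {
                uid: int(a) for uid, a in enumerate(arch_idx)
            }
            truth.responders[culture_id] = responders

            for week in cfg.weeks:
                age_days = int(week) * 7
                p = _effective_params(cfg, group, age_days)
                wrng = np.random.default_rng(crng.integers(2**31))
                onsets = _burst_onsets(
                    wrng,
                    cfg.duration_s,
                    p["burst_rate_per_min"],
                    p["burst_rise_s"],
                    p["burst_decay_s"],
                )
                t_grid, env = burst_envelope(
                    cfg.duration_s,
                    onsets,
                    p["burst_rise_s"],
                    p["burst_decay_s"],
                    p["burst_gain"],
                )
                warp_cum = np.concatenate(
                    [[0.0], np.cumsum(env[:-1] * np.diff(t_grid))]
                )
                units = []
                for uid in range(cfg.n_units):
                    rate = (
                        p["baseline_rate_hz"]
                        * batch_factor[batch]
                        * culture_factor
                        * unit_factors[uid]
                    )
                    st = _gamma_renewal_train(
                        wrng, rate, p["regularity"], t_grid, warp_cum
                    )
                    units.append(
                        Unit(
                            unit_id=uid,
                            spike_times_s=st,
                            template=templates[uid],
                            electrode_positions=positions,
                            sampling_rate_hz=cfg.sampling_rate_hz,
                        )
                    )
                recordings.append(
                    SortedRecording(
                        culture_id=culture_id,
                        group=group,
                        treatment="untreated",
                        batch=batch,
                        age_days=age_days,
                        duration_s=cfg.duration_s,
                        sampling_rate_hz=cfg.sampling_rate_hz,
                        units=units,
                    )
                )
                truth.burst_windows[(culture_id, age_days)] = _burst_windows(
                    onsets, p["burst_rise_s"], p["burst_decay_s"], cfg.duration_s
                )
                truth.params[(culture_id, age_days)] = p
    return recordings, truth


def simulate_perturbation(
    rec: SortedRecording,
    truth: GroundTruth,
    responder_fr_ratio: float,
    seed: int = 0,
) -> SortedRecording:
    """Acute-perturbation recording: responder trains binomially thinned.

    Each spike of a responder unit is kept with probability
    ``responder_fr_ratio``; non-responders are untouched. The returned
    recording carries treatment label "QP".
    """
    if not 0.0 < responder_fr_ratio <= 1.0:
        raise InvalidParameter("responder_fr_ratio must be in (0, 1]")
    flags = truth.responders.get(rec.culture_id)
    if flags is None:
        raise InvalidParameter(
            f"no responder ground truth for culture {rec.culture_id}"
        )
    rng = np.random.default_rng(seed)
    units = []
    for u in rec.units:
        if flags.get(u.unit_id, False) and responder_fr_ratio < 1.0:
            keep = rng.random(u.n_spikes) < responder_fr_ratio
            st = u.spike_times_s[keep]
        else:
            st = u.spike_times_s.copy()
        units.append(
            Unit(
                unit_id=u.unit_id,
                spike_times_s=st,
                template=u.template.copy(),
                electrode_positions=u.electrode_positions.copy(),
                sampling_rate_hz=u.sampling_rate_hz,
            )
        )
    out = rec.with_units(units)
    out.treatment = "QP"
    return out
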