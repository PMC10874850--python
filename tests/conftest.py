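import numpy as np
import pytest

from meaphen import SimulationConfig, simulate_culture_series
from meaphen.core import SortedRecording, Unit


def make_unit(unit_id, spike_times, fs=20_000.0, trough_uv=-50.0, t2p_ms=0.6):
    """Small biphasic-template unit for hand-constructed tests."""
    n = int(3e-3 * fs)
    t_ms = np.arange(n) / fs * 1e3
    wave = trough_uv * np.exp(-((t_ms - 1.0) ** 2) / (2 * 0.08**2))
    wave += -trough_uv * 0.4 * np.exp(-((t_ms - 1.0 - t2p_ms) ** 2) / (2 * 0.15**2))
    template = np.vstack([wave, 0.3 * wave])
    pos = np.array([[0.0, 0.0], [17.5, 0.0]])
    return Unit(
        unit_id=unit_id,
        spike_times_s=np.asarray(spike_times, float),
        template=template,
        electrode_positions=pos,
        sampling_rate_hz=fs,
    )


def make_recording(units, duration_s=100.0, **meta):
    defaults = dict(
        culture_id="c0", group="WT", treatment="untreated", batch="b1",
        age_days=21, sampling_rate_hz=20_000.0,
    )
    defaults.update(meta)
    return SortedRecording(duration_s=duration_s, units=units, **defaults)


@pytest.fixture(scope="session")
def small_study():
    """2 groups x 2 cultures x 3 weeks, small but structured."""
    cfg = SimulationConfig(
        seed=11, n_cultures_per_group=2, weeks=(1, 2, 3), n_units=6,
        duration_s=120.0,
    )
    return simulate_culture_series(cfg)


@pytest.fixture(scope="session")
def single_recording(small_study):
    recs, _ = small_study
    return recs[0]
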