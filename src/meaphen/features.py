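"""Feature extraction orchestration.

Builds per-unit feature tables and culture-level feature vectors from
quality-controlled recordings. Single-cell features (waveform, spike-time,
and per-unit time-series metrics) are averaged across units to one value per
culture and recording; network features (burst, graph, network time-series)
are computed once per recording on the population activity. Time-series
feature names carry a leading ``s`` (single-cell) or ``n`` (network).

Output is tidy (long-format) pandas DataFrames, one row per
culture x recording x feature, ready for the phenotyping and statistics
layers or for CSV export.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .core import EmptyInput, NoSignal, SortedRecording
from .network import (
    BURST_FEATURE_NAMES,
    bin_population,
    compute_graph_features,
    detect_network_bursts,
    infer_connectivity_ccg,
    infer_connectivity_sttc,
)
from .spiketime import bin_spike_counts, extract_spike_time_features
from .timeseries import (
    MIN_LENGTH,
    TIMESERIES_FEATURE_NAMES,
    extract_timeseries_features,
)
from .waveform import WAVEFORM_FEATURE_NAMES, extract_waveform_features

__all__ = [
    "unit_feature_table",
    "aggregate_culture",
    "extract_network_features",
    "extract_culture_features",
    "extract_study_features",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = (
    "waveform",
    "spike-time",
    "sc-time-series",
    "burst",
    "graph",
    "net-time-series",
)

_META_COLS = ["culture_id", "unit_id"]


def unit_feature_table(
    rec: SortedRecording,
    include_timeseries: bool = True,
    bin_s: float = 0.1,
) -> pd.DataFrame:
    """Per-unit feature table: waveform + spike-time (+ time-series) metrics.

    One row per unit; metrics that cannot be computed are NaN.
    """
    rows = []
    for u in rec.units:
        row = {"culture_id": rec.culture_id, "unit_id": u.unit_id}
        try:
            row.update(extract_waveform_features(u).as_dict())
        except NoSignal:
            row.update({k: np.nan for k in WAVEFORM_FEATURE_NAMES})
        row.update(
            extract_spike_time_features(u.spike_times_s, rec.duration_s).as_dict()
        )
        if include_timeseries:
            binned = bin_spike_counts(u.spike_times_s, rec.duration_s, bin_s)
            if binned.size >= MIN_LENGTH:
                ts = extract_timeseries_features(binned, bin_s)
            else:
                ts = {k: np.nan for k in TIMESERIES_FEATURE_NAMES}
            row.update({f"s{k}": v for k, v in ts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def feature_class_of(name: str) -> str:
    """Feature class from a feature name."""
    if name in WAVEFORM_FEATURE_NAMES:
        return "waveform"
    if name in ("MIS", "CVI", "firing_rate_hz", "isi_pacf1"):
        return "spike-time"
    if name.startswith("s") and name[1:] in TIMESERIES_FEATURE_NAMES:
        return "sc-time-series"
    if name in BURST_FEATURE_NAMES:
        return "burst"
    if name in ("DEC", "GEC"):
        return "graph"
    if name.startswith("n") and name[1:] in TIMESERIES_FEATURE_NAMES:
        return "net-time-series"
    raise KeyError(f"unknown feature {name}")


def aggregate_culture(per_unit: pd.DataFrame) -> pd.DataFrame:
    """Average per-unit features to one representative value per culture.

    NaN (not-available) entries are ignored per feature; the number of units
    contributing to each feature is recorded. Raises EmptyInput with zero
    rows.
    """
    if per_unit.empty:
        raise EmptyInput("no passing units to aggregate")
    feat_cols = [c for c in per_unit.columns if c not in _META_COLS]
    out = []
    for cid, grp in per_unit.groupby("culture_id", sort=True):
        for col in feat_cols:
            vals = grp[col].to_numpy(dtype=float)
            n_ok = int(np.sum(~np.isnan(vals)))
            out.append(
                {
                    "culture_id": cid,
                    "feature": col,
                    "value": float(np.nanmean(vals)) if n_ok else np.nan,
                    "n_units": n_ok,
                }
            )
    return pd.DataFrame(out)


def extract_network_features(
    rec: SortedRecording,
    bin_s: float = 0.1,
    graph_method: str = "ccg",
    graph_kwargs: Optional[dict] = None,
    seed: int = 0,
) -> dict:
    """Burst, graph, and network time-series features for one recording."""
    out: dict = {}
    pop = bin_population(rec, bin_s=bin_s)
    bursts = detect_network_bursts(pop)
    out.update(bursts.features)

    kwargs = dict(graph_kwargs or {})
    if rec.n_units >= 2:
        if graph_method == "ccg":
            g = infer_connectivity_ccg(rec, seed=seed, **kwargs)
        elif graph_method == "sttc":
            g = infer_connectivity_sttc(rec, **kwargs)
        else:
            raise ValueError(f"unknown graph method {graph_method!r}")
        out.update(compute_graph_features(g))
    else:
        out.update({"DEC": np.nan, "GEC": np.nan})

    if pop.counts.size >= MIN_LENGTH:
        ts = extract_timeseries_features(pop.counts, bin_s)
    else:
        ts = {k: np.nan for k in TIMESERIES_FEATURE_NAMES}
    out.update({f"n{k}": v for k, v in ts.items()})
    return out


def extract_culture_features(
    rec: SortedRecording,
    bin_s: float = 0.1,
    graph_method: str = "ccg",
    graph_kwargs: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy culture-level feature rows for one recording (all classes)."""
    meta = {
        "culture_id": rec.culture_id,
        "group": rec.group,
        "treatment": rec.treatment,
        "batch": rec.batch,
        "age_days": rec.age_days,
        "age_week": rec.age_week,
    }
    rows: List[dict] = []
    if rec.n_units:
        per_unit = unit_feature_table(rec, bin_s=bin_s)
        agg = aggregate_culture(per_unit)
        for _, r in agg.iterrows():
            rows.append(
                {
                    **meta,
                    "feature": r["feature"],
                    "feature_class": feature_class_of(r["feature"]),
                    "value": r["value"],
                    "n_units": r["n_units"],
                }
            )
    net = extract_network_features(
        rec, bin_s=bin_s, graph_method=graph_method,
        graph_kwargs=graph_kwargs, seed=seed,
    )
    for name, val in net.items():
        rows.append(
            {
                **meta,
                "feature": name,
                "feature_class": feature_class_of(name),
                "value": val,
                "n_units": rec.n_units,
            }
        )
    return pd.DataFrame(rows)


def extract_study_features(
    recordings: Iterable[SortedRecording],
    bin_s: float = 0.1,
    graph_method: str = "ccg",
    graph_kwargs: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenated tidy feature table over a whole study."""
    frames = [
        extract_culture_features(
            rec, bin_s=bin_s, graph_method=graph_method,
            graph_kwargs=graph_kwargs, seed=seed,
        )
        for rec in recordings
    ]
    if not frames:
        raise EmptyInput("no recordings")
    return pd.concat(frames, ignore_index=True)
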