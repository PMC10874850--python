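"""Readers and writers for spike-sorted recordings.

Two on-disk layouts are supported:

* **Layout A** — the phy/Kilosort convention: ``spike_times.npy`` (sample
  indices), ``spike_clusters.npy`` (or ``spike_templates.npy``),
  ``templates.npy`` with shape (n_templates, n_samples, n_channels),
  ``channel_positions.npy``, and a ``params.py``/``params.json`` carrying
  ``sample_rate``.
* **Layout B** — a portable exchange bundle: ``manifest.json`` (metadata +
  duration + sampling rate), ``spikes.csv`` with columns ``unit_id,time_s``,
  and ``templates.npy`` (units x electrodes x samples) with
  ``electrode_positions.npy``. CSV template variants are accepted.

Required metadata (``culture_id``, ``group``, ``age_days``) comes from the
``metadata`` mapping passed to :func:`load_recording`, with the manifest as a
fallback for layout B.
"""

from __future__ import annotations

import ast
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import CorruptInput, MetadataError, MissingInput, SortedRecording, Unit

__all__ = ["load_recording", "write_bundle", "read_metadata_table"]

_REQUIRED_META = ("culture_id", "group", "age_days")


def _parse_params_py(path: Path) -> dict:
    """Parse a phy params.py (simple ``key = literal`` assignments)."""
    out = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, val = line.partition("=")
        try:
            out[key.strip()] = ast.literal_eval(val.strip())
        except (ValueError, SyntaxError):
            out[key.strip()] = val.strip()
    return out


def _finalize_meta(metadata: Mapping, defaults: Optional[Mapping] = None) -> dict:
    meta = dict(defaults or {})
    meta.update({k: v for k, v in (metadata or {}).items() if v is not None})
    missing = [k for k in _REQUIRED_META if meta.get(k) in (None, "")]
    if missing:
        raise MetadataError(f"missing required metadata: {missing}")
    meta.setdefault("treatment", "untreated")
    meta.setdefault("batch", "batch0")
    return meta


def load_recording(path, metadata: Optional[Mapping] = None) -> SortedRecording:
    """Load a spike-sorted recording from a supported directory layout.

    Layout is auto-detected: ``manifest.json`` selects layout B, otherwise
    phy-style NPY files are expected.
    """
    path = Path(path)
    if not path.is_dir():
        raise MissingInput(f"not a directory: {path}")
    if (path / "manifest.json").exists():
        return _load_bundle(path, metadata)
    return _load_phy(path, metadata)


def _load_phy(path: Path, metadata: Optional[Mapping]) -> SortedRecording:
    for fname in ("spike_times.npy", "templates.npy", "channel_positions.npy"):
        if not (path / fname).exists():
            raise MissingInput(f"missing {fname} in {path}")
    spike_samples = np.load(path / "spike_times.npy").ravel()
    if (path / "spike_clusters.npy").exists():
        clusters = np.load(path / "spike_clusters.npy").ravel()
    elif (path / "spike_templates.npy").exists():
        clusters = np.load(path / "spike_templates.npy").ravel()
    else:
        raise MissingInput(f"missing spike_clusters.npy/spike_templates.npy in {path}")
    if spike_samples.size != clusters.size:
        raise CorruptInput(
            f"spike_times ({spike_samples.size}) and cluster assignments "
            f"({clusters.size}) differ in length"
        )
    templates = np.load(path / "templates.npy")  # (n_templates, n_samples, n_chan)
    positions = np.load(path / "channel_positions.npy")
    if templates.ndim != 3:
        raise CorruptInput("templates.npy must be 3-D (templates x samples x channels)")
    if templates.shape[2] != positions.shape[0]:
        raise CorruptInput("templates channel count does not match channel_positions")

    params: dict = {}
    if (path / "params.json").exists():
        params = json.loads((path / "params.json").read_text())
    elif (path / "params.py").exists():
        params = _parse_params_py(path / "params.py")
    meta = _finalize_meta(metadata or {}, params)
    fs = float(meta.get("sampling_rate_hz") or params.get("sample_rate") or 0)
    if fs <= 0:
        raise MetadataError("sampling rate not found in params or metadata")

    order = np.argsort(spike_samples, kind="stable")
    spike_samples = spike_samples[order]
    clusters = clusters[order]
    times_s = spike_samples.astype(float) / fs
    duration = float(meta.get("duration_s") or (times_s[-1] if times_s.size else 0.0))

    units = []
    for uid in np.unique(clusters):
        st = times_s[clusters == uid]
        units.append(
            Unit(
                unit_id=int(uid),
                spike_times_s=st,
                template=templates[int(uid)].T,  # -> electrodes x samples
                electrode_positions=positions[:, :2],
                sampling_rate_hz=fs,
            )
        )
    return SortedRecording(
        culture_id=str(meta["culture_id"]),
        group=str(meta["group"]),
        treatment=str(meta["treatment"]),
        batch=str(meta["batch"]),
        age_days=int(meta["age_days"]),
        duration_s=duration,
        sampling_rate_hz=fs,
        units=units,
    )


def _load_bundle(path: Path, metadata: Optional[Mapping]) -> SortedRecording:
    manifest = json.loads((path / "manifest.json").read_text())
    spikes_file = path / "spikes.csv"
    if not spikes_file.exists():
        raise MissingInput(f"missing spikes.csv in {path}")
    spikes = pd.read_csv(spikes_file)
    if not {"unit_id", "time_s"} <= set(spikes.columns):
        raise CorruptInput("spikes.csv must have columns unit_id,time_s")

    if (path / "templates.npy").exists():
        templates = np.load(path / "templates.npy")
    elif (path / "templates.csv").exists():
        flat = pd.read_csv(path / "templates.csv")
        shape = manifest.get("template_shape")
        if shape is None:
            raise CorruptInput("templates.csv requires template_shape in manifest")
        templates = flat.to_numpy(dtype=float).reshape(shape)
    else:
        raise MissingInput(f"missing templates.npy/templates.csv in {path}")
    if (path / "electrode_positions.npy").exists():
        positions = np.load(path / "electrode_positions.npy")
    elif (path / "electrode_positions.csv").exists():
        positions = pd.read_csv(path / "electrode_positions.csv").to_numpy(float)
    else:
        raise MissingInput(f"missing electrode_positions in {path}")

    meta = _finalize_meta(metadata or {}, manifest)
    fs = float(meta.get("sampling_rate_hz") or 20_000.0)
    unit_ids = manifest.get("unit_ids")
    if unit_ids is None:
        unit_ids = sorted(spikes["unit_id"].unique().tolist())
    if templates.shape[0] != len(unit_ids):
        raise CorruptInput(
            f"{templates.shape[0]} templates for {len(unit_ids)} units"
        )
    units = []
    for i, uid in enumerate(unit_ids):
        st = np.sort(spikes.loc[spikes["unit_id"] == uid, "time_s"].to_numpy(float))
        units.append(
            Unit(
                unit_id=int(uid),
                spike_times_s=st,
                template=templates[i],
                electrode_positions=positions,
                sampling_rate_hz=fs,
            )
        )
    return SortedRecording(
        culture_id=str(meta["culture_id"]),
        group=str(meta["group"]),
        treatment=str(meta["treatment"]),
        batch=str(meta["batch"]),
        age_days=int(meta["age_days"]),
        duration_s=float(meta["duration_s"]),
        sampling_rate_hz=fs,
        units=units,
    )


def write_bundle(rec: SortedRecording, path) -> Path:
    """Write a recording as a portable layout-B bundle; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    unit_ids = [u.unit_id for u in rec.units]
    manifest = {
        "culture_id": rec.culture_id,
        "group": rec.group,
        "treatment": rec.treatment,
        "batch": rec.batch,
        "age_days": int(rec.age_days),
        "duration_s": float(rec.duration_s),
        "sampling_rate_hz": float(rec.sampling_rate_hz),
        "unit_ids": unit_ids,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = [
        {"unit_id": u.unit_id, "time_s": t}
        for u in rec.units
        for t in u.spike_times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        path / "spikes.csv", index=False
    )
    if rec.units:
        templates = np.stack([u.template for u in rec.units])
        np.save(path / "templates.npy", templates)
        np.save(path / "electrode_positions.npy", rec.units[0].electrode_positions)
    return path


def read_metadata_table(path) -> pd.DataFrame:
    """Read a culture metadata table (CSV or JSON records).

    Expected columns: culture_id, group, treatment, batch, age_days.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInput(str(path))
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table missing columns: {missing}")
    return df
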