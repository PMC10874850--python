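"""Unit-level cell typing: clustering, cluster classifiers, composition
prediction, and acute-perturbation response mapping.

Units pooled across cultures are clustered on z-scored waveform features
(``mode="waveform"``) or waveform plus activity features — spike-time and
per-unit time-series metrics (``mode="combined"``). Clustering is Louvain
community detection on a k-nearest-neighbor graph, with cluster IDs
relabeled by descending size. A random-forest classifier trained on the
clusters can then predict cluster compositions of new cultures, and an
acute drug application (baseline versus post recordings of the same units)
is summarized as per-cluster responder fractions, where a responder shows a
firing-rate drop beyond a configurable threshold.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import kneighbors_graph

from .core import EmptyInput, InvalidParameter, SchemaError, SortedRecording
from .features import unit_feature_table
from .spiketime import SPIKE_TIME_FEATURE_NAMES
from .waveform import WAVEFORM_FEATURE_NAMES

__all__ = [
    "build_unit_feature_table",
    "ClusterAssignment",
    "cluster_units",
    "train_cluster_classifier",
    "predict_composition",
    "PerturbationResponse",
    "map_perturbation_response",
]

_KEY_COLS = ["culture_id", "unit_id"]


def build_unit_feature_table(
    recordings: Iterable[SortedRecording], mode: str = "combined"
) -> pd.DataFrame:
    """Pooled per-unit feature table across cultures.

    ``mode="waveform"`` keeps only waveform metrics; ``mode="combined"``
    adds spike-time and single-cell time-series metrics. Rows that are
    entirely not-available are dropped; remaining NaNs are imputed with the
    column median.
    """
    if mode not in ("waveform", "combined"):
        raise InvalidParameter(f"unknown mode {mode!r}")
    tables = [
        unit_feature_table(rec, include_timeseries=(mode == "combined"))
        for rec in recordings
    ]
    if not tables:
        raise EmptyInput("no recordings")
    t = pd.concat(tables, ignore_index=True)
    if mode == "waveform":
        t = t[_KEY_COLS + WAVEFORM_FEATURE_NAMES]
    feat_cols = [c for c in t.columns if c not in _KEY_COLS]
    t = t.dropna(subset=feat_cols, how="all").reset_index(drop=True)
    t[feat_cols] = t[feat_cols].fillna(t[feat_cols].median())
    return t


@dataclass
class ClusterAssignment:
    """Louvain partition of the unit feature table."""

    table: pd.DataFrame  # culture_id, unit_id, cluster
    embedding: np.ndarray  # 2-D UMAP coordinates, rows as in table
    modularity: float
    cluster_sizes: pd.Series

    @property
    def labels(self) -> np.ndarray:
        return self.table["cluster"].to_numpy()


def _zscore_columns(X: pd.DataFrame) -> np.ndarray:
    """Column-wise z-scoring with a near-constant filter.

    Columns whose spread is below 1e-3 of their magnitude carry only
    numerical residue; z-scoring would inflate that residue into a
    full-variance noise axis, so such columns are zeroed instead.
    """
    sd = X.std(ddof=1)
    scale = X.abs().mean().combine(sd, max)
    degenerate = sd <= 1e-3 * scale.where(scale > 0, 1.0)
    Z = (X - X.mean()) / sd.mask(degenerate | (sd == 0.0))
    return Z.fillna(0.0).to_numpy()


def cluster_units(
    table: pd.DataFrame,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    compute_embedding: bool = True,
) -> ClusterAssignment:
    """Louvain clustering of units on a k-nearest-neighbor graph.

    Features are z-scored column-wise; the kNN graph is built in that
    space; Louvain community detection (seeded) yields the partition, and
    cluster IDs are relabeled by descending cluster size. Requires >= 10
    units and more units than ``n_neighbors``.
    """
    feat_cols = [c for c in table.columns if c not in _KEY_COLS]
    n = len(table)
    if n < 10:
        raise InvalidParameter("need >= 10 units to cluster")
    if n <= n_neighbors:
        raise InvalidParameter("fewer units than n_neighbors")
    Z = _zscore_columns(table[feat_cols])
    knn = kneighbors_graph(Z, n_neighbors=n_neighbors, mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()
    g = ig.Graph(
        n=n, edges=list(zip(knn.row.tolist(), knn.col.tolist())),
        directed=False,
    ).simplify()
    rng = random.Random(seed)
    ig.set_random_number_generator(rng)
    part = g.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership)
    # relabel by descending size, ties by original label for determinism
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])

    coords = np.zeros((n, 2))
    if compute_embedding:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = umap.UMAP(
                n_components=2, n_neighbors=n_neighbors, min_dist=0.1,
                random_state=seed,
            ).fit_transform(Z)

    out = table[_KEY_COLS].copy()
    out["cluster"] = labels
    sizes = out["cluster"].value_counts().sort_index()
    return ClusterAssignment(
        table=out,
        embedding=coords,
        modularity=float(g.modularity(part.membership)),
        cluster_sizes=sizes,
    )


@dataclass
class ClusterClassifier:
    model: RandomForestClassifier
    schema: list
    confusion: pd.DataFrame
    importance: pd.DataFrame
    merged_clusters: Dict[int, int]


def train_cluster_classifier(
    table: pd.DataFrame,
    clusters: np.ndarray,
    min_cluster_size: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> ClusterClassifier:
    """Random-forest cluster classifier with stratified k-fold CV.

    Clusters below ``min_cluster_size`` are merged into the nearest cluster
    (centroid distance in z-scored feature space) with a warning. Returns
    the refit model, the CV confusion matrix, and permutation importance
    per feature.
    """
    feat_cols = [c for c in table.columns if c not in _KEY_COLS]
    y = np.asarray(clusters).copy()
    Z = _zscore_columns(table[feat_cols])

    merged: Dict[int, int] = {}
    ids, counts = np.unique(y, return_counts=True)
    small = ids[counts < min_cluster_size]
    big = ids[counts >= min_cluster_size]
    if small.size and big.size:
        warnings.warn(f"merging small clusters {small.tolist()} into nearest")
        centroids = {c: Z[y == c].mean(axis=0) for c in ids}
        for c in small:
            target = min(
                big, key=lambda b: np.linalg.norm(centroids[c] - centroids[b])
            )
            merged[int(c)] = int(target)
            y[y == c] = target

    classes = np.unique(y)
    n_folds = min(n_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    conf = np.zeros((classes.size, classes.size), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for tr, te in skf.split(Z, y):
        clf = RandomForestClassifier(n_estimators=300, random_state=seed)
        clf.fit(Z[tr], y[tr])
        for t_true, t_pred in zip(y[te], clf.predict(Z[te])):
            conf[pos[t_true], pos[t_pred]] += 1
    confusion = pd.DataFrame(conf, index=classes, columns=classes)

    final = RandomForestClassifier(n_estimators=300, random_state=seed)
    final.fit(Z, y)
    rng = np.random.default_rng(seed)
    base = final.score(Z, y)
    rows = []
    for j, col in enumerate(feat_cols):
        drops = []
        for _ in range(5):
            Zp = Z.copy()
            Zp[:, j] = Zp[rng.permutation(len(Zp)), j]
            drops.append(base - final.score(Zp, y))
        rows.append({"feature": col, "importance": float(np.mean(drops))})
    importance = (
        pd.DataFrame(rows).sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )
    return ClusterClassifier(final, feat_cols, confusion, importance, merged)


def predict_composition(
    clf: ClusterClassifier, new_units: pd.DataFrame
) -> pd.DataFrame:
    """Per-culture predicted cluster fractions (sum to 1) plus counts."""
    if new_units.empty:
        raise EmptyInput("no units to classify")
    missing = [c for c in clf.schema if c not in new_units.columns]
    if missing:
        raise SchemaError("missing feature columns", missing=missing)
    Z = _zscore_columns(new_units[clf.schema])
    pred = clf.model.predict(Z)
    out = []
    for cid, grp in pd.DataFrame(
        {"culture_id": new_units["culture_id"], "cluster": pred}
    ).groupby("culture_id"):
        counts = grp["cluster"].value_counts()
        for c in clf.model.classes_:
            n = int(counts.get(c, 0))
            out.append(
                {
                    "culture_id": cid,
                    "cluster": int(c),
                    "count": n,
                    "fraction": n / len(grp),
                }
            )
    return pd.DataFrame(out)


@dataclass
class PerturbationResponse:
    """Per-unit firing-rate change after an acute perturbation."""

    table: pd.DataFrame  # culture_id, unit_id, baseline/post FR, ratio, responder, cluster
    cluster_fractions: pd.Series
    n_unmatched: int


def map_perturbation_response(
    baseline: SortedRecording,
    post: SortedRecording,
    clusters: Optional[pd.DataFrame] = None,
    decrease_threshold: float = 0.1,
) -> PerturbationResponse:
    """Responder mapping: FR ratio post/baseline per matched unit.

    A unit is a responder when its ratio drops below 1 - decrease_threshold.
    ``clusters`` (culture_id, unit_id, cluster) attaches cluster IDs, and
    per-cluster responder fractions are reported. Unmatched units are
    dropped and counted.
    """
    base_ids = {u.unit_id for u in baseline.units}
    post_ids = {u.unit_id for u in post.units}
    common = sorted(base_ids & post_ids)
    n_unmatched = len(base_ids ^ post_ids)
    rows = []
    for uid in common:
        fr0 = baseline.unit_by_id(uid).firing_rate(baseline.duration_s)
        fr1 = post.unit_by_id(uid).firing_rate(post.duration_s)
        ratio = fr1 / fr0 if fr0 > 0 else np.nan
        rows.append(
            {
                "culture_id": baseline.culture_id,
                "unit_id": uid,
                "baseline_fr_hz": fr0,
                "post_fr_hz": fr1,
                "fr_ratio": ratio,
                "responder": bool(ratio < 1.0 - decrease_threshold)
                if np.isfinite(ratio)
                else False,
            }
        )
    t = pd.DataFrame(rows)
    if clusters is not None and not t.empty:
        t = t.merge(
            clusters[_KEY_COLS + ["cluster"]], on=_KEY_COLS, how="left"
        )
        fractions = t.dropna(subset=["cluster"]).groupby("cluster")[
            "responder"
        ].mean()
    else:
        fractions = pd.Series(dtype=float)
    return PerturbationResponse(t, fractions, n_unmatched)
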