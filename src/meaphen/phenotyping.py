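"""Machine-learning phenotyping: feature matrices, batch normalization,
random-forest classification/regression, importance, model transfer, and
low-dimensional embedding.

The central object is the :class:`FeatureMatrix`: cultures as rows, columns
spanning the selected recording weeks x features (week-major order), with
culture metadata (group, treatment, batch) carried alongside. Before any fit
the matrix is batch-wise z-scored using parameters derived from training
rows only, which removes inter-batch offsets without leaking test
information. Classification accuracy uses leave-one-culture-out
cross-validation; age regression holds out all recordings of a culture
together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .core import InvalidLabels, InvalidParameter, InvalidSelection, SchemaError

__all__ = [
    "FeatureMatrix",
    "PhenotypeModel",
    "EvaluationResult",
    "EmbeddingResult",
    "assemble_feature_matrix",
    "batch_zscore",
    "classify_loo",
    "permutation_importance",
    "tune_hyperparameters",
    "predict_age",
    "apply_pretrained",
    "embed_and_purity",
    "cluster_purity",
]

_CONTROL_TREATMENTS = ("untreated", "ntLNA", "none", "control")


@dataclass
class FeatureMatrix:
    """Cultures x (weeks x features) design matrix with metadata.

    ``values`` has one column per (age_week, feature), named
    ``w{week}:{feature}``; ``row_meta`` is indexed like ``values`` and holds
    culture_id/group/treatment/batch; ``col_info`` maps each column to its
    week, feature name and feature class; ``imputed`` flags filled cells.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    col_info: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def columns_for_weeks(self, weeks: Sequence[int]) -> List[str]:
        return list(self.col_info.index[self.col_info["age_week"].isin(weeks)])


@dataclass
class NormParams:
    """Per-batch (and global-fallback) z-scoring parameters."""

    by_batch: Dict[str, Tuple[pd.Series, pd.Series]]
    global_mean: pd.Series
    global_sd: pd.Series
    fallback_batches: List[str] = field(default_factory=list)


@dataclass
class PhenotypeModel:
    model: object
    norm: NormParams
    schema: List[str]
    task: str  # "classification" | "regression"
    classes: Optional[np.ndarray] = None


@dataclass
class EvaluationResult:
    predictions: pd.DataFrame
    accuracy: Optional[float] = None
    mae_days: Optional[float] = None
    mae_by_week: Optional[pd.Series] = None
    baseline_mae_days: Optional[float] = None
    importance: Optional[pd.DataFrame] = None


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    kmeans_labels: np.ndarray
    purity: float


def assemble_feature_matrix(
    feature_table: pd.DataFrame,
    feature_classes: Optional[Sequence[str]] = None,
    weeks: Optional[Sequence[int]] = None,
) -> FeatureMatrix:
    """Pivot a tidy feature table into the cultures x (weeks x features)
    matrix.

    Column order is deterministic: week-major, feature name second. Missing
    culture-week cells are imputed with the per-column median of same-group
    cultures (global column median as last resort) and flagged in
    ``imputed``.
    """
    t = feature_table.copy()
    if feature_classes is not None:
        feature_classes = list(feature_classes)
        if not feature_classes:
            raise InvalidSelection("empty feature-class selection")
        unknown = set(feature_classes) - set(t["feature_class"].unique())
        t = t[t["feature_class"].isin(feature_classes)]
        if t.empty:
            raise InvalidSelection(f"no features in classes {feature_classes}"
                                   + (f" (unknown: {sorted(unknown)})" if unknown else ""))
    if "age_week" not in t.columns:
        t["age_week"] = t["age_days"] // 7
    if weeks is not None:
        weeks = sorted(set(int(w) for w in weeks))
        if not weeks:
            raise InvalidSelection("empty week selection")
        t = t[t["age_week"].isin(weeks)]
        if t.empty:
            raise InvalidSelection(f"no recordings in weeks {weeks}")

    t["column"] = "w" + t["age_week"].astype(int).astype(str) + ":" + t["feature"]
    wide = t.pivot_table(index="culture_id", columns="column", values="value",
                         aggfunc="mean")
    col_info = (
        t[["column", "age_week", "feature", "feature_class"]]
        .drop_duplicates("column")
        .set_index("column")
    )
    order = col_info.sort_values(["age_week", "feature"]).index
    wide = wide.reindex(columns=order)
    col_info = col_info.loc[order]

    meta = (
        t[["culture_id", "group", "treatment", "batch"]]
        .drop_duplicates("culture_id")
        .set_index("culture_id")
        .loc[wide.index]
    )

    imputed = wide.isna()
    # drop columns with no observed value at all
    dead = wide.columns[wide.isna().all()]
    wide = wide.drop(columns=dead)
    col_info = col_info.drop(index=dead)
    imputed = imputed.drop(columns=dead)
    for col in wide.columns[wide.isna().any()]:
        grp_med = wide.groupby(meta["group"])[col].transform("median")
        fill = grp_med.fillna(wide[col].median())
        wide[col] = wide[col].fillna(fill)
    return FeatureMatrix(values=wide, row_meta=meta, col_info=col_info,
                         imputed=imputed)


def batch_zscore(
    fm: FeatureMatrix, train_rows: Optional[Sequence] = None
) -> Tuple[pd.DataFrame, NormParams]:
    """Batch-wise z-scoring with parameters derived from training rows only.

    Per batch and column: subtract the training mean, divide by the training
    sample sd; zero-variance columns map to 0. Batches with fewer than 2
    training rows fall back to global training parameters (with a warning).
    """
    X = fm.values
    train_idx = X.index if train_rows is None else pd.Index(train_rows)
    train = X.loc[train_idx]
    g_mean = train.mean()
    g_sd = train.std(ddof=1)
    by_batch: Dict[str, Tuple[pd.Series, pd.Series]] = {}
    fallback = []
    for b in fm.row_meta["batch"].unique():
        members = train_idx[fm.row_meta.loc[train_idx, "batch"] == b]
        if len(members) < 2:
            by_batch[b] = (g_mean, g_sd)
            fallback.append(b)
            warnings.warn(
                f"batch {b!r} has <2 training rows; using global parameters"
            )
        else:
            sub = X.loc[members]
            by_batch[b] = (sub.mean(), sub.std(ddof=1))
    norm = NormParams(by_batch, g_mean, g_sd, fallback)
    return _apply_norm(X, fm.row_meta["batch"], norm), norm


def _apply_norm(
    X: pd.DataFrame, batches: pd.Series, norm: NormParams
) -> pd.DataFrame:
    out = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    for b, rows in X.groupby(batches):
        mean, sd = norm.by_batch.get(b, (norm.global_mean, norm.global_sd))
        sd = sd.replace(0.0, np.nan)
        z = (rows - mean) / sd
        out.loc[rows.index] = z.fillna(0.0)
    return out


def _make_classifier(seed: int, **params) -> RandomForestClassifier:
    defaults = dict(
        n_estimators=500, class_weight="balanced_subsample", random_state=seed
    )
    defaults.update(params)
    return RandomForestClassifier(**defaults)


def classify_loo(
    fm: FeatureMatrix,
    labels: Optional[pd.Series] = None,
    seed: int = 0,
    rf_params: Optional[dict] = None,
) -> Tuple[EvaluationResult, PhenotypeModel]:
    """Leave-one-culture-out random-forest classification.

    One fold per culture; each fold re-derives batch z-scoring parameters
    from its training rows, then fits a fresh forest. The returned model is
    refit on all rows (with all-row normalization) for later transfer.
    """
    y = (labels if labels is not None else fm.row_meta["group"]).loc[
        fm.values.index
    ]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise InvalidLabels("need >= 2 classes")
    if np.any(counts < 2):
        raise InvalidLabels("need >= 2 cultures per class")

    params = rf_params or {}
    preds = []
    for i, cid in enumerate(fm.values.index):
        train_rows = fm.values.index.drop(cid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xz, norm = batch_zscore(fm, train_rows)
        clf = _make_classifier(seed + 1000 + i, **params)
        clf.fit(Xz.loc[train_rows], y.loc[train_rows])
        pred = clf.predict(Xz.loc[[cid]])[0]
        proba = clf.predict_proba(Xz.loc[[cid]])[0]
        preds.append(
            {"culture_id": cid, "true": y.loc[cid], "predicted": pred,
             **{f"score_{c}": p for c, p in zip(clf.classes_, proba)}}
        )
    pred_df = pd.DataFrame(preds).set_index("culture_id")
    acc = float((pred_df["true"] == pred_df["predicted"]).mean())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xz_all, norm_all = batch_zscore(fm)
    final = _make_classifier(seed, **params)
    final.fit(Xz_all, y)
    model = PhenotypeModel(
        model=final, norm=norm_all, schema=list(fm.values.columns),
        task="classification", classes=final.classes_,
    )
    return EvaluationResult(predictions=pred_df, accuracy=acc), model


def permutation_importance(
    model: PhenotypeModel,
    fm: FeatureMatrix,
    labels: Optional[pd.Series] = None,
    by_time: bool = False,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation predictor importance of the fitted model.

    Shuffles each feature's columns (all weeks jointly, or per week when
    ``by_time``) and reports the mean drop in score. Returns one row per
    feature (x week).
    """
    y = (labels if labels is not None else fm.row_meta["group"]).loc[
        fm.values.index
    ]
    Xz = _apply_norm(fm.values, fm.row_meta["batch"], model.norm)
    Xz = Xz[model.schema]
    base = model.model.score(Xz, y)
    rng = np.random.default_rng(seed)

    if by_time:
        groups = [
            ((feat, int(week)), list(sub.index))
            for (feat, week), sub in fm.col_info.groupby(["feature", "age_week"])
        ]
    else:
        groups = [
            ((feat, None), list(sub.index))
            for feat, sub in fm.col_info.groupby("feature")
        ]

    rows = []
    for (feat, week), cols in groups:
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = Xz.copy()
            perm = rng.permutation(len(Xp))
            Xp[cols] = Xp[cols].to_numpy()[perm]
            drops[r] = base - model.model.score(Xp, y)
        row = {"feature": feat, "importance": float(drops.mean()),
               "importance_sd": float(drops.std(ddof=1))}
        if by_time:
            row["age_week"] = week
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        "importance", ascending=False
    ).reset_index(drop=True)


def tune_hyperparameters(
    fm: FeatureMatrix,
    labels: Optional[pd.Series] = None,
    budget: int = 100,
    n_folds: int = 5,
    seed: int = 0,
) -> Tuple[dict, float]:
    """Seeded randomized hyperparameter search with inner k-fold CV.

    Samples forest settings (tree count, depth, leaf size, features per
    split) and returns the best setting with its inner-CV accuracy.
    Deterministic given the seed.
    """
    if budget < 1:
        raise InvalidParameter("budget must be >= 1")
    y = (labels if labels is not None else fm.row_meta["group"]).loc[
        fm.values.index
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xz, _ = batch_zscore(fm)
    rng = np.random.default_rng(seed)
    space = {
        "n_estimators": [100, 300, 500],
        "max_depth": [None, 3, 5, 10, 20],
        "min_samples_leaf": [1, 2, 4],
        "max_features": ["sqrt", 0.3, 0.6, 1.0],
    }
    n_folds = min(n_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    if n_folds < 2:
        raise InvalidLabels("not enough rows per class for inner CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xz, y))
    best_score, best_params = -np.inf, None
    for _ in range(budget):
        params = {k: v[rng.integers(len(v))] for k, v in space.items()}
        scores = []
        for tr, te in splits:
            clf = _make_classifier(seed, **params)
            clf.fit(Xz.iloc[tr], y.iloc[tr])
            scores.append(clf.score(Xz.iloc[te], y.iloc[te]))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    return best_params, best_score


def predict_age(
    feature_table: pd.DataFrame,
    seed: int = 0,
    rf_params: Optional[dict] = None,
) -> EvaluationResult:
    """Leave-one-culture-out random-forest age regression.

    Rows are individual recordings (culture x week); all recordings of the
    held-out culture leave the training set together, preventing culture
    identity leakage. Reports MAE overall and per true week, plus the
    predict-the-training-mean baseline MAE.
    """
    t = feature_table.copy()
    if "age_week" not in t.columns:
        t["age_week"] = t["age_days"] // 7
    wide = t.pivot_table(
        index=["culture_id", "age_days"], columns="feature", values="value"
    )
    wide = wide.dropna(axis=1, how="all")
    wide = wide.fillna(wide.median())
    ages = wide.index.get_level_values("age_days").to_numpy(float)
    if np.unique(ages).size < 3:
        raise InvalidLabels("need >= 3 distinct ages")

    cultures = wide.index.get_level_values("culture_id")
    params = dict(n_estimators=500, random_state=seed)
    params.update(rf_params or {})
    preds = np.empty(len(wide))
    for cid in cultures.unique():
        te = cultures == cid
        reg = RandomForestRegressor(**params)
        reg.fit(wide.to_numpy()[~te], ages[~te])
        preds[te] = reg.predict(wide.to_numpy()[te])

    err = np.abs(preds - ages)
    weeks = (ages // 7).astype(int)
    mae_by_week = pd.Series(err).groupby(weeks).mean()
    mae_by_week.index.name = "age_week"
    # baseline: predict the training mean age for each held-out culture
    base_err = []
    for cid in cultures.unique():
        te = cultures == cid
        base_err.append(np.abs(ages[te] - ages[~te].mean()))
    pred_df = pd.DataFrame(
        {"culture_id": cultures, "age_days": ages, "predicted_days": preds}
    )
    return EvaluationResult(
        predictions=pred_df,
        mae_days=float(err.mean()),
        mae_by_week=mae_by_week,
        baseline_mae_days=float(np.concatenate(base_err).mean()),
    )


def apply_pretrained(
    model: PhenotypeModel, new_fm: FeatureMatrix
) -> pd.DataFrame:
    """Apply a trained classifier to new (e.g., treated) cultures.

    Columns are aligned by name; any missing column raises SchemaError. New
    batches are z-scored with their own statistics computed on
    control/untreated rows when present, otherwise on all rows of the batch
    (flagged in the output).
    """
    missing = [c for c in model.schema if c not in new_fm.values.columns]
    if missing:
        raise SchemaError(f"missing {len(missing)} columns", missing=missing)
    X = new_fm.values[model.schema]
    meta = new_fm.row_meta
    out_rows = []
    for b, rows in X.groupby(meta["batch"]):
        members = rows.index
        is_control = meta.loc[members, "treatment"].isin(_CONTROL_TREATMENTS)
        ref = members[is_control] if is_control.sum() >= 2 else members
        flagged = is_control.sum() < 2
        mean, sd = X.loc[ref].mean(), X.loc[ref].std(ddof=1).replace(0.0, np.nan)
        Z = ((rows - mean) / sd).fillna(0.0)
        pred = model.model.predict(Z)
        proba = model.model.predict_proba(Z)
        for i, cid in enumerate(members):
            out_rows.append(
                {
                    "culture_id": cid,
                    "predicted": pred[i],
                    "batch": b,
                    "norm_on_all_rows": flagged,
                    **{
                        f"score_{c}": proba[i, j]
                        for j, c in enumerate(model.model.classes_)
                    },
                }
            )
    return pd.DataFrame(out_rows).set_index("culture_id")


def cluster_purity(cluster_labels: np.ndarray, class_labels: np.ndarray) -> float:
    """Purity = (1/N) * sum over clusters of the majority class count."""
    cluster_labels = np.asarray(cluster_labels)
    class_labels = np.asarray(class_labels)
    total = 0
    for c in np.unique(cluster_labels):
        members = class_labels[cluster_labels == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return float(total / class_labels.size)


def embed_and_purity(
    fm: FeatureMatrix,
    labels: Optional[pd.Series] = None,
    k: int = 2,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> EmbeddingResult:
    """2-D UMAP embedding, k-means on the embedding, and cluster purity."""
    import umap  # deferred: numba-compiled import is slow
    from sklearn.cluster import KMeans

    y = (labels if labels is not None else fm.row_meta["group"]).loc[
        fm.values.index
    ]
    n = fm.n_rows
    if k > n:
        raise InvalidParameter("k exceeds the number of rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xz, _ = batch_zscore(fm)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, n - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        coords = reducer.fit_transform(Xz.to_numpy())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
    purity = cluster_purity(km.labels_, y.to_numpy())
    return EmbeddingResult(coords=coords, kmeans_labels=km.labels_, purity=purity)
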