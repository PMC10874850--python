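import numpy as np
import pandas as pd
import pytest

from meaphen import (
    InvalidLabels,
    InvalidParameter,
    InvalidSelection,
    SchemaError,
    apply_pretrained,
    assemble_feature_matrix,
    batch_zscore,
    classify_loo,
    cluster_purity,
    embed_and_purity,
    permutation_importance,
    predict_age,
    tune_hyperparameters,
)


def synthetic_feature_table(
    n_per_group=6,
    weeks=(1, 2),
    features=("f1", "f2", "f3"),
    effect=0.0,
    informative=("f1",),
    seed=0,
    batches=("b1", "b2"),
    age_slope=None,
    noise_sd=1.0,
):
    """Designed tidy feature table: group effect on selected features only."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, sign in (("WT", 1.0), ("MUT", -1.0)):
        for i in range(n_per_group):
            cid = f"{g}{i}"
            batch = batches[i % len(batches)]
            b_off = 0.5 if batch == "b2" else 0.0
            for w in weeks:
                for f in features:
                    mu = b_off
                    if f in informative:
                        mu += sign * effect
                    if age_slope is not None:
                        mu += age_slope.get(f, 0.0) * w * 7
                    rows.append(
                        dict(
                            culture_id=cid, group=g, treatment="untreated",
                            batch=batch, age_days=w * 7, age_week=w,
                            feature=f, feature_class="spike-time",
                            value=mu + rng.normal(0, noise_sd), n_units=10,
                        )
                    )
    return pd.DataFrame(rows)


class TestAssemble:
    def test_shape_and_week_major_order(self):
        t = synthetic_feature_table(n_per_group=2, weeks=(1, 2))
        fm = assemble_feature_matrix(t)
        assert fm.values.shape == (4, 6)
        assert list(fm.values.columns[:3]) == ["w1:f1", "w1:f2", "w1:f3"]
        assert fm.col_info.loc["w2:f3", "age_week"] == 2

    def test_class_selection_restricts_columns(self):
        t = synthetic_feature_table(n_per_group=2)
        t.loc[t.feature == "f3", "feature_class"] = "burst"
        fm = assemble_feature_matrix(t, feature_classes=["burst"])
        assert set(fm.col_info["feature"]) == {"f3"}

    def test_empty_selection_raises(self):
        t = synthetic_feature_table(n_per_group=2)
        with pytest.raises(InvalidSelection):
            assemble_feature_matrix(t, feature_classes=[])
        with pytest.raises(InvalidSelection):
            assemble_feature_matrix(t, feature_classes=["no-such-class"])

    def test_missing_week_imputed_by_group_median_and_flagged(self):
        t = synthetic_feature_table(n_per_group=3, weeks=(1, 2))
        drop = (t.culture_id == "WT0") & (t.age_week == 2)
        t = t[~drop]
        fm = assemble_feature_matrix(t)
        assert fm.imputed.loc["WT0", "w2:f1"]
        same_group = t[(t.group == "WT") & (t.age_week == 2) & (t.feature == "f1")]
        assert fm.values.loc["WT0", "w2:f1"] == pytest.approx(
            same_group["value"].median()
        )


class TestBatchZscore:
    def test_train_column_standardized(self):
        t = synthetic_feature_table(n_per_group=3, weeks=(1,), batches=("b1",))
        fm = assemble_feature_matrix(t)
        fm.values.loc[:, "w1:f1"] = [1, 2, 3, 4, 5, 6]
        Xz, _ = batch_zscore(fm)
        col = Xz["w1:f1"]
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=1) == pytest.approx(1.0)

    def test_three_point_example(self):
        t = synthetic_feature_table(n_per_group=2, weeks=(1,), batches=("b1",))
        fm = assemble_feature_matrix(t)
        fm.values.loc[:, :] = 0.0
        fm.values.loc[["WT0", "WT1", "MUT0"], "w1:f1"] = [1.0, 2.0, 3.0]
        Xz, _ = batch_zscore(fm, train_rows=["WT0", "WT1", "MUT0"])
        np.testing.assert_allclose(
            Xz.loc[["WT0", "WT1", "MUT0"], "w1:f1"], [-1, 0, 1]
        )

    def test_constant_column_maps_to_zero(self):
        t = synthetic_feature_table(n_per_group=2, weeks=(1,), batches=("b1",))
        fm = assemble_feature_matrix(t)
        fm.values.loc[:, "w1:f2"] = 7.0
        Xz, _ = batch_zscore(fm)
        assert (Xz["w1:f2"] == 0.0).all()

    def test_test_rows_use_train_parameters(self):
        t = synthetic_feature_table(n_per_group=3, weeks=(1,), batches=("b1",))
        fm = assemble_feature_matrix(t)
        train = list(fm.values.index[:-1])
        held = fm.values.index[-1]
        Xz, norm = batch_zscore(fm, train_rows=train)
        mean, sd = norm.by_batch["b1"]
        expected = (fm.values.loc[held] - mean) / sd
        np.testing.assert_allclose(Xz.loc[held], expected.fillna(0.0))

    def test_small_batch_falls_back_to_global(self):
        t = synthetic_feature_table(n_per_group=3, weeks=(1,))
        fm = assemble_feature_matrix(t)
        # keep only one b2 culture in training
        train = [c for c in fm.values.index if fm.row_meta.loc[c, "batch"] == "b1"]
        train.append([c for c in fm.values.index if c not in train][0])
        with pytest.warns(UserWarning):
            _, norm = batch_zscore(fm, train_rows=train)
        assert "b2" in norm.fallback_batches

    def test_per_batch_train_mean_zero(self):
        t = synthetic_feature_table(n_per_group=6, seed=3)
        fm = assemble_feature_matrix(t)
        Xz, _ = batch_zscore(fm)
        for b, rows in Xz.groupby(fm.row_meta["batch"]):
            np.testing.assert_allclose(rows.mean().to_numpy(), 0.0, atol=1e-10)


class TestClassification:
    def test_separable_groups_high_accuracy(self):
        t = synthetic_feature_table(n_per_group=6, effect=3.0, seed=1)
        fm = assemble_feature_matrix(t)
        result, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        assert result.accuracy >= 0.9
        assert model.task == "classification"

    def test_single_class_raises(self):
        t = synthetic_feature_table(n_per_group=3)
        t["group"] = "WT"
        fm = assemble_feature_matrix(t)
        with pytest.raises(InvalidLabels):
            classify_loo(fm)

    def test_identical_cultures_opposite_labels_unlearnable(self):
        rows = []
        for cid, g in [("a", "WT"), ("b", "MUT"), ("c", "WT"), ("d", "MUT")]:
            for f in ("f1", "f2"):
                rows.append(
                    dict(culture_id=cid, group=g, treatment="u", batch="b1",
                         age_days=7, age_week=1, feature=f,
                         feature_class="spike-time", value=1.0, n_units=5)
                )
        fm = assemble_feature_matrix(pd.DataFrame(rows))
        result, _ = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        assert result.accuracy <= 0.5

    def test_loo_isolation(self):
        # removing a culture does not change other folds' predictions
        t = synthetic_feature_table(n_per_group=4, effect=2.0, seed=5)
        fm_full = assemble_feature_matrix(t)
        res_full, _ = classify_loo(fm_full, seed=0, rf_params={"n_estimators": 150})
        dropped = "WT3"
        fm_sub = assemble_feature_matrix(t[t.culture_id != dropped])
        res_sub, _ = classify_loo(fm_sub, seed=0, rf_params={"n_estimators": 150})
        # the shared folds see identical training data except for the one
        # dropped row; predictions for a clearly-separated design agree
        common = res_sub.predictions.index
        agree = (
            res_full.predictions.loc[common, "predicted"]
            == res_sub.predictions.loc[common, "predicted"]
        ).mean()
        assert agree >= 0.9


class TestImportance:
    def test_informative_feature_ranks_first(self):
        t = synthetic_feature_table(n_per_group=6, effect=2.5, seed=2)
        fm = assemble_feature_matrix(t)
        _, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        imp = permutation_importance(model, fm, seed=0)
        assert imp.iloc[0]["feature"] == "f1"

    def test_by_time_rows_cover_feature_week_grid(self):
        t = synthetic_feature_table(n_per_group=4, effect=1.0)
        fm = assemble_feature_matrix(t)
        _, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        imp = permutation_importance(model, fm, by_time=True, seed=0)
        assert len(imp) == 3 * 2
        assert set(imp["age_week"]) == {1, 2}

    def test_row_count_equals_feature_count(self):
        t = synthetic_feature_table(n_per_group=4)
        fm = assemble_feature_matrix(t)
        _, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        assert len(permutation_importance(model, fm, seed=0)) == 3


class TestTuning:
    def test_budget_one_returns_single_setting(self):
        t = synthetic_feature_table(n_per_group=4, effect=2.0)
        fm = assemble_feature_matrix(t)
        params, score = tune_hyperparameters(fm, budget=1, seed=0)
        assert set(params) == {
            "n_estimators", "max_depth", "min_samples_leaf", "max_features"
        }
        assert 0.0 <= score <= 1.0

    def test_deterministic_given_seed(self):
        t = synthetic_feature_table(n_per_group=4, effect=2.0)
        fm = assemble_feature_matrix(t)
        p1, s1 = tune_hyperparameters(fm, budget=5, seed=7)
        p2, s2 = tune_hyperparameters(fm, budget=5, seed=7)
        assert p1 == p2 and s1 == s2

    def test_invalid_budget(self):
        t = synthetic_feature_table(n_per_group=4)
        fm = assemble_feature_matrix(t)
        with pytest.raises(InvalidParameter):
            tune_hyperparameters(fm, budget=0)


class TestAgeRegression:
    def test_linear_maturation_recovered(self):
        t = synthetic_feature_table(
            n_per_group=5, weeks=(1, 2, 3, 4, 5),
            age_slope={"f1": 0.05, "f2": -0.03, "f3": 0.02}, seed=4,
            noise_sd=0.1,
        )
        res = predict_age(t, seed=0, rf_params={"n_estimators": 200})
        assert res.mae_days < 3.5
        assert res.mae_days < 0.5 * res.baseline_mae_days
        assert set(res.mae_by_week.index) == {1, 2, 3, 4, 5}

    def test_uninformative_features_near_baseline(self):
        t = synthetic_feature_table(n_per_group=5, weeks=(1, 2, 3, 4, 5), seed=6)
        res = predict_age(t, seed=0, rf_params={"n_estimators": 200})
        assert res.mae_days > 0.6 * res.baseline_mae_days

    def test_single_age_raises(self):
        t = synthetic_feature_table(n_per_group=4, weeks=(2,))
        with pytest.raises(InvalidLabels):
            predict_age(t)


class TestTransfer:
    def test_training_rows_score_at_least_loo(self):
        t = synthetic_feature_table(n_per_group=6, effect=1.5, seed=8)
        fm = assemble_feature_matrix(t)
        res, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        preds = apply_pretrained(model, fm)
        train_acc = (
            preds["predicted"] == fm.row_meta["group"].loc[preds.index]
        ).mean()
        assert train_acc >= res.accuracy

    def test_opposite_group_parameters_predicted_as_opposite(self):
        t = synthetic_feature_table(n_per_group=6, effect=3.0, seed=10)
        fm = assemble_feature_matrix(t)
        _, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        # "treated" WT cultures generated with the mutant group's
        # parameters, alongside untreated controls in the same new batch so
        # transfer normalization can anchor on them
        t2 = synthetic_feature_table(n_per_group=6, effect=3.0, seed=11)
        flipped = t2[t2.group == "MUT"].copy()
        flipped["group"] = "WT"
        flipped["treatment"] = "LNA"
        controls = t2[t2.group == "WT"].copy()
        controls["treatment"] = "ntLNA"
        new = pd.concat([flipped, controls], ignore_index=True)
        new["batch"] = "b9"
        fm2 = assemble_feature_matrix(new)
        preds = apply_pretrained(model, fm2)
        treated = preds.loc[fm2.row_meta["treatment"] == "LNA"]
        assert (treated["predicted"] == "MUT").mean() >= 0.8
        assert not preds["norm_on_all_rows"].any()

    def test_missing_columns_raise_schema_error(self):
        t = synthetic_feature_table(n_per_group=4)
        fm = assemble_feature_matrix(t)
        _, model = classify_loo(fm, seed=0, rf_params={"n_estimators": 150})
        t_sub = t[t.feature != "f3"]
        fm_sub = assemble_feature_matrix(t_sub)
        with pytest.raises(SchemaError) as exc:
            apply_pretrained(model, fm_sub)
        assert all("f3" in c for c in exc.value.missing)


class TestEmbedding:
    def test_separated_groups_high_purity(self):
        t = synthetic_feature_table(
            n_per_group=8, effect=4.0, informative=("f1", "f2", "f3"), seed=12
        )
        fm = assemble_feature_matrix(t)
        res = embed_and_purity(fm, k=2, seed=0)
        assert res.purity >= 0.95
        assert res.coords.shape == (16, 2)

    def test_purity_definition_and_bounds(self):
        labels = np.array(["a", "a", "b", "b", "b"])
        clusters = np.array([0, 0, 0, 1, 1])
        # cluster 0 majority a (2), cluster 1 majority b (2) -> 4/5
        assert cluster_purity(clusters, labels) == pytest.approx(0.8)
        # purity >= max class frequency
        assert cluster_purity(np.zeros(5), labels) == pytest.approx(3 / 5)

    def test_k_exceeding_rows_raises(self):
        t = synthetic_feature_table(n_per_group=2)
        fm = assemble_feature_matrix(t)
        with pytest.raises(InvalidParameter):
            embed_and_purity(fm, k=10)
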