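import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from meaphen import (
    EmptyInput,
    InvalidParameter,
    SchemaError,
    SimulationConfig,
    build_unit_feature_table,
    cluster_units,
    map_perturbation_response,
    predict_composition,
    simulate_culture_series,
    simulate_perturbation,
    train_cluster_classifier,
)
from meaphen.simulate import WaveformArchetype

from conftest import make_recording, make_unit

SEPARATED = (
    WaveformArchetype("broad", trough_uv=-90.0, trough_uv_sd=4.0,
                      trough_to_peak_ms=1.0, responder_prob=0.3),
    WaveformArchetype("narrow", trough_uv=-40.0, trough_uv_sd=4.0,
                      trough_to_peak_ms=0.3, responder_prob=0.7),
)


@pytest.fixture(scope="module")
def archetype_study():
    cfg = SimulationConfig(
        seed=23, groups=("WT",), n_cultures_per_group=3, weeks=(3,),
        n_units=12, duration_s=120.0, archetypes=SEPARATED,
        archetype_probs=(0.5, 0.5), group_effects={"WT": {}},
    )
    return simulate_culture_series(cfg)


class TestClustering:
    def test_two_archetypes_recovered_exactly(self, archetype_study):
        recs, truth = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        assign = cluster_units(table, seed=0, compute_embedding=False)
        true_labels = [
            truth.unit_archetype[cid][uid]
            for cid, uid in zip(assign.table.culture_id, assign.table.unit_id)
        ]
        assert adjusted_rand_score(true_labels, assign.labels) == 1.0

    def test_same_seed_identical_partition(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        a1 = cluster_units(table, seed=5, compute_embedding=False)
        a2 = cluster_units(table, seed=5, compute_embedding=False)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_labels_stable_under_row_permutation(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        a1 = cluster_units(table, seed=0, compute_embedding=False)
        perm = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a2 = cluster_units(perm, seed=0, compute_embedding=False)
        merged = a1.table.merge(
            a2.table, on=["culture_id", "unit_id"], suffixes=("_a", "_b")
        )
        assert adjusted_rand_score(merged.cluster_a, merged.cluster_b) == 1.0

    def test_too_few_units_rejected(self):
        t = pd.DataFrame(
            {"culture_id": ["c"] * 5, "unit_id": range(5), "f": range(5)}
        )
        with pytest.raises(InvalidParameter):
            cluster_units(t)


class TestClusterClassifier:
    def test_separated_clusters_diagonal_confusion(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        assign = cluster_units(table, seed=0, compute_embedding=False)
        clf = train_cluster_classifier(table, assign.labels, seed=0)
        conf = clf.confusion.to_numpy()
        assert np.all(conf == np.diag(np.diag(conf)))

    def test_importance_covers_every_feature(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        assign = cluster_units(table, seed=0, compute_embedding=False)
        clf = train_cluster_classifier(table, assign.labels, seed=0)
        feat_cols = [c for c in table.columns if c not in ("culture_id", "unit_id")]
        assert set(clf.importance["feature"]) == set(feat_cols)

    def test_small_cluster_merged_with_warning(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        labels = np.zeros(len(table), dtype=int)
        labels[:30] = 1
        labels[:3] = 2  # undersized cluster
        with pytest.warns(UserWarning):
            clf = train_cluster_classifier(table, labels, seed=0)
        assert 2 in clf.merged_clusters


class TestComposition:
    def test_fractions_sum_to_one(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        assign = cluster_units(table, seed=0, compute_embedding=False)
        clf = train_cluster_classifier(table, assign.labels, seed=0)
        comp = predict_composition(clf, table)
        sums = comp.groupby("culture_id")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_single_archetype_culture_dominated(self):
        cfg = SimulationConfig(
            seed=31, groups=("WT",), n_cultures_per_group=4, weeks=(3,),
            n_units=12, duration_s=120.0, archetypes=SEPARATED,
            archetype_probs=(0.5, 0.5), group_effects={"WT": {}},
        )
        recs, truth = simulate_culture_series(cfg)
        table = build_unit_feature_table(recs, mode="waveform")
        assign = cluster_units(table, seed=0, compute_embedding=False)
        clf = train_cluster_classifier(table, assign.labels, seed=0)
        # homogeneous culture drawn from the broad archetype only
        cfg2 = SimulationConfig(
            seed=32, groups=("WT",), n_cultures_per_group=1, weeks=(3,),
            n_units=15, duration_s=120.0, archetypes=SEPARATED,
            archetype_probs=(1.0, 0.0), group_effects={"WT": {}},
        )
        recs2, _ = simulate_culture_series(cfg2)
        t2 = build_unit_feature_table(recs2, mode="waveform")
        comp = predict_composition(clf, t2)
        assert comp["fraction"].max() >= 0.9

    def test_schema_mismatch_and_empty(self, archetype_study):
        recs, _ = archetype_study
        table = build_unit_feature_table(recs, mode="waveform")
        assign = cluster_units(table, seed=0, compute_embedding=False)
        clf = train_cluster_classifier(table, assign.labels, seed=0)
        with pytest.raises(SchemaError):
            predict_composition(clf, table.drop(columns=["half_width_ms"]))
        with pytest.raises(EmptyInput):
            predict_composition(clf, table.iloc[:0])


class TestPerturbationResponse:
    def test_ratio_and_responder_arithmetic(self):
        base = make_recording(
            [make_unit(0, np.arange(0, 10, 0.1)), make_unit(1, np.arange(0, 10, 0.5))],
            duration_s=10.0,
        )
        post = make_recording(
            [make_unit(0, np.arange(0, 10, 0.2)), make_unit(1, np.arange(0, 10, 0.5))],
            duration_s=10.0,
        )
        resp = map_perturbation_response(base, post)
        row0 = resp.table.set_index("unit_id").loc[0]
        assert row0.fr_ratio == pytest.approx(0.5)
        assert bool(row0.responder)
        assert not bool(resp.table.set_index("unit_id").loc[1].responder)

    def test_cluster_fraction_counting(self):
        base = make_recording(
            [make_unit(i, np.arange(0, 10, 0.1)) for i in range(5)], duration_s=10.0
        )
        post_units = [
            make_unit(i, np.arange(0, 10, 0.4 if i < 3 else 0.1)) for i in range(5)
        ]
        post = make_recording(post_units, duration_s=10.0)
        clusters = pd.DataFrame(
            {"culture_id": ["c0"] * 5, "unit_id": range(5), "cluster": [0] * 5}
        )
        resp = map_perturbation_response(base, post, clusters)
        assert resp.cluster_fractions.loc[0] == pytest.approx(3 / 5)

    def test_unmatched_units_dropped_and_counted(self):
        base = make_recording([make_unit(0, np.arange(0, 10, 0.1))], duration_s=10.0)
        post = make_recording([make_unit(7, np.arange(0, 10, 0.1))], duration_s=10.0)
        resp = map_perturbation_response(base, post)
        assert len(resp.table) == 0 and resp.n_unmatched == 2

    def test_responder_calling_monotone_in_threshold(self):
        base = make_recording(
            [make_unit(i, np.arange(0, 20, 0.1)) for i in range(6)], duration_s=20.0
        )
        rng = np.random.default_rng(0)
        post = make_recording(
            [
                make_unit(i, np.sort(rng.choice(
                    np.arange(0, 20, 0.1), size=int(200 * r), replace=False)))
                for i, r in enumerate([1.0, 0.95, 0.8, 0.6, 0.4, 0.2])
            ],
            duration_s=20.0,
        )
        n_resp = [
            map_perturbation_response(base, post, decrease_threshold=th)
            .table["responder"].sum()
            for th in (0.05, 0.1, 0.3, 0.5)
        ]
        assert all(a >= b for a, b in zip(n_resp, n_resp[1:]))

    def test_designed_responder_fraction_recovered(self):
        cfg = SimulationConfig(
            seed=41, groups=("WT",), n_cultures_per_group=1, weeks=(3,),
            n_units=40, duration_s=300.0,
            archetypes=(
                WaveformArchetype("a", responder_prob=0.5),
                WaveformArchetype("b", responder_prob=0.5),
            ),
            archetype_probs=(0.5, 0.5), group_effects={"WT": {}},
        )
        recs, truth = simulate_culture_series(cfg)
        rec = recs[0]
        post = simulate_perturbation(rec, truth, responder_fr_ratio=0.5, seed=2)
        resp = map_perturbation_response(rec, post)
        true_frac = np.mean(list(truth.responders[rec.culture_id].values()))
        got_frac = resp.table["responder"].mean()
        assert abs(got_frac - true_frac) <= 0.1
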