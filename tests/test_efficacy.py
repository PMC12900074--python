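import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dynaglep import efficacy, synthdata
from dynaglep.efficacy import (ConfusionCounts, DockingScoreTable, TLConfig,
                               auc_score, compute_metrics, concat_features,
                               confusion_counts, crossval_scores,
                               label_from_emax, make_split, mcc_from_counts,
                               predict_tl, rf_ensemble_classifier,
                               static_classifier, tanimoto_matrix,
                               train_tl_head, two_states_classifier, welch_test)


class TestLabeling:
    @pytest.mark.parametrize("emax,expected", [
        (100.0, "agonist"),       # full agonist (e.g. serotonin)
        (10.0, "nonagonist"),     # weak partial response (e.g. methiothepin)
        (50.0, "nonagonist"),     # boundary: strictly greater than 50 required
        (50.0001, "agonist"),
        (120.0, "agonist"),       # superagonist
    ])
    def test_threshold(self, emax, expected):
        assert label_from_emax(emax) == expected

    def test_missing_emax_rejected(self):
        with pytest.raises(ValueError):
            label_from_emax(float("nan"))


class TestConcatFeatures:
    def test_order_preserving_flatten(self):
        feats = np.arange(6).reshape(1, 2, 3).astype(float)
        fe = efficacy.FeatureEnsemble(["a"], feats, np.array(["active", "inactive"]),
                                      np.array([1]))
        out = concat_features(fe)
        np.testing.assert_array_equal(out, [[0, 1, 2, 3, 4, 5]])

    def test_single_conformation_is_identity(self):
        feats = np.arange(3).reshape(1, 1, 3).astype(float)
        fe = efficacy.FeatureEnsemble(["a"], feats, np.array(["active"]), np.array([0]))
        np.testing.assert_array_equal(concat_features(fe), feats[:, 0, :])

    def test_block_permutation_permutes_output(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(2, 3, 4))
        fe = efficacy.FeatureEnsemble(["a", "b"], feats,
                                      np.array(["active"] * 3), np.array([0, 1]))
        fe_perm = efficacy.FeatureEnsemble(["a", "b"], feats[:, [2, 0, 1], :],
                                           np.array(["active"] * 3), np.array([0, 1]))
        out, out_p = concat_features(fe), concat_features(fe_perm)
        np.testing.assert_array_equal(out_p[:, :4], out[:, 8:12])


class TestMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        rep = compute_metrics(scores, labels)
        assert rep.auc == rep.acc == rep.mcc == 1.0

    def test_hand_evaluated_confusion_counts(self):
        # TP=3, TN=3, FP=1, FN=1
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.2, 0.3, 0.9])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rep = compute_metrics(scores, labels)
        assert rep.confusion == ConfusionCounts(tp=3, tn=3, fp=1, fn=1)
        assert rep.mcc == pytest.approx(0.5)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)
        assert rep.acc == pytest.approx(0.75)

    def test_auc_matches_pair_count_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 40
            scores = np.round(rng.normal(size=n), 1)  # ties on purpose
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc_score(scores, labels) == pytest.approx(oracle, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(15, dtype=int), np.zeros(15, dtype=int)]
        a1 = auc_score(scores, labels)
        a2 = auc_score(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_mcc_class_swap_symmetry(self, tp, tn, fp, fn):
        a = mcc_from_counts(ConfusionCounts(tp, tn, fp, fn))
        b = mcc_from_counts(ConfusionCounts(tn, tp, fn, fp))
        assert a == pytest.approx(b, abs=1e-12)

    def test_mcc_zero_denominator_defined_as_zero(self):
        assert mcc_from_counts(ConfusionCounts(0, 0, 0, 5)) == 0.0

    def test_single_class_auc_flagged(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.9], [1, 1])


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        assert welch_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(5, 30))
            b = rng.normal(0.3, 2, rng.integers(5, 30))
            t, p = welch_test(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestBaselines:
    def test_static_perfect_separation_auc_one(self):
        # agonists dock better (more negative) against the active state
        scores = np.array([-8.0, -7.5, -5.0, -4.5])
        labels = np.array([1, 1, 0, 0])
        assert auc_score(static_classifier(scores), labels) == 1.0

    def test_orientation_flip_reverses_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        a = auc_score(static_classifier(scores, "active"), labels)
        b = auc_score(static_classifier(scores, "inactive"), labels)
        assert a + b == pytest.approx(1.0)

    def test_two_states_sign_convention_printed_means(self):
        # serotonin (agonist): active −6.53 vs inactive −6.02 → Δ < 0
        # methiothepin (nonagonist): active −4.95 vs inactive −5.36 → Δ > 0
        ranking = two_states_classifier([-6.53, -4.95], [-6.02, -5.36])
        assert ranking[0] > ranking[1]

    def test_two_states_equal_scores_zero(self):
        assert two_states_classifier([-5.0], [-5.0])[0] == 0.0

    def test_rf_on_state_signal_table(self):
        table, labels = synthdata.gen_score_table(synthdata.ScoreTableSpec(
            n_ligands_per_class=30, n_conformations_per_state=20, seed=4))
        plan = make_split(len(labels), "random", k=3, seed=4)
        prob = rf_ensemble_classifier(table, labels, plan, seed=4)
        assert auc_score(prob, labels) >= 0.8

    def test_rf_label_permutation_near_chance(self):
        table, labels = synthdata.gen_score_table(synthdata.ScoreTableSpec(
            n_ligands_per_class=30, n_conformations_per_state=20, seed=5))
        rng = np.random.default_rng(5)
        aucs = []
        for rep in range(5):
            perm = rng.permutation(labels)
            if perm.sum() in (0, len(perm)):
                continue
            plan = make_split(len(perm), "random", k=3, seed=rep)
            prob = rf_ensemble_classifier(table, perm, plan, seed=rep)
            aucs.append(auc_score(prob, perm))
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_rf_seeded_reproducibility(self):
        table, labels = synthdata.gen_score_table(synthdata.ScoreTableSpec(
            n_ligands_per_class=10, n_conformations_per_state=10, seed=6))
        plan = make_split(len(labels), "random", k=3, seed=6)
        p1 = rf_ensemble_classifier(table, labels, plan, seed=6)
        p2 = rf_ensemble_classifier(table, labels, plan, seed=6)
        np.testing.assert_array_equal(p1, p2)

    def test_rf_all_missing_column_dropped_with_warning(self):
        table, labels = synthdata.gen_score_table(synthdata.ScoreTableSpec(
            n_ligands_per_class=10, n_conformations_per_state=5, seed=7))
        table.scores[:, 3] = np.nan
        plan = make_split(len(labels), "random", k=3, seed=7)
        with pytest.warns(UserWarning, match="all-missing"):
            rf_ensemble_classifier(table, labels, plan, seed=7)


class TestTransferHead:
    def test_strong_signal_high_heldout_auc(self):
        fe = synthdata.gen_feature_ensemble(synthdata.FeatureEnsembleSpec(
            delta=2.0, seed=8))
        X = concat_features(fe)
        plan = make_split(len(fe.labels), "random", k=3, seed=8)
        prob = crossval_scores(X, fe.labels, plan, seed=8)
        assert auc_score(prob, fe.labels) >= 0.9

    def test_label_permutation_near_chance(self):
        fe = synthdata.gen_feature_ensemble(synthdata.FeatureEnsembleSpec(
            delta=2.0, seed=9))
        X = concat_features(fe)
        rng = np.random.default_rng(9)
        aucs = []
        for rep in range(5):
            perm = rng.permutation(fe.labels)
            plan = make_split(len(perm), "random", k=3, seed=rep)
            aucs.append(auc_score(crossval_scores(X, perm, plan, seed=rep), perm))
        assert abs(np.mean(aucs) - 0.5) <= 0.07

    def test_fixed_seed_reproducible_predictions(self):
        fe = synthdata.gen_feature_ensemble(synthdata.FeatureEnsembleSpec(
            n_ligands=40, delta=1.0, seed=10))
        X = concat_features(fe)
        c1 = train_tl_head(X, fe.labels, seed=10)
        c2 = train_tl_head(X, fe.labels, seed=10)
        np.testing.assert_array_equal(predict_tl(c1, X), predict_tl(c2, X))

    def test_probabilities_bounded(self):
        fe = synthdata.gen_feature_ensemble(synthdata.FeatureEnsembleSpec(
            n_ligands=40, delta=1.0, seed=11))
        X = concat_features(fe)
        clf = train_tl_head(X, fe.labels, seed=11)
        p = predict_tl(clf, X)
        assert np.all((p >= 0) & (p <= 1))

    def test_dim_mismatch_rejected(self):
        fe = synthdata.gen_feature_ensemble(synthdata.FeatureEnsembleSpec(
            n_ligands=40, delta=1.0, seed=12))
        X = concat_features(fe)
        clf = train_tl_head(X, fe.labels, seed=12)
        with pytest.raises(ValueError, match="dim"):
            predict_tl(clf, X[:, :-3])

    def test_single_class_rejected(self):
        X = np.random.default_rng(13).normal(size=(10, 4))
        with pytest.raises(ValueError):
            train_tl_head(X, np.ones(10), seed=13)


class TestSplits:
    def test_random_split_near_equal_folds(self):
        plan = make_split(9, "random", k=3, seed=14)
        counts = np.bincount(plan.folds, minlength=3)
        assert list(counts) == [3, 3, 3]

    def test_identical_fingerprints_share_fold(self):
        fps = np.zeros((4, 64), dtype=np.uint8)
        fps[:2, :10] = 1          # identical pair
        fps[2, 30:40] = 1
        fps[3, 50:60] = 1
        with pytest.warns(UserWarning):  # 2-member cluster > 4/3 fold share
            plan = make_split(4, "tanimoto", k=3, seed=15, fingerprints=fps)
        assert plan.folds[0] == plan.folds[1]

    def test_planted_clusters_one_per_fold(self):
        fps, clusters = synthdata.gen_fingerprints(30, n_clusters=3, seed=16)
        plan = make_split(30, "tanimoto", k=3, seed=16, fingerprints=fps)
        for c in range(3):
            assert len(set(plan.folds[clusters == c])) == 1
        assert len(set(plan.folds)) == 3

    def test_folds_partition_exactly(self):
        plan = make_split(20, "random", k=3, seed=17)
        assert len(plan.folds) == 20
        assert set(plan.folds) <= {0, 1, 2}

    def test_oversized_cluster_warns(self):
        fps = np.zeros((6, 64), dtype=np.uint8)
        fps[:, :10] = 1  # one giant cluster
        with pytest.warns(UserWarning, match="cluster"):
            make_split(6, "tanimoto", k=3, seed=18, fingerprints=fps)

    def test_tanimoto_matrix_known_values(self):
        a = np.array([[1, 1, 0, 0], [1, 0, 1, 0]], dtype=float)
        sim = tanimoto_matrix(a)
        assert sim[0, 1] == pytest.approx(1 / 3)
        assert sim[0, 0] == 1.0


class TestEvaluateTL:
    def test_report_schema_and_repetitions(self):
        fe = synthdata.gen_feature_ensemble(synthdata.FeatureEnsembleSpec(
            n_ligands=60, delta=2.0, seed=19))
        X = concat_features(fe)
        out = efficacy.evaluate_tl(X, fe.labels, strategy="random", k=3,
                                   base_seed=19,
                                   config=TLConfig(n_repetitions=3))
        assert set(out["pooled"]) == {"auc", "acc", "mcc", "precision", "recall"}
        assert len(out["pooled"]["auc"]["values"]) == 3
        assert "per_fold_auc" in out
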