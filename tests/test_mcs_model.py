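import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcscreen import (
    ACTIVE,
    INACTIVE,
    ClassifierSpec,
    MCSModel,
    MetaModel,
    PredictionResult,
    build_mcs,
    cluster_features,
    combine_meta,
    compact_roster,
    confusion_matrix,
    generate_dataset,
    majority_vote,
    mcc,
    optimize_cluster_classifier,
    predict,
    weighted_vote,
)
from mcscreen.mcs_model import MINIMIZE_FP, MINIMIZE_FN
from mcscreen.synthetic_data import SyntheticSpec

A, I = ACTIVE, INACTIVE


class TestMajorityVote:
    def test_basic(self):
        assert majority_vote([A, A, I]) == A
        assert majority_vote([I, I, I]) == I

    def test_tie_goes_to_active(self):
        assert majority_vote([A, I]) == A

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    @pytest.mark.parametrize("n", [3, 5])
    def test_exhaustive_oracle(self, n):
        for pattern in itertools.product([A, I], repeat=n):
            expected = A if pattern.count(A) >= pattern.count(I) else I
            assert majority_vote(list(pattern)) == expected


class TestWeightedVote:
    def test_equal_weights(self):
        assert weighted_vote([0.9, 0.9, 0.1], [1, 1, 1]) == A

    def test_zero_weight_silences(self):
        assert weighted_vote([0.2, 0.99], [1, 0]) == I

    def test_tie_goes_to_active(self):
        assert weighted_vote([0.5, 0.5, 0.5], [1, 1, 1]) == A

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_vote([0.5, 0.5], [0, 0])


class TestPredict:
    def test_all_confident_actives(self, tiny_table, stub_model_factory):
        model = stub_model_factory(tiny_table, [1.0, 1.0, 1.0])
        result = predict(model, tiny_table)
        assert set(result.labels) == {A}
        assert result.probabilities.shape == (6, 3)

    def test_majority_one_vs_two(self, tiny_table, stub_model_factory):
        model = stub_model_factory(tiny_table, [0.6, 0.4, 0.4])
        assert set(predict(model, tiny_table).labels) == {I}

    def test_half_probability_votes_inactive(self, tiny_table, stub_model_factory):
        # inner threshold: Active > 0.5, Inactive <= 0.5
        model = stub_model_factory(tiny_table, [0.6, 0.5, 0.4])
        assert set(predict(model, tiny_table).labels) == {I}

    def test_schema_mismatch_rejected(self, tiny_table, stub_model_factory):
        model = stub_model_factory(tiny_table, [1.0, 1.0])
        stripped = tiny_table.subset(range(6))
        stripped.bit_names = ["zz" + n for n in stripped.bit_names]
        with pytest.raises(ValueError, match="missing"):
            predict(model, stripped)


class TestCombineMeta:
    def test_disagreement(self, tiny_table, stub_model_factory):
        pred_a = predict(stub_model_factory(tiny_table, [0.9]), tiny_table)
        pred_b = predict(stub_model_factory(tiny_table, [0.1]), tiny_table)
        assert set(combine_meta(pred_a, pred_b, MINIMIZE_FP).labels) == {I}
        assert set(combine_meta(pred_a, pred_b, MINIMIZE_FN).labels) == {A}

    def test_agreement(self, tiny_table, stub_model_factory):
        hi = predict(stub_model_factory(tiny_table, [0.9]), tiny_table)
        lo = predict(stub_model_factory(tiny_table, [0.1]), tiny_table)
        for rule in (MINIMIZE_FP, MINIMIZE_FN):
            assert set(combine_meta(hi, hi, rule).labels) == {A}
            assert set(combine_meta(lo, lo, rule).labels) == {I}

    def test_probability_vectors_concatenate(self, tiny_table, stub_model_factory):
        pred_a = predict(stub_model_factory(tiny_table, [0.9, 0.8, 0.7]), tiny_table)
        pred_b = predict(
            stub_model_factory(tiny_table, [0.6, 0.9, 0.6], objective="PPV"), tiny_table
        )
        meta = combine_meta(pred_a, pred_b, MINIMIZE_FP)
        assert meta.probabilities.shape == (6, 6)
        assert meta.prob_columns == [
            "mcc_c1", "mcc_c2", "mcc_c3", "ppv_c1", "ppv_c2", "ppv_c3",
        ]

    def test_id_mismatch_rejected(self, tiny_table, stub_model_factory):
        pred_a = predict(stub_model_factory(tiny_table, [0.9]), tiny_table)
        other = tiny_table.subset([0, 1, 2])
        pred_b = predict(stub_model_factory(other, [0.9]), other)
        with pytest.raises(ValueError):
            combine_meta(pred_a, pred_b, MINIMIZE_FP)


@settings(max_examples=100, deadline=None)
@given(data=st.data(), n=st.integers(1, 40))
def test_meta_set_algebra_theorems(data, n):
    """AND can only remove predicted actives; OR can only add them."""
    labels = st.sampled_from([A, I])
    truth = data.draw(st.lists(labels, min_size=n, max_size=n))
    la = data.draw(st.lists(labels, min_size=n, max_size=n))
    lb = data.draw(st.lists(labels, min_size=n, max_size=n))
    ids = [f"C{i}" for i in range(n)]
    probs = np.zeros((n, 1))
    pa = PredictionResult(ids=ids, probabilities=probs, labels=np.array(la, dtype=object))
    pb = PredictionResult(ids=ids, probabilities=probs, labels=np.array(lb, dtype=object))
    cm_a = confusion_matrix(truth, la)
    cm_b = confusion_matrix(truth, lb)
    cm_and = confusion_matrix(truth, list(combine_meta(pa, pb, MINIMIZE_FP).labels))
    cm_or = confusion_matrix(truth, list(combine_meta(pa, pb, MINIMIZE_FN).labels))
    assert cm_and.fp <= min(cm_a.fp, cm_b.fp)
    assert cm_and.tn >= max(cm_a.tn, cm_b.tn)
    assert cm_or.fn <= min(cm_a.fn, cm_b.fn)
    assert cm_or.tp >= max(cm_a.tp, cm_b.tp)


class TestOptimizeClusterClassifier:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([A] * (n // 2) + [I] * (n // 2), dtype=object)
        X = rng.normal(0, 1, size=(n, 5))
        X[: n // 2, 0] += 6.0  # wide margin on one feature
        return X, y

    def test_separable_cluster_reaches_high_mcc(self):
        X, y = self._separable()
        clf = optimize_cluster_classifier(
            X, y, "MCC", roster=compact_roster(), cv_folds=5, seed=0
        )
        assert clf.cv_score >= 0.95

    def test_permuted_labels_give_null_mcc(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, size=(400, 5))
        y = np.array([A, I] * 200, dtype=object)
        rng.shuffle(y)
        roster = [compact_roster()[0]]  # logistic only
        clf = optimize_cluster_classifier(X, y, "MCC", roster=roster, cv_folds=5, seed=11)
        assert abs(clf.cv_score) <= 0.2

    def test_default_roster_families_all_fit(self):
        from mcscreen import default_roster

        X, y = self._separable(n=80)
        clf = optimize_cluster_classifier(
            X, y, "MCC", roster=default_roster(), cv_folds=3, seed=0
        )
        assert clf.cv_score >= 0.9
        # the winner exposes an Active probability
        proba = clf.active_probability(X)
        assert proba.shape == (80,)
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_single_spec_roster_is_returned(self):
        X, y = self._separable(n=60)
        only = [compact_roster()[0]]
        clf = optimize_cluster_classifier(X, y, "MCC", roster=only, cv_folds=3, seed=0)
        assert clf.spec_name == only[0].name

    def test_empty_roster_rejected(self):
        X, y = self._separable(n=40)
        with pytest.raises(ValueError):
            optimize_cluster_classifier(X, y, "MCC", roster=[], cv_folds=3, seed=0)

    def test_failing_family_is_skipped(self):
        X, y = self._separable(n=60)

        def broken_factory(seed):
            raise RuntimeError("cannot build")

        roster = [
            ClassifierSpec("broken", broken_factory, {"x": [1]}),
            compact_roster()[0],
        ]
        clf = optimize_cluster_classifier(X, y, "MCC", roster=roster, cv_folds=3, seed=0)
        assert clf.spec_name == "logistic"


class TestBuildMCS:
    def test_k3_gives_three_inner_classifiers(self, strong_models):
        assert len(strong_models["mcc"].classifiers) == 3
        assert len(strong_models["ppv"].classifiers) == 3

    def test_holdout_mcc_recovery(self, strong_models):
        test = strong_models["test"]
        pred = predict(strong_models["mcc"], test)
        cm = confusion_matrix(list(test.labels), list(pred.labels))
        assert mcc(cm) >= 0.8

    def test_minimize_fp_never_exceeds_constituent_fp(self, strong_models):
        test = strong_models["test"]
        truth = list(test.labels)
        pred_mcc = predict(strong_models["mcc"], test)
        pred_ppv = predict(strong_models["ppv"], test)
        cm_mcc = confusion_matrix(truth, list(pred_mcc.labels))
        cm_ppv = confusion_matrix(truth, list(pred_ppv.labels))
        cm_and = confusion_matrix(
            truth, list(combine_meta(pred_mcc, pred_ppv, MINIMIZE_FP).labels)
        )
        assert cm_and.fp <= min(cm_mcc.fp, cm_ppv.fp)

    def test_save_load_round_trip(self, strong_models, tmp_path):
        model = strong_models["mcc"]
        test = strong_models["test"]
        before = predict(model, test)
        p = model.save(tmp_path / "model.joblib")
        again = predict(MCSModel.load(p), test)
        assert list(before.labels) == list(again.labels)
        assert np.allclose(before.probabilities, again.probabilities)
        assert (tmp_path / "model.joblib.json").exists()

    def test_determinism_same_seed_same_specs(self):
        spec = SyntheticSpec(n_active=80, n_inactive=80, n_bits=24,
                             n_informative_bits=8, seed=5)
        table, _ = generate_dataset(spec)
        clustering = cluster_features(table, k=2)
        kwargs = dict(roster=compact_roster(), cv_folds=3, seed=5)
        m1 = build_mcs(table, clustering, "MCC", **kwargs)
        m2 = build_mcs(table, clustering, "MCC", **kwargs)
        assert [c.spec_name for c in m1.classifiers] == [c.spec_name for c in m2.classifiers]
        assert [c.params for c in m1.classifiers] == [c.params for c in m2.classifiers]
        assert [c.cv_score for c in m1.classifiers] == [c.cv_score for c in m2.classifiers]


class TestMetaModel:
    def test_meta_predict_equals_manual_combination(self, strong_models):
        test = strong_models["test"]
        meta = MetaModel(
            model_mcc=strong_models["mcc"], model_ppv=strong_models["ppv"],
            rule=MINIMIZE_FP,
        )
        manual = combine_meta(
            predict(strong_models["mcc"], test),
            predict(strong_models["ppv"], test),
            MINIMIZE_FP,
        )
        auto = meta.predict(test)
        assert list(auto.labels) == list(manual.labels)

    def test_bad_rule_rejected(self, strong_models):
        with pytest.raises(ValueError):
            MetaModel(strong_models["mcc"], strong_models["ppv"], rule="bogus")
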