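"""Probbase estimation and the reference Bayes / random classifiers."""

import numpy as np
import pytest

from va_validate import (
    BayesClassifier,
    CauseList,
    ClassifierConfig,
    GeneratorConfig,
    Probbase,
    RandomClassifier,
    SymptomDictionary,
    VADataset,
    ccc_per_cause,
    classify,
    confusion_counts,
    estimate_probbase,
    generate_dataset,
    generate_probbase,
    overall_ccc,
    predict_all,
)


def make_dataset(causes, symptoms, gold, X, module="adult"):
    n = len(gold)
    return VADataset(
        record_ids=np.array([f"r{i}" for i in range(n)], dtype=object),
        module=module,
        sites=np.array(["s"] * n, dtype=object),
        gold_causes=np.array(gold, dtype=object),
        symptoms=np.asarray(X, dtype=np.int8),
        cause_list=causes,
        symptom_dict=symptoms,
    )


class TestEstimateProbbase:
    causes = CauseList("adult", ("A", "B"))
    sdict = SymptomDictionary(("s1",), (False,))

    def _train(self):
        # cause A: s1 endorsed 3 of 4 observed (one missing record)
        X = [[1], [1], [1], [0], [-1], [0], [0]]
        gold = ["A", "A", "A", "A", "A", "B", "B"]
        return make_dataset(self.causes, self.sdict, gold, X)

    def test_unsmoothed_counting(self):
        pb = estimate_probbase(self._train(), smoothing=0.0)
        assert pb.values[0, 0] == pytest.approx(0.75)

    def test_jeffreys_smoothing(self):
        pb = estimate_probbase(self._train(), smoothing=0.5)
        assert pb.values[0, 0] == pytest.approx(3.5 / 5.0)
        assert pb.provenance == "trained"

    def test_zero_record_cause_flagged(self):
        X = [[1], [0]]
        ds = make_dataset(CauseList("adult", ("A", "B", "C")),
                          self.sdict, ["A", "B"], X)
        pb = estimate_probbase(ds)
        assert pb.zero_train_causes == ("C",)
        np.testing.assert_allclose(pb.values[2], 0.5)

    def test_label_permutation_equivariance(self):
        cfg = GeneratorConfig(n_causes=3, n_symptoms=9, n_records=600, seed=41)
        ds = generate_dataset(generate_probbase(cfg), cfg)
        pb = estimate_probbase(ds)
        # permute cause order in the cause list and relabel the data to match
        perm = [2, 0, 1]
        causes_p = CauseList("adult", tuple(ds.cause_list.causes[j] for j in perm))
        ds_p = VADataset(ds.record_ids, ds.module, ds.sites, ds.gold_causes,
                         ds.symptoms, causes_p, ds.symptom_dict)
        pb_p = estimate_probbase(ds_p)
        np.testing.assert_allclose(pb_p.values, pb.values[perm])


class TestBayesClassifier:
    causes = CauseList("adult", ("A", "B"))
    sdict = SymptomDictionary(("s1",), (False,))
    pb = Probbase(np.array([[0.9], [0.1]]), causes, sdict)

    def test_endorsed_symptom_bayes_by_hand(self):
        cause, post = classify(self.pb, None, [1], ClassifierConfig(prior="uniform"))
        assert cause == "A"
        np.testing.assert_allclose(post, [0.9, 0.1], atol=1e-12)

    def test_absent_symptom_bayes_by_hand(self):
        cause, post = classify(self.pb, None, [0], ClassifierConfig(prior="uniform"))
        assert cause == "B"
        np.testing.assert_allclose(post, [0.1, 0.9], atol=1e-12)

    def test_endorsed_only_ignores_absences(self):
        cfg = ClassifierConfig(kind="bayes_endorsed_only", prior="uniform")
        cause, post = classify(self.pb, None, [0], cfg)
        # no endorsement evidence: scores equal, tie broken to first cause
        assert cause == "A"
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_identical_rows_tie_break_to_first(self):
        pb = Probbase(np.array([[0.5], [0.5]]), self.causes, self.sdict)
        cause, _ = classify(pb, None, [1], ClassifierConfig(prior="uniform"))
        assert cause == "A"

    def test_all_missing_record_flagged_and_uses_prior(self):
        ds = make_dataset(self.causes, self.sdict, ["A"], [[-1]])
        clf = BayesClassifier(self.pb, ClassifierConfig(prior="uniform"))
        pred = clf.predict(ds)
        assert pred.flagged_ids == ("r0",)
        assert pred.predicted_causes[0] == "A"  # uniform prior -> first cause
        clf2 = BayesClassifier(self.pb, ClassifierConfig(), prior=np.array([0.2, 0.8]))
        assert clf2.predict(ds).predicted_causes[0] == "B"  # argmax prior

    def test_posteriors_sum_to_one_and_finite(self):
        cfg = GeneratorConfig(n_causes=4, n_symptoms=12, n_records=400, seed=6)
        ds = generate_dataset(generate_probbase(cfg), cfg)
        pb = estimate_probbase(ds)
        pred = BayesClassifier(pb, ClassifierConfig(prior="uniform")).predict(ds)
        assert np.isfinite(pred.posteriors).all()
        np.testing.assert_allclose(pred.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_symptom_mismatch_errors(self, toy_dataset):
        with pytest.raises(ValueError, match="do not match"):
            BayesClassifier(self.pb, ClassifierConfig()).predict(toy_dataset)

    def test_empty_dataset_errors(self):
        ds = make_dataset(self.causes, self.sdict, [], np.empty((0, 1)))
        with pytest.raises(ValueError, match="empty"):
            predict_all(BayesClassifier(self.pb, ClassifierConfig()), ds)


class TestSeparableLimit:
    def test_predictions_equal_gold_exactly(self, separable_dataset):
        ds, pb_true = separable_dataset
        pb = estimate_probbase(ds, smoothing=0.5)
        pred = BayesClassifier(pb, ClassifierConfig(prior="uniform")).predict(ds)
        assert (pred.predicted_causes == ds.gold_causes).all()


class TestRandomClassifier:
    def test_uniform_concentration(self):
        causes = CauseList("adult", tuple(f"c{i}" for i in range(34)))
        rc = RandomClassifier(causes, rng=9)
        labels = rc.predict_labels(34_000)
        counts = np.array([(labels == c).sum() for c in causes.causes])
        assert (np.abs(counts - 1000) <= 100).all()

    def test_determinism(self, separable_dataset):
        ds, _ = separable_dataset
        a = RandomClassifier(ds.cause_list, rng=4).predict(ds)
        b = RandomClassifier(ds.cause_list, rng=4).predict(ds)
        assert (a.predicted_causes == b.predicted_causes).all()

    def test_expected_ccc_near_zero_over_replicates(self):
        causes = CauseList("adult", ("A", "B", "C", "D"))
        rng = np.random.default_rng(11)
        cccs = []
        for _ in range(200):
            true = rng.choice(list("ABCD"), size=200)
            rc_labels = rng.choice(list("ABCD"), size=200)
            c = confusion_counts(true.tolist(), rc_labels.tolist(), causes)
            cccs.append(overall_ccc(ccc_per_cause(c), "mean"))
        assert abs(np.mean(cccs)) < 0.02


def test_full_likelihood_beats_endorsed_only_with_informative_absences():
    """Using absences must help when one cause's symptom profile nests
    another's: endorsements alone cannot tell the narrow cause from the broad
    one, while the absence of the broad cause's extra symptoms can."""
    cfg = GeneratorConfig(n_causes=3, n_symptoms=8, n_records=2400,
                          signature_size=2, noise_eps=0.05, missing_rate=0.0,
                          seed=29)
    pb_true = generate_probbase(cfg)
    P = np.full((3, 8), 0.05)
    P[0, 0:4] = 0.8          # broad cause: endorses s1-s4
    P[1, 0:2] = 0.8          # narrow cause nested in the broad one
    P[2, 2:4] = 0.8          # second narrow cause
    pb_true = Probbase(P, pb_true.cause_list, pb_true.symptom_dict)
    ds = generate_dataset(pb_true, cfg)
    pb = estimate_probbase(ds)
    mean_ccc = {}
    for kind in ("bayes_full", "bayes_endorsed_only"):
        pred = BayesClassifier(pb, ClassifierConfig(kind=kind, prior="uniform")).predict(ds)
        conf = confusion_counts(ds.gold_causes.tolist(),
                                pred.predicted_causes.tolist(), ds.cause_list)
        mean_ccc[kind] = overall_ccc(ccc_per_cause(conf), "mean")
    assert mean_ccc["bayes_full"] >= mean_ccc["bayes_endorsed_only"]
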