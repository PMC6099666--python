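"""Metrics, ROC/AUC, SVM training, cross-validation, bundles and binning."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imsp.encoding import FeatureMatrix
from imsp.model_eval import (EvalReport, ModelError, bin_probabilities,
                             cross_validate, fit_svc, fold_assignment,
                             metrics_from_counts, positive_probability,
                             roc_auc, train_svm)
from imsp.motif_mining import MotifPattern


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_metrics(tp, tn, fp, fn):
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    den = math.sqrt((tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return sens, spec, acc, mcc


def oracle_auc(scores, labels):
    """Pairwise comparison: P(random positive outscores random negative)."""
    pos = [s for s, l in zip(scores, labels) if l > 0]
    neg = [s for s, l in zip(scores, labels) if l < 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_fm(X, y):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])],
                      index=pd.Index([f"s{i}" for i in range(len(X))],
                                     name="id"))
    return FeatureMatrix(X=df, labels=pd.Series(y, index=df.index),
                         failures=[])


def two_cluster_data(n_per_class=100, sep=4.0, seed=0, d=6):
    rng = np.random.default_rng(seed)
    y = np.array([1.0] * n_per_class + [-1.0] * n_per_class)
    X = rng.normal(0, 1, (2 * n_per_class, d)) + sep / 2 * y[:, None]
    return X, y


class TestMetricsFromCounts:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 50, 0, 0), (1.0, 1.0, 1.0, 1.0)),
        ((25, 25, 25, 25), (0.5, 0.5, 0.5, 0.0)),
        ((70, 80, 20, 30), (0.7, 0.8, 0.75, 0.5025189076296064)),
    ])
    def test_examples(self, counts, expected):
        r = metrics_from_counts(*counts)
        assert (r.sensitivity, r.specificity, r.accuracy) == \
            pytest.approx(expected[:3])
        assert r.mcc == pytest.approx(expected[3])

    def test_fuzzed_against_oracle(self):
        rng = random.Random(0)
        for _ in range(1000):
            tp, tn = rng.randint(1, 500), rng.randint(1, 500)
            fp, fn = rng.randint(0, 500), rng.randint(0, 500)
            r = metrics_from_counts(tp, tn, fp, fn)
            sens, spec, acc, mcc = oracle_metrics(tp, tn, fp, fn)
            assert r.sensitivity == pytest.approx(sens)
            assert r.specificity == pytest.approx(spec)
            assert r.accuracy == pytest.approx(acc)
            assert r.mcc == pytest.approx(mcc)
            assert -1.0 <= r.mcc <= 1.0 and 0.0 <= r.accuracy <= 1.0

    def test_zero_denominator_mcc_is_zero(self):
        # every prediction negative: the TP+FP marginal is zero
        assert metrics_from_counts(0, 10, 0, 5).mcc == 0.0

    def test_absent_class_rejected(self):
        with pytest.raises(ModelError):
            metrics_from_counts(0, 10, 5, 0)


class TestROCAUC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, -1, -1, -1])
        assert auc == 0.5

    def test_mixed_example_against_pairwise_oracle(self):
        scores, labels = [0.9, 0.4, 0.35, 0.8], [1, -1, 1, -1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle_auc(scores, labels))
        assert auc == pytest.approx(0.5)  # 2 concordant of 4 pairs

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_roc_endpoints_and_monotonicity(self):
        roc, _ = roc_auc([0.9, 0.1, 0.8, 0.3, 0.5], [1, -1, 1, -1, 1])
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
        assert all(a[0] <= b[0] and a[1] <= b[1]
                   for a, b in zip(roc, roc[1:]))

    @given(st.lists(st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                              st.sampled_from([1, -1])),
                    min_size=2, max_size=12))
    @settings(max_examples=300, derandomize=True)
    def test_equals_pairwise_oracle_on_small_inputs(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if len({l for l in labels}) < 2:
            return
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle_auc(scores, labels))
        assert 0.0 <= auc <= 1.0


class TestTraining:
    def test_separable_clusters_high_cv_accuracy(self):
        X, y = two_cluster_data(n_per_class=100, sep=4.0, seed=0)
        report = cross_validate(make_fm(X, y), k=5, seed=0,
                                hyperparams=(8.0, 0.125))
        assert report.accuracy >= 0.95
        assert report.mcc >= 0.9

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(5):
            X, y = two_cluster_data(n_per_class=50, sep=4.0, seed=seed)
            rng = np.random.default_rng(seed)
            report = cross_validate(make_fm(X, rng.permutation(y)), k=5,
                                    seed=seed, hyperparams=(8.0, 0.125))
            accs.append(report.accuracy)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_train_svm_requires_min_samples(self):
        X, y = two_cluster_data(n_per_class=5, seed=0)
        motifs = [MotifPattern("KGD", 3)]
        with pytest.raises(ModelError, match="10 samples"):
            train_svm(make_fm(X, y), motifs)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ModelError):
            cross_validate(make_fm(X, np.ones(20)), k=5, seed=0)


class TestCrossValidation:
    def test_every_sample_predicted_once(self):
        X, y = two_cluster_data(n_per_class=50, seed=1)
        report = cross_validate(make_fm(X, y), k=5, seed=1,
                                hyperparams=(8.0, 0.125))
        assert report.n == 100

    def test_same_seed_identical_report(self):
        X, y = two_cluster_data(n_per_class=30, sep=1.0, seed=2)
        fm = make_fm(X, y)
        a = cross_validate(fm, k=5, seed=2, hyperparams=(8.0, 0.125))
        b = cross_validate(fm, k=5, seed=2, hyperparams=(8.0, 0.125))
        assert a.as_dict() == b.as_dict()

    def test_class_smaller_than_k_rejected(self):
        X, y = two_cluster_data(n_per_class=3, seed=0)
        with pytest.raises(ModelError):
            fold_assignment(y, 5, 0)

    def test_fold_assignment_stratified(self):
        y = np.array([1.0] * 50 + [-1.0] * 50)
        folds = fold_assignment(y, 5, 0)
        for f in range(5):
            assert (y[folds == f] > 0).sum() == 10


class TestBundle:
    def _bundle(self, seed=0):
        X, y = two_cluster_data(n_per_class=40, seed=seed, d=3)
        fm = make_fm(X, y)
        motifs = [MotifPattern("KGD", 3), MotifPattern("LLL", 3)]
        return train_svm(fm, motifs, seed=seed,
                         c_grid=(1.0, 8.0), gamma_grid=(0.125, 0.5)), X

    def test_roundtrip_bit_identical_predictions(self, tmp_path):
        bundle, X = self._bundle()
        before = positive_probability(bundle.classifier, X)
        bundle.save(tmp_path / "m")
        from imsp.model_eval import ModelBundle
        loaded = ModelBundle.load(tmp_path / "m")
        after = positive_probability(loaded.classifier, X)
        assert np.array_equal(before, after)
        assert loaded.selected_features == bundle.selected_features
        assert loaded.hyperparams == bundle.hyperparams
        assert [m.pattern for m in loaded.motifs] == \
            [m.pattern for m in bundle.motifs]

    def test_checksum_guard(self, tmp_path):
        bundle, _ = self._bundle()
        bundle.save(tmp_path / "m")
        (tmp_path / "m" / "classifier.joblib").write_bytes(b"corrupt")
        from imsp.model_eval import ModelBundle
        with pytest.raises(ModelError, match="checksum"):
            ModelBundle.load(tmp_path / "m")


class TestProbabilityBins:
    def test_basic_binning(self):
        pb = bin_probabilities([0.05, 0.55, 0.95])
        assert pb.counts[0] == pb.counts[5] == pb.counts[9] == 1
        assert sum(pb.counts) == 3

    def test_half_open_lower_edges(self):
        pb = bin_probabilities([0.10, 0.10, 0.10])
        assert pb.counts[1] == 3 and pb.counts[0] == 0

    def test_top_bin_closed_at_one(self):
        pb = bin_probabilities([1.0, 0.999])
        assert pb.counts[9] == 2

    def test_published_proteome_percentage(self):
        # one decile bin holding 7601 of 51469 scored proteins prints 14.77%
        probs = np.concatenate([np.full(7601, 0.85),
                                np.full(51469 - 7601, 0.15)])
        pb = bin_probabilities(probs)
        assert pb.total == 51469
        assert pb.counts[8] == 7601
        assert pb.percentages[8] == 14.77
        assert sum(pb.percentages) == pytest.approx(100.0, abs=0.05)
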