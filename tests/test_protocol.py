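import numpy as np
import pytest

from heartprint.protocol import (MCNEMAR_CRITICAL_95, ConfusionCounts,
                                 accuracy, confusion_matrix,
                                 cumulative_accuracy_distribution,
                                 fisher_z_summary, hter, mcnemar_yates,
                                 multisession_split, one_vs_rest_counts,
                                 per_subject_accuracies, pooled_one_vs_rest,
                                 stratified_kfold, verification_metrics)


class TestStratifiedKFold:
    def test_folds_partition_and_stratify(self):
        labels = np.repeat([f"s{i}" for i in range(5)], 100)
        folds = stratified_kfold(labels, k=10, seed=0)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(500))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)
            _, counts = np.unique(labels[te], return_counts=True)
            assert set(counts) == {10}

    def test_deterministic(self):
        labels = np.repeat(["a", "b"], 20)
        a = stratified_kfold(labels, k=4, seed=3)
        b = stratified_kfold(labels, k=4, seed=3)
        for (t1, e1), (t2, e2) in zip(a, b):
            np.testing.assert_array_equal(e1, e2)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array(["a"] * 20 + ["b"] * 3), k=5)


class TestMultisessionSplit:
    def test_two_session_swap(self):
        sessions = np.array(["1"] * 50 + ["2"] * 50, dtype=object)
        subjects = np.array((["a"] * 25 + ["b"] * 25) * 2, dtype=object)
        (a_tr, a_te), (b_tr, b_te) = multisession_split(sessions, subjects)
        assert sorted(np.concatenate([a_tr, a_te])) == list(range(100))
        np.testing.assert_array_equal(a_tr, b_te)
        np.testing.assert_array_equal(a_te, b_tr)
        assert set(sessions[a_tr]) == {"1"} and set(sessions[a_te]) == {"2"}

    def test_single_session_subject_halved(self):
        sessions = np.array(["1"] * 40, dtype=object)
        subjects = np.array(["solo"] * 40, dtype=object)
        (a, b), _ = multisession_split(sessions, subjects, seed=1)
        assert len(a) == 20 and len(b) == 20

    def test_deterministic(self):
        sessions = np.array(["1"] * 30, dtype=object)
        subjects = np.array(["x"] * 30, dtype=object)
        s1 = multisession_split(sessions, subjects, seed=5)
        s2 = multisession_split(sessions, subjects, seed=5)
        np.testing.assert_array_equal(s1[0][0], s2[0][0])


class TestAccuracy:
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(tp=95, tn=0, fp=5, fn=0), 0.95),
        (ConfusionCounts(tp=50, tn=50, fp=0, fn=0), 1.0),
        (ConfusionCounts(tp=25, tn=25, fp=25, fn=25), 0.5),
    ])
    def test_arithmetic(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))


class TestOneVsRest:
    CONFUSION = np.array([[8, 1, 1], [0, 10, 0], [2, 0, 8]])

    def test_hand_counted_example(self):
        c = one_vs_rest_counts(self.CONFUSION, 0)
        assert (c.tp, c.fn, c.fp, c.tn) == (8, 2, 2, 18)

    def test_counts_sum_to_total(self):
        for t in range(3):
            assert one_vs_rest_counts(self.CONFUSION, t).total \
                == self.CONFUSION.sum()

    def test_perfect_classifier_has_no_errors(self):
        eye = np.eye(4, dtype=int) * 10
        for t in range(4):
            c = one_vs_rest_counts(eye, t)
            assert c.fp == 0 and c.fn == 0

    def test_target_out_of_range(self):
        with pytest.raises(ValueError):
            one_vs_rest_counts(self.CONFUSION, 5)

    def test_pooled_counts(self):
        pooled = pooled_one_vs_rest(self.CONFUSION)
        assert pooled.total == 3 * self.CONFUSION.sum()
        assert pooled.fp == pooled.fn  # multiclass errors count once each way


class TestVerificationMetrics:
    def test_hand_counted_rates(self):
        m = verification_metrics(ConfusionCounts(tp=8, tn=18, fp=2, fn=2))
        assert m.frr == pytest.approx(0.2)
        assert m.far == pytest.approx(0.1)
        assert m.hter == pytest.approx(0.15)

    def test_published_style_hter(self):
        # a verification row with FRR=0.0008 and FAR=0.0658 implies
        # HTER = 0.033 at three decimals
        assert round(hter(0.0008, 0.0658), 3) == 0.033

    def test_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 100, 4)
            m = verification_metrics(ConfusionCounts(int(tp), int(tn),
                                                     int(fp), int(fn)))
            assert m.frr + m.tar == pytest.approx(1.0)
            assert m.far + m.trr == pytest.approx(1.0)
            assert m.hter == pytest.approx((m.frr + m.far) / 2)

    def test_zero_attempts_rejected(self):
        with pytest.raises(ValueError):
            verification_metrics(ConfusionCounts(tp=0, tn=5, fp=1, fn=0))


class TestMcNemar:
    def test_critical_value(self):
        assert MCNEMAR_CRITICAL_95 == pytest.approx(3.8415, abs=5e-5)

    def test_no_discordance(self):
        assert mcnemar_yates(0, 0) == (0.0, 1.0)

    def test_formula(self):
        stat, p = mcnemar_yates(10, 2)
        assert stat == pytest.approx(49 / 12)
        assert 0 < p < 0.05

    def test_symmetric_in_arguments(self):
        assert mcnemar_yates(3, 9) == mcnemar_yates(9, 3)


class TestFisherZ:
    def test_constant_input_recovers_value(self):
        mean, sd = fisher_z_summary(np.full(10, 0.85))
        assert mean == pytest.approx(0.85)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_two_value_example(self):
        # tanh((atanh(0.8) + atanh(0.95)) / 2)
        mean, _ = fisher_z_summary(np.array([0.8, 0.95]))
        assert mean == pytest.approx(0.8986, abs=1e-4)

    def test_duplication_invariance(self):
        a = np.array([0.7, 0.9, 1.0])
        m1, _ = fisher_z_summary(a)
        m2, _ = fisher_z_summary(np.concatenate([a, a]))
        assert m1 == pytest.approx(m2)

    def test_perfect_accuracies_do_not_diverge(self):
        mean, sd = fisher_z_summary(np.ones(5))
        assert np.isfinite(mean) and np.isfinite(sd)


class TestCumulativeDistribution:
    def test_all_perfect(self):
        t, f = cumulative_accuracy_distribution(np.ones(7))
        assert np.all(f == 1.0)

    def test_two_subject_example(self):
        _, f = cumulative_accuracy_distribution(
            np.array([0.5, 1.0]), thresholds=np.array([0.75]))
        assert f[0] == 0.5

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        _, f = cumulative_accuracy_distribution(rng.uniform(size=50))
        assert np.all(np.diff(f) <= 0)


class TestConfusionHelpers:
    def test_confusion_matrix_layout(self):
        m = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(m, [[1, 1], [0, 1]])

    def test_per_subject_accuracy_recovers_rates(self):
        confusion = np.array([[9, 1], [4, 16]])
        np.testing.assert_allclose(per_subject_accuracies(confusion),
                                   [0.9, 0.8])
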