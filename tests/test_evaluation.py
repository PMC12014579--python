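import numpy as np
import pytest

from cnmclda.evaluation import (
    UndefinedAUCError,
    kfold_cv,
    lodocv,
    loocv,
    rank_candidates,
    roc_auc,
)
from cnmclda.model import Hyperparameters
from cnmclda.synthetic import permute_labels
from conftest import mann_whitney_auc


class TestRocAuc:
    def test_worked_example_three_of_four_pairs_ordered(self):
        res = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 1]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        res = roc_auc(rng.random(30), rng.integers(0, 2, 30))
        assert (res.tpr[0], res.fpr[0]) == (0.0, 0.0)
        assert (res.tpr[-1], res.fpr[-1]) == (1.0, 1.0)
        assert (np.diff(res.tpr) >= 0).all() and (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.thresholds) < 0).all()

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = rng.integers(4, 40)
            scores = rng.choice(np.round(rng.random(6), 2), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_reference_implementation(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.random(50)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        base = roc_auc(scores, labels).auc
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert roc_auc(f(scores), labels).auc == pytest.approx(base, abs=1e-12)


class TestKfoldCV:
    def test_folds_partition_positives_with_balanced_sizes(self, small_fixture):
        _, dataset, similarities, _ = small_fixture
        hyper = Hyperparameters(max_iterations=30, seed=0)
        report = kfold_cv(dataset, similarities, K=4, seed=7, hyper=hyper)
        cells = [tuple(c) for fold in report.assignments.values() for c in fold]
        assert sorted(cells) == sorted(map(tuple, np.argwhere(dataset.LD == 1)))
        sizes = [len(f) for f in report.assignments.values()]
        assert max(sizes) - min(sizes) <= 1
        assert len(report.aucs) == 4
        assert report.mean == pytest.approx(report.aucs.mean())

    def test_assignments_reproducible_per_seed(self, small_fixture):
        _, dataset, similarities, _ = small_fixture
        hyper = Hyperparameters(max_iterations=5, seed=0)
        r1 = kfold_cv(dataset, similarities, K=3, seed=11, hyper=hyper)
        r2 = kfold_cv(dataset, similarities, K=3, seed=11, hyper=hyper)
        for f in r1.assignments:
            np.testing.assert_array_equal(r1.assignments[f], r2.assignments[f])
        np.testing.assert_array_equal(r1.aucs, r2.aucs)

    def test_too_few_positives_rejected(self, small_fixture):
        _, dataset, similarities, _ = small_fixture
        with pytest.raises(ValueError):
            kfold_cv(dataset, similarities, K=1, seed=0, hyper=Hyperparameters())


class TestLodocv:
    def test_reports_exactly_diseases_with_positives(self, small_fixture):
        _, dataset, similarities, _ = small_fixture
        hyper = Hyperparameters(max_iterations=30, seed=0)
        report = lodocv(dataset, similarities, hyper)
        with_pos = [
            dataset.disease_names[dataset.disease_sub_index[j]]
            for j in range(dataset.nd_ld)
            if dataset.LD[:, j].sum() > 0
        ]
        assert report.keys == with_pos
        assert ((report.aucs >= 0) & (report.aucs <= 1)).all()

    def test_planted_signal_beats_permuted_labels(self, default_fixture):
        _, dataset, similarities, _ = default_fixture
        hyper = Hyperparameters(max_iterations=1500, seed=0)
        real = lodocv(dataset, similarities, hyper)
        permuted = lodocv(permute_labels(dataset, seed=99), similarities, hyper)
        assert real.mean > permuted.mean


class TestLoocv:
    def test_pooled_auc_and_determinism(self, identity_2x2):
        dataset, similarities = identity_2x2
        hyper = Hyperparameters(max_iterations=60, seed=0)
        a1 = loocv(dataset, similarities, hyper)
        a2 = loocv(dataset, similarities, hyper)
        assert 0.0 <= a1 <= 1.0
        assert a1 == a2


class TestRankCandidates:
    def make(self):
        from cnmclda.data_io import AssociationDataset

        return AssociationDataset(
            mirna_names=["m1"],
            disease_names=["dA", "dB"],
            lncrna_names=["lnc1", "lnc2", "lnc3", "lnc4"],
            MD=np.ones((1, 2)),
            ML=np.ones((1, 4)),
            LD=np.array([[1.0, 0.0], [0.0, 0.0]]),
            lncrna_sub_index=np.array([0, 1]),
            disease_sub_index=np.array([0, 1]),
        )

    def test_manual_ordering_and_exclusion(self):
        ds = self.make()
        scores = np.array([[0.9, 0.1], [0.2, 0.2], [0.8, 0.3], [0.8, 0.4]])
        top = rank_candidates(scores, ds, "dA", k=3)
        # lnc1 is known for dA and must not appear; tie 0.8 broken by name
        assert top == [("lnc3", 0.8), ("lnc4", 0.8), ("lnc2", 0.2)]

    def test_k_larger_than_candidate_pool(self):
        ds = self.make()
        scores = np.zeros((4, 2))
        assert len(rank_candidates(scores, ds, "dA", k=100)) == 3

    def test_unknown_disease_rejected(self):
        with pytest.raises(KeyError):
            rank_candidates(np.zeros((4, 2)), self.make(), "nope", 3)
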