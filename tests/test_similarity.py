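import itertools

import numpy as np
import pytest

from cnmclda.data_io import DiseaseAnnotation
from cnmclda.similarity import (
    disease_semantic_similarity,
    lncrna_functional_similarity,
    semantic_contributions,
)


def ann(name, *codes):
    return DiseaseAnnotation(disease_name=name, tree_numbers=frozenset(codes))


class TestSemanticContributions:
    def test_own_node_contributes_one(self):
        assert semantic_contributions(ann("x", "C04")) == {"C04": 1.0}

    def test_chain_decays_geometrically(self):
        c = semantic_contributions(ann("x", "A.B.C"), decay=0.5)
        assert c == {"A.B.C": 1.0, "A.B": 0.5, "A": 0.25}

    def test_diamond_takes_max_over_children(self):
        # children of R have contributions 0.5 (via R.A) and 0.25 (via R.C),
        # so R gets 0.5 * max = 0.25
        c = semantic_contributions(ann("x", "R.A.B", "R.C.D.E"), decay=0.5)
        assert c["R.A"] == 0.5
        assert c["R.C"] == 0.25
        assert c["R"] == 0.25

    def test_empty_annotation_empty_map(self):
        assert semantic_contributions(ann("x")) == {}

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            semantic_contributions(ann("x", "C04"), decay=1.0)


class TestDiseaseSemanticSimilarity:
    def run(self, annotations, decay=0.5):
        names = [a.disease_name for a in annotations]
        amap = {a.disease_name: a for a in annotations}
        return disease_semantic_similarity(names, amap, decay)

    def test_identical_annotations_give_one(self):
        S = self.run([ann("a", "C04.1"), ann("b", "C04.1")])
        assert S[0, 1] == 1.0

    def test_disjoint_dags_give_zero(self):
        S = self.run([ann("a", "C04"), ann("b", "D05")])
        assert S[0, 1] == 0.0

    def test_shared_parent_gives_one_third(self):
        # each disease: own node 1, shared parent 0.5 -> (0.5+0.5)/(1.5+1.5)
        S = self.run([ann("a", "T.A"), ann("b", "T.B")])
        assert S[0, 1] == pytest.approx(1.0 / 3.0)

    def test_unannotated_disease_zero_offdiag_unit_diag(self):
        S = self.run([ann("a", "C04"), ann("b")])
        assert S[0, 1] == 0.0 and S[1, 1] == 1.0

    def test_deeper_shared_ancestor_increases_similarity(self):
        # star family: pairs share a prefix of increasing depth
        base = "A.B.C.D"
        sims = []
        for k in range(1, 5):
            shared = ".".join(base.split(".")[:k])
            S = self.run([ann("x", shared + ".X"), ann("y", shared + ".Y")])
            sims.append(S[0, 1])
        assert all(a < b for a, b in zip(sims, sims[1:]))

    def test_matches_bruteforce_oracle_on_six_diseases(self):
        annotations = [
            ann("d1", "C04.588.274"),
            ann("d2", "C04.588"),
            ann("d3", "C04.111", "C06.2"),
            ann("d4", "C06.2.9"),
            ann("d5", "D12"),
            ann("d6", "C04.588.274.5"),
        ]
        S = self.run(annotations, decay=0.5)

        def contributions(a):  # independent dict-based re-derivation
            nodes = {}
            for tn in a.tree_numbers:
                parts = tn.split(".")
                chain = [".".join(parts[: k + 1]) for k in range(len(parts))]
                for depth_from_leaf, node in enumerate(reversed(chain)):
                    val = 0.5 ** depth_from_leaf
                    nodes[node] = max(nodes.get(node, 0.0), val)
            return nodes

        for i, j in itertools.combinations(range(6), 2):
            ca, cb = contributions(annotations[i]), contributions(annotations[j])
            shared = ca.keys() & cb.keys()
            expect = (
                sum(ca[t] + cb[t] for t in shared)
                / (sum(ca.values()) + sum(cb.values()))
                if shared
                else 0.0
            )
            assert S[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetry_range_and_diagonal(self):
        rng = np.random.default_rng(1)
        pool = ["C01", "C01.2", "C01.2.3", "C04", "C04.5", "D06.1"]
        annotations = [
            ann(f"d{i}", *rng.choice(pool, size=rng.integers(1, 3), replace=False))
            for i in range(8)
        ]
        S = self.run(annotations)
        np.testing.assert_array_equal(S, S.T)
        assert (S >= 0).all() and (S <= 1).all()
        np.testing.assert_array_equal(np.diag(S), np.ones(8))


class TestLncrnaFunctionalSimilarity:
    def test_identical_single_disease_sets_give_one(self):
        S_D = np.eye(2)
        LD = np.array([[1.0, 0.0], [1.0, 0.0]])
        S_L = lncrna_functional_similarity(
            S_D, LD, np.array([0, 1]), np.array([0, 1]), nl=2
        )
        assert S_L[0, 1] == 1.0

    def test_zero_cross_similarity_gives_zero(self):
        S_D = np.eye(2)
        LD = np.array([[1.0, 0.0], [0.0, 1.0]])
        S_L = lncrna_functional_similarity(
            S_D, LD, np.array([0, 1]), np.array([0, 1]), nl=2
        )
        assert S_L[0, 1] == 0.0

    def test_best_match_average_worked_example(self):
        # D_u = {d1}, D_v = {d1, d2}, S_D(d1,d2) = 0.4 -> (1 + 1 + 0.4)/3
        S_D = np.array([[1.0, 0.4], [0.4, 1.0]])
        LD = np.array([[1.0, 0.0], [1.0, 1.0]])
        S_L = lncrna_functional_similarity(
            S_D, LD, np.array([0, 1]), np.array([0, 1]), nl=2
        )
        assert S_L[0, 1] == pytest.approx(0.8)

    def test_unassociated_lncrnas_zero_offdiag_unit_diag(self):
        S_D = np.eye(2)
        LD = np.array([[1.0, 0.0], [0.0, 0.0]])
        S_L = lncrna_functional_similarity(
            S_D, LD, np.array([0, 1]), np.array([0, 1]), nl=3
        )
        assert S_L[2, 0] == 0.0 and S_L[1, 0] == 0.0
        np.testing.assert_array_equal(np.diag(S_L), np.ones(3))

    def test_symmetry_on_synthetic_fixture(self, small_fixture):
        _, dataset, similarities, _ = small_fixture
        S_L = lncrna_functional_similarity(
            similarities.S_D,
            dataset.LD,
            dataset.lncrna_sub_index,
            dataset.disease_sub_index,
            dataset.nl,
        )
        np.testing.assert_allclose(S_L, S_L.T, atol=0)
        assert (S_L >= 0).all() and (S_L <= 1).all()
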