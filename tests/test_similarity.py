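import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from combowalk import (
    AlignmentParams,
    AssociationMatrix,
    FingerprintSet,
    OntologyDAG,
    ProteinAnnotation,
    SimilarityMatrix,
    bipartite_projection_flow,
    bipartite_projection_similarity,
    disjunction_integrate,
    go_semantic_similarity,
    jaccard_similarity,
    sequence_similarity,
    wang_term_similarity,
)
from oracles import jaccard_sets, smith_waterman_gotoh, wang_pair


def fps(rows) -> FingerprintSet:
    rows = np.atleast_2d(np.asarray(rows))
    return FingerprintSet([f"d{i}" for i in range(rows.shape[0])], rows)


class TestJaccard:
    def test_identity_and_disjoint(self):
        sim = jaccard_similarity(
            fps([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        )
        assert sim.values[0, 1] == 1.0
        assert sim.values[0, 2] == 0.0
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_partial_overlap(self):
        # bit sets {1,2,3} vs {2,3,4}: intersection 2, union 4
        sim = jaccard_similarity(
            fps([[0, 1, 1, 1, 0], [0, 0, 1, 1, 1]])
        )
        assert sim.values[0, 1] == pytest.approx(0.5)

    def test_empty_pair_is_zero(self, caplog):
        with caplog.at_level("WARNING"):
            sim = jaccard_similarity(fps([[0, 0], [0, 0]]))
        assert sim.values[0, 1] == 0.0
        assert "empty fingerprints" in caplog.text

    def test_matches_set_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        bits = (rng.random((50, 880)) < 0.1).astype(int)
        sim = jaccard_similarity(fps(bits))
        sets = [set(np.flatnonzero(row)) for row in bits]
        for i in range(50):
            for j in range(50):
                assert sim.values[i, j] == pytest.approx(
                    jaccard_sets(sets[i], sets[j]), abs=1e-14
                )


class TestBipartiteProjection:
    def test_worked_2x2_example(self):
        assoc = AssociationMatrix(["d1", "d2"], ["p1", "p2"], np.array([[1.0, 1.0], [0.0, 1.0]]))
        flow = bipartite_projection_flow(assoc)
        assert flow[0, 1] == pytest.approx(0.5)
        assert flow[1, 0] == pytest.approx(0.25)
        sim = bipartite_projection_similarity(assoc)
        assert sim.values[0, 1] == pytest.approx((0.5 + 0.25) / 2)

    def test_isolated_drug_row_and_column_zero(self):
        assoc = AssociationMatrix(
            ["d1", "d2", "d3"], ["p1", "p2"],
            np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]]),
        )
        sim = bipartite_projection_similarity(assoc)
        assert np.all(sim.values[1, :] == 0)
        assert np.all(sim.values[:, 1] == 0)

    def test_binary_resource_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = (rng.random((8, 6)) < 0.4).astype(float)
            assoc = AssociationMatrix(
                [f"d{i}" for i in range(8)], [f"p{j}" for j in range(6)], a
            )
            flow = bipartite_projection_flow(assoc)
            colsums = flow.sum(axis=0)
            for j in range(8):
                if a[j].sum() > 0:
                    assert colsums[j] == pytest.approx(1.0, abs=1e-10)
                else:
                    assert colsums[j] == 0.0


class TestSequenceSimilarity:
    def make_annotation(self, seqs):
        return ProteinAnnotation(
            [f"p{i}" for i in range(len(seqs))], seqs, [set() for _ in seqs]
        )

    def test_self_similarity_is_one_and_symmetric(self):
        ann = self.make_annotation(["HEAGAWGHEE", "PAWHEAE", "MKTAYIAKQR"])
        sim = sequence_similarity(ann)
        assert np.allclose(np.diag(sim.values), 1.0)
        assert np.allclose(sim.values, sim.values.T)
        assert sim.values.max() <= 1 + 1e-12

    def test_matches_gotoh_oracle(self):
        params = AlignmentParams()
        blosum = substitution_matrices.load(params.matrix_name)
        rng = np.random.default_rng(11)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["HEAGAWGHEE", "PAWHEAE"] + [
            "".join(rng.choice(aa, size=rng.integers(8, 25))) for _ in range(4)
        ]
        ann = self.make_annotation(seqs)
        sim = sequence_similarity(ann, params)
        for i in range(len(seqs)):
            for j in range(i, len(seqs)):
                raw = smith_waterman_gotoh(
                    seqs[i], seqs[j], blosum, params.gap_open, params.gap_extend
                )
                self_i = smith_waterman_gotoh(
                    seqs[i], seqs[i], blosum, params.gap_open, params.gap_extend
                )
                self_j = smith_waterman_gotoh(
                    seqs[j], seqs[j], blosum, params.gap_open, params.gap_extend
                )
                expected = raw / np.sqrt(self_i * self_j)
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


@pytest.fixture
def toy_dag():
    # R <- A <- C ; A <- D (part_of) ; R <- B
    return OntologyDAG(
        terms={"R", "A", "B", "C", "D"},
        edges=[
            ("A", "R", "is_a"),
            ("B", "R", "is_a"),
            ("C", "A", "is_a"),
            ("D", "A", "part_of"),
        ],
    )


class TestGOSimilarity:
    def test_identical_term_sets(self, toy_dag):
        ann = ProteinAnnotation(["p1", "p2"], ["MK", "MK"], [{"C"}, {"C"}])
        sim = go_semantic_similarity(ann, toy_dag)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_no_common_ancestor(self):
        dag = OntologyDAG(
            terms={"R1", "R2", "A", "B"},
            edges=[("A", "R1", "is_a"), ("B", "R2", "is_a")],
        )
        ann = ProteinAnnotation(["p1", "p2"], ["MK", "MK"], [{"A"}, {"B"}])
        sim = go_semantic_similarity(ann, dag)
        assert sim.values[0, 1] == 0.0

    def test_matches_hand_enumerated_wang_values(self, toy_dag):
        parents = {
            "A": [("R", 0.8)],
            "B": [("R", 0.8)],
            "C": [("A", 0.8)],
            "D": [("A", 0.6)],
        }
        # hand enumeration: S_C = {C:1, A:.8, R:.64}, S_D = {D:1, A:.6, R:.48}
        # sim(C,D) = (1.4 + 1.12) / (2.44 + 2.08)
        assert wang_term_similarity("C", "D", toy_dag) == pytest.approx(2.52 / 4.52)
        for a in "ABCD":
            for b in "ABCD":
                assert wang_term_similarity(a, b, toy_dag) == pytest.approx(
                    wang_pair(a, b, parents), abs=1e-12
                )

    def test_unresolvable_terms_dropped_with_warning(self, toy_dag, caplog):
        ann = ProteinAnnotation(
            ["p1", "p2"], ["MK", "MK"], [{"C", "ZZZ"}, {"C"}]
        )
        with caplog.at_level("WARNING"):
            sim = go_semantic_similarity(ann, toy_dag)
        assert "ZZZ" in caplog.text
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_protein_without_terms_is_zero(self, toy_dag, caplog):
        ann = ProteinAnnotation(["p1", "p2"], ["MK", "MK"], [set(), {"C"}])
        with caplog.at_level("WARNING"):
            sim = go_semantic_similarity(ann, toy_dag)
        assert sim.values[0, 1] == 0.0

    def test_namespace_average(self):
        # identical in one namespace, absent in the other for p2
        dag = OntologyDAG(
            terms={"R1", "R2", "A", "B"},
            edges=[("A", "R1", "is_a"), ("B", "R2", "is_a")],
            namespaces={"R1": "bp", "A": "bp", "R2": "mf", "B": "mf"},
        )
        ann = ProteinAnnotation(
            ["p1", "p2"], ["MK", "MK"], [{"A", "B"}, {"A"}]
        )
        sim = go_semantic_similarity(ann, dag)
        # only the bp namespace is shared -> average over 1 namespace = 1.0
        assert sim.values[0, 1] == pytest.approx(1.0)


class TestDisjunction:
    def grid_matrices(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        pairs = [(a, b) for a in grid for b in grid]
        n = len(pairs)
        ids = [f"x{i}" for i in range(2)]
        return grid, pairs, ids

    def test_exhaustive_grid(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for a in grid:
            for b in grid:
                s1 = SimilarityMatrix(["i", "j"], np.array([[1.0, a], [a, 1.0]]))
                s2 = SimilarityMatrix(["i", "j"], np.array([[1.0, b], [b, 1.0]]))
                fused = disjunction_integrate(s1, s2)
                assert fused.values[0, 1] == pytest.approx(1 - (1 - a) * (1 - b))
                assert fused.values[0, 1] >= max(a, b) - 1e-15
                assert fused.values[0, 1] <= 1.0

    def test_mismatched_ids_error(self):
        s1 = SimilarityMatrix(["i", "j"], np.eye(2))
        s2 = SimilarityMatrix(["i", "k"], np.eye(2))
        with pytest.raises(ValueError, match="mismatched"):
            disjunction_integrate(s1, s2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0, 1), b=st.floats(0, 1), delta=st.floats(0, 1)
    )
    def test_monotone_in_each_argument(self, a, b, delta):
        a2 = min(a + delta, 1.0)

        def fuse(x, y):
            s1 = SimilarityMatrix(["i", "j"], np.array([[1.0, x], [x, 1.0]]))
            s2 = SimilarityMatrix(["i", "j"], np.array([[1.0, y], [y, 1.0]]))
            return disjunction_integrate(s1, s2).values[0, 1]

        assert fuse(a2, b) >= fuse(a, b) - 1e-12
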