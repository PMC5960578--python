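"""Semantic, GIP-kernel and integrated disease similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lmpairnet as lp
from lmpairnet.io import disease_dag_from_edges

from conftest import gip_loop, random_dag, semantic_contribution_paths


class TestSemanticProfile:
    def test_isolated_node(self):
        dag = lp.DiseaseDAG(("x",), ())
        prof = lp.semantic_profile(dag, "x", 0.5)
        assert prof.contributions == {"x": 1.0}
        assert prof.semantic_value == 1.0

    def test_chain_decay(self):
        dag = disease_dag_from_edges([("a", "root"), ("b", "a")])
        prof = lp.semantic_profile(dag, "b", 0.5)
        assert prof.contributions == {"b": 1.0, "a": 0.5, "root": 0.25}
        assert prof.semantic_value == pytest.approx(1.75)

    def test_diamond_takes_max_over_paths(self):
        dag = disease_dag_from_edges(
            [("a1", "root"), ("a2", "root"), ("b", "a1"), ("b", "a2")]
        )
        prof = lp.semantic_profile(dag, "b", 0.5)
        assert prof.contributions["root"] == pytest.approx(0.25)
        assert prof.semantic_value == pytest.approx(2.25)

    def test_unknown_disease_raises(self):
        dag = lp.DiseaseDAG(("x",), ())
        with pytest.raises(KeyError):
            lp.semantic_profile(dag, "nope", 0.5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_contributions_match_max_over_paths_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, 12)
        delta = 0.5
        for disease in dag.nodes[6:]:
            prof = lp.semantic_profile(dag, disease, delta)
            for t, c in prof.contributions.items():
                assert c == pytest.approx(
                    semantic_contribution_paths(dag, disease, t, delta), abs=1e-12
                )


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self):
        dag = disease_dag_from_edges([("a", "root"), ("b", "a")])
        assert lp.semantic_similarity(dag, "b", "b", 0.5) == pytest.approx(1.0)

    def test_siblings_under_shared_root(self):
        dag = disease_dag_from_edges([("d1", "root"), ("d2", "root")])
        assert lp.semantic_similarity(dag, "d1", "d2", 0.5) == pytest.approx(1.0 / 3.0)

    def test_disjoint_ancestries_are_zero(self):
        dag = disease_dag_from_edges([("a", "r1"), ("b", "r2")])
        assert lp.semantic_similarity(dag, "a", "b", 0.5) == 0.0

    def test_matrix_properties_on_random_dags(self):
        for seed in range(6):
            dag = random_dag(np.random.default_rng(seed), 15)
            sim = lp.semantic_similarity_matrix(dag, dag.nodes, 0.5)
            assert np.allclose(np.diag(sim.values), 1.0)
            assert (sim.values >= 0).all() and (sim.values <= 1 + 1e-12).all()
            assert np.allclose(sim.values, sim.values.T)

    def test_missing_disease_falls_back_to_isolated(self):
        dag = disease_dag_from_edges([("a", "root")])
        sim = lp.semantic_similarity_matrix(dag, ("a", "ghost"), 0.5)
        assert sim["a", "ghost"] == 0.0
        assert sim["ghost", "ghost"] == 1.0


class TestGipKernel:
    def test_identical_profiles_have_similarity_one(self):
        Y = np.array([[1, 1], [0, 0], [1, 1]], dtype=float)
        assert lp.gip_kernel(Y)[0, 1] == pytest.approx(1.0)

    def test_orthogonal_unit_profiles(self):
        Y = np.array([[1, 0], [0, 1]], dtype=float)
        sim = lp.gip_kernel(Y)
        assert sim[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="empty interaction profiles"):
            lp.gip_kernel(np.zeros((4, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        Y = (rng.random((8, 6)) < 0.4).astype(float)
        if Y.sum() == 0:
            Y[0, 0] = 1.0
        assert np.max(np.abs(lp.gip_kernel(Y) - gip_loop(Y))) < 1e-12

    def test_diagonal_exactly_one_and_range(self):
        rng = np.random.default_rng(9)
        Y = (rng.random((10, 7)) < 0.3).astype(float)
        Y[0, :] = 1.0  # guarantee nonzero
        sim = lp.gip_kernel(Y)
        assert (np.diag(sim) == 1.0).all()
        assert (sim > 0).all() and (sim <= 1.0).all()

    @given(perm_seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_column_permutation_equivariance(self, perm_seed):
        rng = np.random.default_rng(17)
        Y = (rng.random((6, 5)) < 0.5).astype(float)
        Y[0, :] = 1.0
        perm = np.random.default_rng(perm_seed).permutation(5)
        base = lp.gip_kernel(Y)
        assert np.allclose(lp.gip_kernel(Y[:, perm]), base[np.ix_(perm, perm)])


class TestDiseaseGip:
    def test_sqrt_combination_against_loop_kernels(self, default_model):
        m = default_model
        y1 = m.g1.adjacency[
            np.ix_(
                [m.g1.left_index()[g] for g in m.tripartite.lnc_ids],
                [m.g1.right_index()[d] for d in m.tripartite.disease_ids],
            )
        ].astype(float)
        y2 = m.g2.adjacency[
            np.ix_(
                [m.g2.left_index()[g] for g in m.tripartite.mir_ids],
                [m.g2.right_index()[d] for d in m.tripartite.disease_ids],
            )
        ].astype(float)
        expected = np.sqrt(gip_loop(y1) * gip_loop(y2))
        np.fill_diagonal(expected, 1.0)
        got = lp.disease_gip_similarity(
            m.g1, m.g2, m.tripartite.disease_ids,
            lnc_rows=m.tripartite.lnc_ids, mir_rows=m.tripartite.mir_ids,
        )
        assert np.max(np.abs(got.values - expected)) < 1e-12

    def test_equal_layers_reduce_to_single_kernel(self):
        edges_l = [("l1", "d1"), ("l2", "d2")]
        edges_m = [("m1", "d1"), ("m2", "d2")]
        from lmpairnet.io import association_table_from_edges, KIND_LNC_DISEASE, KIND_MIR_DISEASE

        g1 = lp.build_bipartite(association_table_from_edges(edges_l, KIND_LNC_DISEASE))
        g2 = lp.build_bipartite(association_table_from_edges(edges_m, KIND_MIR_DISEASE))
        got = lp.disease_gip_similarity(g1, g2, ("d1", "d2"))
        single = lp.gip_kernel(g1.adjacency.astype(float))
        assert np.allclose(got.values, single)

    def test_missing_disease_is_an_error(self, default_model):
        m = default_model
        with pytest.raises(KeyError):
            lp.disease_gip_similarity(m.g1, m.g2, ("not-a-disease",))


class TestIntegration:
    def test_zero_semantic_falls_back_to_gip(self):
        ids = ("a", "b")
        sem = lp.SimilarityMatrix(ids, np.array([[1.0, 0.0], [0.0, 1.0]]))
        gip = lp.SimilarityMatrix(ids, np.array([[1.0, 0.7], [0.7, 1.0]]))
        out = lp.integrated_disease_similarity(sem, gip)
        assert out["a", "b"] == pytest.approx(0.7)

    def test_nonzero_semantic_averages(self):
        ids = ("a", "b")
        sem = lp.SimilarityMatrix(ids, np.array([[1.0, 0.4], [0.4, 1.0]]))
        gip = lp.SimilarityMatrix(ids, np.array([[1.0, 0.6], [0.6, 1.0]]))
        out = lp.integrated_disease_similarity(sem, gip)
        assert out["a", "b"] == pytest.approx(0.5)

    def test_bounded_by_entrywise_max(self, default_model):
        m = default_model
        sem, gip = m.dis_sem.values, None
        from lmpairnet.disease_similarity import disease_gip_similarity

        gipm = disease_gip_similarity(
            m.g1, m.g2, m.tripartite.disease_ids,
            lnc_rows=m.tripartite.lnc_ids, mir_rows=m.tripartite.mir_ids,
        )
        out = lp.integrated_disease_similarity(m.dis_sem, gipm)
        assert (out.values <= np.maximum(sem, gipm.values) + 1e-12).all()

    def test_shape_mismatch_is_an_error(self):
        a = lp.SimilarityMatrix(("x",), np.array([[1.0]]))
        b = lp.SimilarityMatrix(("x", "y"), np.eye(2))
        with pytest.raises(ValueError):
            lp.integrated_disease_similarity(a, b)
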