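"""Bipartite, tripartite and disease-pair network construction."""

import numpy as np
import pytest

import lmpairnet as lp
from lmpairnet.io import (
    KIND_LNC_DISEASE,
    KIND_LNC_MIR,
    KIND_MIR_DISEASE,
    association_table_from_edges,
)

from conftest import triangles_brute_force


def _table(edges, kind):
    return association_table_from_edges(edges, kind)


def _random_instance(rng, n_d=10, n_l=10, n_m=10, p=0.25):
    lncs = [f"l{i}" for i in range(n_l)]
    mirs = [f"m{i}" for i in range(n_m)]
    dis = [f"d{i}" for i in range(n_d)]
    ld = [(l, d) for l in lncs for d in dis if rng.random() < p]
    md = [(m, d) for m in mirs for d in dis if rng.random() < p]
    lm = [(l, m) for l in lncs for m in mirs if rng.random() < p]
    return ld, md, lm


class TestBipartite:
    def test_adjacency_matches_curated_scale(self):
        """A 2048-edge table over 1126 lncRNAs and 356 diseases yields a
        1126 x 356 adjacency with 2048 ones."""
        rng = np.random.default_rng(0)
        lncs = [f"l{i}" for i in range(1126)]
        dis = [f"d{i}" for i in range(356)]
        edges = set()
        # every id must appear so the vocabulary is exactly 1126 x 356
        for i, l in enumerate(lncs):
            edges.add((l, dis[i % 356]))
        while len(edges) < 2048:
            edges.add((lncs[rng.integers(1126)], dis[rng.integers(356)]))
        net = lp.build_bipartite(_table(sorted(edges), KIND_LNC_DISEASE))
        assert net.adjacency.shape == (1126, 356)
        assert net.n_edges == 2048

    def test_single_edge(self):
        net = lp.build_bipartite(_table([("l1", "d1")], KIND_LNC_DISEASE))
        assert net.adjacency.tolist() == [[1]]

    def test_edge_count_equals_matrix_sum(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ld, _, _ = _random_instance(rng)
            if not ld:
                continue
            net = lp.build_bipartite(_table(ld, KIND_LNC_DISEASE))
            assert net.n_edges == len(set(ld))


class TestTripartite:
    def test_minimal_triangle(self):
        tri = lp.build_tripartite(
            lp.build_bipartite(_table([("l1", "d1")], KIND_LNC_DISEASE)),
            lp.build_bipartite(_table([("m1", "d1")], KIND_MIR_DISEASE)),
            lp.build_bipartite(_table([("l1", "m1")], KIND_LNC_MIR)),
        )
        assert tri.lnc_ids == ("l1",)
        assert tri.mir_ids == ("m1",)
        assert tri.disease_ids == ("d1",)
        assert tri.n_triangles == 1

    def test_no_triangle_is_an_error(self):
        # d1 and d2 are shared, but l1's and m1's disease edges never coincide
        with pytest.raises(ValueError, match="no triangles"):
            lp.build_tripartite(
                lp.build_bipartite(_table([("l1", "d1"), ("l2", "d2")], KIND_LNC_DISEASE)),
                lp.build_bipartite(_table([("m1", "d2"), ("m2", "d1")], KIND_MIR_DISEASE)),
                lp.build_bipartite(_table([("l1", "m1")], KIND_LNC_MIR)),
            )

    def test_disjoint_diseases_are_an_error(self):
        with pytest.raises(ValueError, match="no shared diseases"):
            lp.build_tripartite(
                lp.build_bipartite(_table([("l1", "d1")], KIND_LNC_DISEASE)),
                lp.build_bipartite(_table([("m1", "d2")], KIND_MIR_DISEASE)),
                lp.build_bipartite(_table([("l1", "m1")], KIND_LNC_MIR)),
            )

    def test_no_shared_disease_is_an_error(self):
        with pytest.raises(ValueError, match="no shared diseases"):
            lp.build_tripartite(
                lp.build_bipartite(_table([("l1", "dA")], KIND_LNC_DISEASE)),
                lp.build_bipartite(_table([("m1", "dB")], KIND_MIR_DISEASE)),
                lp.build_bipartite(_table([("l1", "m1")], KIND_LNC_MIR)),
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ld, md, lm = _random_instance(rng)
        expected = triangles_brute_force(ld, md, lm)
        if not expected:
            pytest.skip("no triangles drawn at this seed")
        tri = lp.build_tripartite(
            lp.build_bipartite(_table(ld, KIND_LNC_DISEASE)),
            lp.build_bipartite(_table(md, KIND_MIR_DISEASE)),
            lp.build_bipartite(_table(lm, KIND_LNC_MIR)),
        )
        got = {
            (tri.disease_ids[d], tri.lnc_ids[l], tri.mir_ids[m])
            for l, m, d in zip(*np.nonzero(tri.triangle_tensor()))
        }
        assert got == expected

    def test_pruning_keeps_every_retained_edge_endpoint(self, default_dataset):
        ds = default_dataset
        tri = lp.build_tripartite(
            lp.build_bipartite(ds.lnc_disease),
            lp.build_bipartite(ds.mir_disease),
            lp.build_bipartite(ds.lnc_mir),
        )
        # every retained lncRNA/miRNA is incident to >=1 retained disease edge
        assert tri.A_ld.sum(axis=1).min() >= 1
        assert tri.A_md.sum(axis=1).min() >= 1
        # every retained edge participates in >=1 triangle
        t = tri.triangle_tensor()
        assert np.array_equal(tri.A_ld.astype(bool), t.any(axis=1))
        assert np.array_equal(tri.A_md.astype(bool), t.any(axis=0))
        assert np.array_equal(tri.A_lm.astype(bool), t.any(axis=2))


class TestDiseaseLMPairNetwork:
    def _tri(self, ld, md, lm):
        return lp.build_tripartite(
            lp.build_bipartite(_table(ld, KIND_LNC_DISEASE)),
            lp.build_bipartite(_table(md, KIND_MIR_DISEASE)),
            lp.build_bipartite(_table(lm, KIND_LNC_MIR)),
        )

    def test_minimal_network(self):
        net = lp.build_disease_lmpair_network(
            self._tri([("l1", "d1")], [("m1", "d1")], [("l1", "m1")])
        )
        assert net.n_pairs == 1 and net.n_diseases == 1
        assert net.DP.tolist() == [[1]]

    def test_full_cross_product_with_partial_triangles(self):
        # l2 survives via a (d1, l2, m1)-free path? No: l2 only forms a
        # triangle if all three of its edges exist; give it a disease edge and
        # an interaction so exactly one extra triangle-less pair is enumerated.
        tri = self._tri(
            [("l1", "d1"), ("l2", "d1")],
            [("m1", "d1")],
            [("l1", "m1"), ("l2", "m1")],
        )
        net = lp.build_disease_lmpair_network(tri)
        assert net.DP.shape == (2, 1)
        assert int(net.DP.sum()) == 2

    def test_row_major_pair_indexing(self, default_model):
        net = default_model.network
        n_m = len(net.mir_ids)
        for i in (0, 1, len(net.lnc_ids) - 1):
            for j in (0, n_m - 1):
                assert net.pair_ids[i * n_m + j] == (net.lnc_ids[i], net.mir_ids[j])

    def test_dp_sums_match_brute_force_triangle_counts(self):
        rng = np.random.default_rng(5)
        from conftest import triangles_brute_force

        for _ in range(3):
            ld = [(f"l{i}", f"d{k}") for i in range(6) for k in range(5) if rng.random() < 0.4]
            md = [(f"m{j}", f"d{k}") for j in range(6) for k in range(5) if rng.random() < 0.4]
            lm = [(f"l{i}", f"m{j}") for i in range(6) for j in range(6) if rng.random() < 0.4]
            expected = triangles_brute_force(ld, md, lm)
            if not expected:
                continue
            net = lp.build_disease_lmpair_network(self._tri(ld, md, lm))
            # per-disease counts
            per_disease = {d: 0 for d in net.disease_ids}
            for d, _, _ in expected:
                per_disease[d] += 1
            assert [per_disease[d] for d in net.disease_ids] == net.DP.sum(axis=0).tolist()
            assert int(net.DP.sum()) == len(expected)

    def test_interacting_pairs_mode_keeps_all_known_edges(self, default_dataset):
        ds = default_dataset
        tri = self._tri(list(ds.lnc_disease.edges), list(ds.mir_disease.edges), list(ds.lnc_mir.edges))
        full = lp.build_disease_lmpair_network(tri, pairs="full")
        restricted = lp.build_disease_lmpair_network(tri, pairs="interacting")
        assert restricted.n_pairs < full.n_pairs
        assert restricted.DP.sum() == full.DP.sum()

    def test_size_guard(self):
        tri = self._tri([("l1", "d1")], [("m1", "d1")], [("l1", "m1")])
        with pytest.raises(ValueError, match="interacting"):
            lp.build_disease_lmpair_network(tri, max_pairs=0)

    def test_deterministic_rebuild(self, default_dataset):
        ds = default_dataset
        nets = [
            lp.build_disease_lmpair_network(
                self._tri(list(ds.lnc_disease.edges), list(ds.mir_disease.edges), list(ds.lnc_mir.edges))
            )
            for _ in range(2)
        ]
        assert nets[0].pair_ids == nets[1].pair_ids
        assert np.array_equal(nets[0].DP, nets[1].DP)
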