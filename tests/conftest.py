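"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import lmpairnet as lp


@pytest.fixture(scope="session")
def default_dataset() -> lp.SyntheticDataset:
    return lp.generate(lp.SyntheticConfig())


@pytest.fixture(scope="session")
def default_model(default_dataset) -> lp.PreparedModel:
    ds = default_dataset
    return lp.prepare_model(ds.lnc_disease, ds.mir_disease, ds.lnc_mir, ds.dag)


@pytest.fixture(scope="session")
def small_model() -> lp.PreparedModel:
    """A faster, smaller planted dataset for protocol-level tests."""
    cfg = lp.SyntheticConfig(n_diseases=12, n_lncRNAs=14, n_miRNAs=13, n_communities=2, seed=7)
    ds = lp.generate(cfg)
    return lp.prepare_model(ds.lnc_disease, ds.mir_disease, ds.lnc_mir, ds.dag)


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; never share code with the
# implementation paths they check).


def dense_power_s12(P: np.ndarray, B: np.ndarray, D: np.ndarray, gamma: float, K: int) -> np.ndarray:
    """Accumulate gamma^l * M^l on the explicit block matrix and slice (1,2)."""
    M = np.block([[P, B], [B.T, D]])
    n_p = B.shape[0]
    acc = np.zeros_like(M)
    Ml = np.eye(M.shape[0])
    for _ in range(K):
        Ml = Ml @ M
        acc = acc + gamma ** (_ + 1) * Ml
    return acc[:n_p, n_p:]


def gip_loop(Y: np.ndarray) -> np.ndarray:
    """Literal double-loop Gaussian interaction-profile kernel over columns."""
    n = Y.shape[1]
    norms = [float(np.dot(Y[:, i], Y[:, i])) for i in range(n)]
    gamma = 1.0 / (sum(norms) / n)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = Y[:, i] - Y[:, j]
            out[i, j] = np.exp(-gamma * float(np.dot(diff, diff)))
    np.fill_diagonal(out, 1.0)
    return out


def funsim_loop(sets_a: list[list[int]], S: np.ndarray) -> np.ndarray:
    """Literal best-match-average functional similarity over index sets."""
    n = len(sets_a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            A, B = sets_a[i], sets_a[j]
            if not A or not B:
                out[i, j] = 0.0
                continue
            s1 = sum(max(S[a, b] for b in B) for a in A)
            s2 = sum(max(S[b, a] for a in A) for b in B)
            out[i, j] = (s1 + s2) / (len(A) + len(B))
    return out


def pair_sim_loop(L: np.ndarray, M: np.ndarray, method: str) -> np.ndarray:
    """Four-index loop over row-major (lncRNA, miRNA) pairs."""
    n_l, n_m = L.shape[0], M.shape[0]
    n_p = n_l * n_m
    out = np.empty((n_p, n_p))
    avg_l, avg_m = L.mean(), M.mean()
    for i in range(n_l):
        for j in range(n_m):
            for a in range(n_l):
                for b in range(n_m):
                    p, q = i * n_m + j, a * n_m + b
                    if method == "average":
                        out[p, q] = (L[i, a] + M[j, b]) / 2.0
                    elif method == "sqrt":
                        out[p, q] = np.sqrt(L[i, a] * M[j, b])
                    else:
                        out[p, q] = np.sqrt((L[i, a] - avg_l) ** 2 + (M[j, b] - avg_m) ** 2)
    return out


def triangles_brute_force(edges_ld, edges_md, edges_lm):
    """Enumerate all (d, l, m) triangles by scanning every triple."""
    lncs = {l for l, _ in edges_ld} | {l for l, _ in edges_lm}
    mirs = {m for m, _ in edges_md} | {m for _, m in edges_lm}
    dis = {d for _, d in edges_ld} | {d for _, d in edges_md}
    ld, md, lm = set(edges_ld), set(edges_md), set(edges_lm)
    return {
        (d, l, m)
        for d in dis
        for l in lncs
        for m in mirs
        if (l, d) in ld and (m, d) in md and (l, m) in lm
    }


def auc_pairwise(pos, neg) -> float:
    """O(P*N) pairwise Mann-Whitney AUC."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_dag(rng: np.random.Generator, n_nodes: int, extra_parent_p: float = 0.3):
    """Random acyclic hierarchy: each node attaches to earlier nodes."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parent = nodes[rng.integers(i)]
        edges.append((nodes[i], parent))
        if i > 1 and rng.random() < extra_parent_p:
            other = nodes[rng.integers(i)]
            if other != parent:
                edges.append((nodes[i], other))
    return lp.DiseaseDAG(tuple(nodes), tuple(dict.fromkeys(edges)))


def semantic_contribution_paths(dag, disease: str, ancestor: str, delta: float) -> float:
    """Max over all upward paths of delta^len — the max-over-paths oracle."""
    import networkx as nx

    if ancestor == disease:
        return 1.0
    best = 0.0
    for path in nx.all_simple_paths(dag.graph, disease, ancestor):
        best = max(best, delta ** (len(path) - 1))
    return best
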