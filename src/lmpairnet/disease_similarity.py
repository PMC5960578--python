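"""Disease similarity layers.

Three measures are combined:

* **Semantic similarity** over a MeSH-style hierarchy.  Each disease ``D``
  induces a profile over ``T(D)`` (itself plus ancestors); the contribution of
  an ancestor ``t`` decays with hierarchy distance via the recursion
  ``C_D(D) = 1`` and ``C_D(t) = max{delta * C_D(c) : c child of t, c in T(D)}``
  with decay factor ``delta in (0, 1)`` (default 0.5).  Two diseases are
  similar in proportion to the mass of their shared ancestors:

  ``SemSim(di, dj) = sum_{t in T(di) ∩ T(dj)} (C_di(t) + C_dj(t)) / (DV(di) + DV(dj))``

  where ``DV(D) = sum_t C_D(t)``.

* **Gaussian interaction-profile (GIP) kernel** similarity on the binary
  association profiles, with bandwidth normalized by the mean squared profile
  norm.  The disease-side kernel is computed on both the lncRNA–disease and the
  miRNA–disease layer and the two are combined by a geometric mean.

* **Integrated similarity**: the arithmetic mean of semantic and GIP values,
  falling back to the GIP value alone where the two diseases share no ancestor
  (semantic similarity exactly zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import DiseaseDAG
from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.5

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class SimilarityMatrix:
    """A labeled symmetric nonnegative similarity matrix."""

    ids: tuple[str, ...] | tuple[tuple[str, str], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.isfinite(vals).all():
            raise ValueError("similarity matrix contains nonfinite entries")
        if (vals < 0).any():
            raise ValueError("similarity matrix contains negative entries")
        if np.abs(vals - vals.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, key) -> float:
        i, j = key
        if isinstance(i, str) or isinstance(i, tuple):
            idx = {v: k for k, v in enumerate(self.ids)}
            i, j = idx[i], idx[j]
        return float(self.values[i, j])


@dataclass(frozen=True)
class SemanticProfile:
    """Ancestor contributions to one disease's semantic value."""

    disease_id: str
    contributions: dict[str, float]
    semantic_value: float


def semantic_profile(dag: DiseaseDAG, disease: str, delta: float = DEFAULT_DELTA) -> SemanticProfile:
    """Decayed ancestor-contribution profile of one disease.

    The disease contributes 1 to itself; each ancestor ``t`` contributes
    ``delta`` times the largest contribution among its children inside ``T(D)``,
    so contributions decay along the best (shortest, under a uniform decay)
    path back to the disease.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie strictly between 0 and 1")
    if disease not in dag:
        raise KeyError(f"unknown disease id {disease!r}")
    t_set = dag.ancestors(disease) | {disease}
    sub = dag.graph.subgraph(t_set)
    contributions: dict[str, float] = {disease: 1.0}
    # Child->parent edges: topological order yields children before parents, so
    # each node's contribution is final before it propagates upward.
    for node in nx.topological_sort(sub):
        c = contributions[node]
        for parent in sub.successors(node):
            cand = delta * c
            if cand > contributions.get(parent, 0.0):
                contributions[parent] = cand
    return SemanticProfile(disease, contributions, float(sum(contributions.values())))


def semantic_similarity(
    dag: DiseaseDAG, di: str, dj: str, delta: float = DEFAULT_DELTA
) -> float:
    """Shared-ancestor semantic similarity in [0, 1]."""
    pi = semantic_profile(dag, di, delta)
    pj = semantic_profile(dag, dj, delta)
    return _profile_similarity(pi, pj)


def _profile_similarity(pi: SemanticProfile, pj: SemanticProfile) -> float:
    common = pi.contributions.keys() & pj.contributions.keys()
    if not common:
        return 0.0
    num = sum(pi.contributions[t] + pj.contributions[t] for t in common)
    return num / (pi.semantic_value + pj.semantic_value)


def semantic_similarity_matrix(
    dag: DiseaseDAG,
    diseases: tuple[str, ...],
    delta: float = DEFAULT_DELTA,
    on_missing: str = "warn",
) -> SimilarityMatrix:
    """Pairwise semantic similarity for an ordered disease list.

    Diseases absent from the DAG are treated as isolated terms (profile
    ``{self: 1}``), so their semantic similarity to every other disease is 0
    and the integrated similarity falls back to the GIP branch.
    """
    profiles: list[SemanticProfile] = []
    for d in diseases:
        if d in dag:
            profiles.append(semantic_profile(dag, d, delta))
        else:
            if on_missing == "error":
                raise KeyError(f"disease {d!r} missing from DAG")
            logger.warning("disease %r missing from DAG; semantic similarity falls to 0", d)
            profiles.append(SemanticProfile(d, {d: 1.0}, 1.0))
    n = len(diseases)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = _profile_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(tuple(diseases), vals)


def gip_kernel(profile_matrix: np.ndarray) -> np.ndarray:
    """Gaussian interaction-profile kernel over the *columns* of a binary matrix.

    The bandwidth is ``gamma = 1 / mean_i ||IP_i||^2`` over the n profiles;
    ``sim(i, j) = exp(-gamma * ||IP_i - IP_j||^2)`` with an exact unit diagonal.
    Raises on an all-zero matrix, for which the bandwidth is undefined.
    """
    Y = np.asarray(profile_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("profile matrix must be 2-D with at least one column")
    sq_norms = (Y * Y).sum(axis=0)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ValueError("empty interaction profiles: all-zero matrix")
    gamma = 1.0 / mean_sq
    gram = Y.T @ Y
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    d2 = 0.5 * (d2 + d2.T)
    sim = np.exp(-gamma * d2)
    np.fill_diagonal(sim, 1.0)
    return sim


def disease_gip_similarity(
    g1: BipartiteNetwork,
    g2: BipartiteNetwork,
    diseases: tuple[str, ...],
    lnc_rows: tuple[str, ...] | None = None,
    mir_rows: tuple[str, ...] | None = None,
) -> SimilarityMatrix:
    """Geometric-mean GIP similarity for diseases from both association layers.

    Disease profiles are columns of the lncRNA–disease and miRNA–disease
    adjacencies restricted to ``diseases``.  ``lnc_rows``/``mir_rows`` restrict
    the profile rows (the triangle-surviving gene sets by default upstream);
    ``None`` keeps all genes of the corresponding network.
    """
    y1 = _profile_columns(g1, diseases, lnc_rows)
    y2 = _profile_columns(g2, diseases, mir_rows)
    sim = np.sqrt(gip_kernel(y1) * gip_kernel(y2))
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(tuple(diseases), sim)


def _profile_columns(
    net: BipartiteNetwork, diseases: tuple[str, ...], rows: tuple[str, ...] | None
) -> np.ndarray:
    ridx = net.right_index()
    missing = [d for d in diseases if d not in ridx]
    if missing:
        raise KeyError(f"disease(s) absent from network: {missing[:5]!r}")
    cols = [ridx[d] for d in diseases]
    if rows is None:
        return net.adjacency[:, cols].astype(float)
    lidx = net.left_index()
    missing_rows = [g for g in rows if g not in lidx]
    if missing_rows:
        raise KeyError(f"gene(s) absent from network: {missing_rows[:5]!r}")
    return net.adjacency[np.ix_([lidx[g] for g in rows], cols)].astype(float)


def integrated_disease_similarity(
    sem: SimilarityMatrix, gip: SimilarityMatrix
) -> SimilarityMatrix:
    """Average semantic and GIP similarity; GIP alone where semantic is exactly 0."""
    if sem.ids != gip.ids:
        raise ValueError("semantic and GIP similarity id orderings differ")
    out = np.where(sem.values == 0.0, gip.values, 0.5 * (sem.values + gip.values))
    return SimilarityMatrix(sem.ids, out)
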