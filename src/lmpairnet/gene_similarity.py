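"""Gene-side and pair-level similarity layers.

lncRNAs and miRNAs each get a functional similarity (best-match average of
semantic similarities between their associated disease sets) and a GIP kernel
similarity on their association profiles; the two are averaged entrywise into
the integrated gene similarity.

Composite (lncRNA, miRNA) pair similarity combines the two gene similarities
with one of three schemes.  For pairs ``p = (l_i, m_j)`` and ``q = (l_a, m_b)``:

* ``average`` — ``(lncSim[i, a] + miRSim[j, b]) / 2``
* ``sqrt``    — ``sqrt(lncSim[i, a] * miRSim[j, b])``
* ``centre``  — ``sqrt((lncSim[i, a] - mean(lncSim))^2 + (miRSim[j, b] - mean(miRSim))^2)``
  where the means are grand means over all matrix entries (diagonal included).
  This is a distance used verbatim as a similarity; it is kept uninverted.

With pairs enumerated row-major over (lncRNA, then miRNA), the average scheme is
``(lncSim ⊗ J + J ⊗ miRSim) / 2`` and the sqrt scheme ``sqrt(lncSim) ⊗ sqrt(miRSim)``
(``⊗`` Kronecker, ``J`` all-ones), which admits products with the pair × disease
adjacency without materializing the pair × pair matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .disease_similarity import SimilarityMatrix
from .network import BipartiteNetwork
from .disease_similarity import gip_kernel

logger = logging.getLogger(__name__)

PAIR_METHODS = ("average", "sqrt", "centre")

# Above this many pairs the average/sqrt schemes switch to the structured
# (Kronecker) representation instead of materializing the dense pair matrix.
DEFAULT_DENSE_PAIR_LIMIT = 4096


def gene_disease_sets(
    net: BipartiteNetwork,
    genes: tuple[str, ...],
    diseases: tuple[str, ...],
) -> dict[str, frozenset[str]]:
    """Disease partner sets per gene, restricted to the given disease universe."""
    lidx = net.left_index()
    ridx = net.right_index()
    cols = np.array([ridx[d] for d in diseases if d in ridx], dtype=int)
    kept = [d for d in diseases if d in ridx]
    out: dict[str, frozenset[str]] = {}
    for g in genes:
        if g not in lidx:
            out[g] = frozenset()
            continue
        row = net.adjacency[lidx[g], cols]
        out[g] = frozenset(kept[i] for i in np.nonzero(row)[0])
    return out


def functional_similarity(
    genes: tuple[str, ...],
    disease_sets: dict[str, frozenset[str]],
    dis_sem: SimilarityMatrix,
    warn_empty: bool = True,
) -> SimilarityMatrix:
    """Best-match-average functional similarity between genes.

    For genes with disease sets ``DT1`` (size m) and ``DT2`` (size n), each
    disease is matched to its most semantically similar partner on the other
    side and the matches are averaged:

    ``FunSim = (sum_p max_l S(dt1_p, dt2_l) + sum_q max_p S(dt2_q, dt1_p)) / (m + n)``

    A gene with an empty disease set gets similarity 0 to every other gene
    (self-similarity kept at 1).
    """
    didx = {d: i for i, d in enumerate(dis_sem.ids)}
    sets_idx: list[np.ndarray] = []
    for g in genes:
        ds = disease_sets.get(g, frozenset())
        unknown = [d for d in ds if d not in didx]
        if unknown:
            raise KeyError(f"disease(s) not in semantic similarity matrix: {unknown[:5]!r}")
        if not ds and warn_empty:
            logger.warning("gene %r has no associated diseases; functional similarity set to 0", g)
        sets_idx.append(np.array(sorted(didx[d] for d in ds), dtype=int))
    n = len(genes)
    S = dis_sem.values
    vals = np.eye(n)
    for i in range(n):
        a = sets_idx[i]
        if a.size == 0:
            continue
        for j in range(i + 1, n):
            b = sets_idx[j]
            if b.size == 0:
                continue
            block = S[np.ix_(a, b)]
            vals[i, j] = vals[j, i] = (
                block.max(axis=1).sum() + block.max(axis=0).sum()
            ) / (a.size + b.size)
    return SimilarityMatrix(tuple(genes), vals)


def gene_gip_similarity(profile_matrix: np.ndarray) -> np.ndarray:
    """GIP kernel over gene *rows* of a binary association matrix."""
    Y = np.asarray(profile_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError("profile matrix must be 2-D with at least one row")
    return gip_kernel(Y.T)


def integrated_gene_similarity(fun: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Unconditional entrywise average of functional and GIP similarity."""
    if fun.ids != gip.ids:
        raise ValueError("functional and GIP similarity id orderings differ")
    return SimilarityMatrix(fun.ids, 0.5 * (fun.values + gip.values))


@dataclass
class PairSimilarity:
    """Similarity between composite (lncRNA, miRNA) pairs.

    Holds the two gene similarity matrices and the combination method; the
    dense pair × pair matrix is materialized only when small enough (always,
    for the centre method, which has no Kronecker structure).  ``matmul``
    evaluates ``PairSim @ X`` either way, so the KATZ scorer never needs the
    dense matrix for the structured schemes.
    """

    method: str
    lnc_sim: np.ndarray
    mir_sim: np.ndarray
    pair_ids: tuple[tuple[str, str], ...]
    dense: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_lnc(self) -> int:
        return self.lnc_sim.shape[0]

    @property
    def n_mir(self) -> int:
        return self.mir_sim.shape[0]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def values(self) -> np.ndarray:
        """Dense pair × pair similarity matrix (materializing it if needed)."""
        if self.dense is None:
            self.dense = _dense_pair_matrix(self.method, self.lnc_sim, self.mir_sim)
        return self.dense

    def matmul(self, X: np.ndarray) -> np.ndarray:
        """``PairSim @ X`` for an ``n_pairs × k`` matrix ``X``."""
        if self.dense is not None:
            return self.dense @ X
        n_l, n_m = self.n_lnc, self.n_mir
        Xr = X.reshape(n_l, n_m, -1)
        if self.method == "average":
            # (L ⊗ J) @ X : contract lncRNA side, broadcast over miRNA slots.
            left = np.einsum("ia,abk->ibk", self.lnc_sim, Xr.sum(axis=1, keepdims=True))
            right = np.einsum("jb,abk->ajk", self.mir_sim, Xr.sum(axis=0, keepdims=True))
            out = 0.5 * (np.broadcast_to(left, (n_l, n_m, Xr.shape[2])) +
                         np.broadcast_to(right, (n_l, n_m, Xr.shape[2])))
            return out.reshape(self.n_pairs, -1)
        if self.method == "sqrt":
            sl, sm = np.sqrt(self.lnc_sim), np.sqrt(self.mir_sim)
            out = np.einsum("ia,jb,abk->ijk", sl, sm, Xr, optimize=True)
            return out.reshape(self.n_pairs, -1)
        raise ValueError(
            "centre pair similarity has no structured form; materialize values() first"
        )


def _dense_pair_matrix(method: str, lnc_sim: np.ndarray, mir_sim: np.ndarray) -> np.ndarray:
    n_l, n_m = lnc_sim.shape[0], mir_sim.shape[0]
    J_l, J_m = np.ones((n_l, n_l)), np.ones((n_m, n_m))
    if method == "average":
        return 0.5 * (np.kron(lnc_sim, J_m) + np.kron(J_l, mir_sim))
    if method == "sqrt":
        return np.kron(np.sqrt(lnc_sim), np.sqrt(mir_sim))
    if method == "centre":
        avg_l = lnc_sim.mean()
        avg_m = mir_sim.mean()
        dl = np.kron(lnc_sim - avg_l, J_m)
        dm = np.kron(J_l, mir_sim - avg_m)
        return np.sqrt(dl * dl + dm * dm)
    raise ValueError(f"unknown pair similarity method {method!r}")


def lmpair_similarity(
    lnc_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    pairs: tuple[tuple[str, str], ...] | None = None,
    method: str = "average",
    dense_limit: int = DEFAULT_DENSE_PAIR_LIMIT,
) -> PairSimilarity:
    """Build the pair similarity for the full row-major pair enumeration.

    ``pairs`` may be supplied for validation; it must equal the row-major cross
    product of the gene id lists (the structured evaluation depends on it).
    """
    if method not in PAIR_METHODS:
        raise ValueError(f"unknown pair similarity method {method!r}; choose from {PAIR_METHODS}")
    expected = tuple((l, m) for l in lnc_sim.ids for m in mir_sim.ids)
    if pairs is not None and tuple(pairs) != expected:
        raise ValueError("pair list is not the row-major (lncRNA, miRNA) cross product")
    ps = PairSimilarity(
        method=method,
        lnc_sim=lnc_sim.values,
        mir_sim=mir_sim.values,
        pair_ids=expected,
    )
    if method == "centre" or ps.n_pairs <= dense_limit:
        ps.values()
    return ps
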