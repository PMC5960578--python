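"""Truncated KATZ scoring on the disease–pair block matrix.

The pair similarity ``P`` (n_p × n_p), the binary disease–pair adjacency
``B = DP`` (n_p × n_d) and the disease similarity ``D`` (n_d × n_d) are
assembled into one symmetric block matrix

    M = [[P, B], [B^T, D]]

and candidate (pair, disease) links are scored by the damped walk count

    S = sum_{l=1..K} gamma^l * M^l ,    0 < gamma < 1 ,

of which only the upper-right ``n_p × n_d`` block ``S12`` is the prediction
matrix.  For K = 2, 3, 4 the block is expanded in closed form (the terms are
exactly the length-l block walks from the pair side to the disease side, e.g.
``S12(2) = gamma*B + gamma^2*(P@B + B@D)``); longer truncations iterate the
block recursion without forming ``M^l``.  The infinite-sum form
``(I - gamma*M)^{-1} - I`` is provided for validation when ``gamma`` is below
the spectral-radius bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gene_similarity import PairSimilarity
from .disease_similarity import SimilarityMatrix
from .io import PredictionRecord
from .network import DiseaseLMPairNetwork

DEFAULT_GAMMA = 0.01
DEFAULT_K = 2


@dataclass(frozen=True)
class KatzParams:
    """Damping factor and walk-length truncation of the KATZ measure."""

    gamma: float = DEFAULT_GAMMA
    K: int = DEFAULT_K

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie strictly between 0 and 1")
        if int(self.K) != self.K or self.K < 2:
            raise ValueError("K must be an integer >= 2")


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted association scores, pairs × diseases."""

    pair_ids: tuple[tuple[str, str], ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.pair_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.isfinite(vals).all():
            raise ValueError("score matrix contains nonfinite entries")
        object.__setattr__(self, "values", vals)


def _as_operator(pair_sim) -> PairSimilarity | None:
    return pair_sim if isinstance(pair_sim, PairSimilarity) else None


def _pair_matmul(pair_sim, X: np.ndarray) -> np.ndarray:
    ps = _as_operator(pair_sim)
    if ps is not None:
        return ps.matmul(X)
    return np.asarray(pair_sim, dtype=float) @ X


def _dis_values(dis_sim) -> np.ndarray:
    if isinstance(dis_sim, SimilarityMatrix):
        return dis_sim.values
    return np.asarray(dis_sim, dtype=float)


def assemble_dpstar(pair_sim, DP: np.ndarray, dis_sim) -> np.ndarray:
    """Dense (n_p + n_d) square block matrix [[PairSim, DP], [DP^T, DisSim]]."""
    P = pair_sim.values() if isinstance(pair_sim, PairSimilarity) else np.asarray(pair_sim, float)
    D = _dis_values(dis_sim)
    B = np.asarray(DP, dtype=float)
    if P.shape[0] != B.shape[0] or D.shape[0] != B.shape[1]:
        raise ValueError(
            f"block shapes not conformable: PairSim {P.shape}, DP {B.shape}, DisSim {D.shape}"
        )
    return np.block([[P, B], [B.T, D]])


def katz_s12(pair_sim, DP: np.ndarray, dis_sim, params: KatzParams) -> np.ndarray:
    """Raw truncated-KATZ prediction block as an ndarray."""
    B = np.asarray(DP, dtype=float)
    if not np.isfinite(B).all():
        raise ValueError("DP contains nonfinite entries")
    D = _dis_values(dis_sim)
    g = params.gamma

    if params.K <= 4:
        PB = _pair_matmul(pair_sim, B)
        BD = B @ D
        S = g * B + g * g * (PB + BD)
        if params.K >= 3:
            A = B.T @ B  # n_d × n_d
            D2 = D @ D
            PPB = _pair_matmul(pair_sim, PB)
            S = S + g**3 * (B @ A + PPB + _pair_matmul(pair_sim, BD) + B @ D2)
        if params.K >= 4:
            S = S + g**4 * (
                _pair_matmul(pair_sim, PPB)          # P^3 B
                + B @ (B.T @ PB)                      # B B^T P B
                + _pair_matmul(pair_sim, B @ A)       # P B B^T B
                + B @ (D @ A)                         # B D B^T B
                + B @ (A @ D)                         # B B^T B D
                + PPB @ D                             # P^2 B D
                + _pair_matmul(pair_sim, BD) @ D      # P B D^2
                + B @ (D2 @ D)                        # B D^3
            )
        return S

    # Generic truncation: iterate the right block-column of M^l.
    X12, X22 = B.copy(), D.copy()
    S = g * B
    for l in range(2, params.K + 1):
        X12, X22 = _pair_matmul(pair_sim, X12) + B @ X22, B.T @ X12 + D @ X22
        S = S + g**l * X12
    return S


def katz_score(
    pair_sim,
    DP: np.ndarray,
    dis_sim,
    params: KatzParams,
    pair_ids: Sequence[tuple[str, str]] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Truncated KATZ score matrix S12 with labels."""
    S = katz_s12(pair_sim, DP, dis_sim, params)
    if pair_ids is None:
        ps = _as_operator(pair_sim)
        pair_ids = ps.pair_ids if ps is not None else tuple(
            (f"l{i}", f"m{i}") for i in range(S.shape[0])
        )
    if disease_ids is None:
        disease_ids = (
            dis_sim.ids if isinstance(dis_sim, SimilarityMatrix)
            else tuple(f"d{j}" for j in range(S.shape[1]))
        )
    return ScoreMatrix(tuple(pair_ids), tuple(disease_ids), S)


def katz_score_closed_form(
    pair_sim, DP: np.ndarray, dis_sim, gamma: float = DEFAULT_GAMMA
) -> np.ndarray:
    """Infinite-sum KATZ block ``S12`` via ``(I - gamma*M)^{-1} - I``.

    Requires ``gamma * rho(M) < 1`` (rho the spectral radius); raises naming the
    admissible bound otherwise.  Intended for validation on modest sizes — it
    materializes and inverts the dense block matrix.
    """
    M = assemble_dpstar(pair_sim, DP, dis_sim)
    n_p = np.asarray(DP).shape[0]
    rho = float(np.max(np.abs(np.linalg.eigvals(M))))
    if gamma * rho >= 1.0:
        raise ValueError(
            f"KATZ series does not converge: gamma={gamma} but spectral radius {rho:.6g} "
            f"requires gamma < {1.0 / rho:.6g}"
        )
    n = M.shape[0]
    S = np.linalg.inv(np.eye(n) - gamma * M) - np.eye(n)
    return S[:n_p, n_p:]


def rank_predictions(
    scores: ScoreMatrix, known_edges: frozenset[tuple[int, int]] | set[tuple[int, int]]
) -> list[PredictionRecord]:
    """All (pair, disease) cells sorted by descending score.

    ``known_edges`` holds (disease index, pair index) training associations.
    Ties break deterministically by ascending (disease index, pair index).
    """
    S = scores.values
    n_p, n_d = S.shape
    p_idx, d_idx = np.meshgrid(np.arange(n_p), np.arange(n_d), indexing="ij")
    p_flat, d_flat = p_idx.ravel(), d_idx.ravel()
    flat = S.ravel()
    order = np.lexsort((p_flat, d_flat, -flat))
    known = known_edges if isinstance(known_edges, frozenset) else frozenset(known_edges)
    records: list[PredictionRecord] = []
    for rank, idx in enumerate(order, start=1):
        p, d = int(p_flat[idx]), int(d_flat[idx])
        l, m = scores.pair_ids[p]
        records.append(
            PredictionRecord(
                disease_id=scores.disease_ids[d],
                lncRNA_id=l,
                miRNA_id=m,
                score=float(flat[idx]),
                rank=rank,
                known=(d, p) in known,
            )
        )
    return records
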