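"""Cross-validated evaluation of the disease–pair predictor.

Known disease–pair associations are positives; every (pair, disease) cell with
no known association is a candidate (negative background).  In LOOCV each known
edge is masked from ``DP`` in turn, the score matrix is recomputed, and the
held-out score is converted to a percentile within its own fold's candidate
score distribution.  k-fold CV masks a random k-partition of the known edges
per fold and repeats the random division (100 times by default).  Percentiles
are pooled into one ROC; a fold-pooled AUC is their mean, which equals the
Mann–Whitney probability that a held-out association outranks a random
candidate.

Similarity matrices are held fixed across folds — only the disease–pair
adjacency is masked, mirroring a protocol in which the similarity layers derive
from the (unmasked) gene-level networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .katz import KatzParams, katz_s12, _pair_matmul
from .network import DiseaseLMPairNetwork


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings."""

    scheme: str = "kfold"
    k: int = 5
    repeats: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        if self.scheme not in ("loocv", "kfold"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class CVResult:
    """Per-repeat AUCs with pooled ROC points."""

    per_repeat_auc: tuple[float, ...]
    roc_points: tuple[tuple[float, float], ...]
    mean_auc: float = field(init=False)
    std_auc: float = field(init=False)

    def __post_init__(self) -> None:
        aucs = np.asarray(self.per_repeat_auc, dtype=float)
        object.__setattr__(self, "mean_auc", float(aucs.mean()))
        std = float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0
        object.__setattr__(self, "std_auc", std)


def roc_auc(
    positive_scores, negative_scores
) -> tuple[float, tuple[tuple[float, float], ...]]:
    """Tie-aware ROC/AUC by threshold sweep over the pooled scores.

    The AUC is the Mann–Whitney statistic ``P(pos > neg) + 0.5 * P(pos = neg)``
    computed from midranks, so ties contribute half weight exactly.
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    for t in thresholds:
        tpr.append((pos.size - np.searchsorted(pos_sorted, t, side="left")) / pos.size)
        fpr.append((neg.size - np.searchsorted(neg_sorted, t, side="left")) / neg.size)
    tpr.append(1.0)
    fpr.append(1.0)
    points = tuple(zip(fpr, tpr))
    return float(auc), points


def percentile_among(score: float, candidate_scores: np.ndarray) -> float:
    """Tie-aware percentile of one score within a candidate distribution."""
    less = np.count_nonzero(candidate_scores < score)
    equal = np.count_nonzero(candidate_scores == score)
    return (less + 0.5 * equal) / candidate_scores.size


class _KatzCVScorer:
    """Scores masked adjacencies, with an exact O(n_p + n_d) single-edge fast
    path for K = 2 (the masked score is the full score minus the masked entry's
    own walk contributions)."""

    def __init__(self, pair_sim, DP: np.ndarray, dis_sim, params: KatzParams):
        self.pair_sim = pair_sim
        self.DP = np.asarray(DP, dtype=float)
        self.dis_values = dis_sim.values if hasattr(dis_sim, "values") and not isinstance(
            dis_sim, np.ndarray
        ) else np.asarray(dis_sim, dtype=float)
        self.params = params
        self._base_s12: np.ndarray | None = None
        self._pair_cols: dict[int, np.ndarray] = {}

    def s12(self, DP_masked: np.ndarray) -> np.ndarray:
        return katz_s12(self.pair_sim, DP_masked, self.dis_values, self.params)

    def s12_single_masked(self, p: int, d: int) -> np.ndarray:
        """S12 with the single known edge (pair p, disease d) masked."""
        if self.params.K != 2:
            DPm = self.DP.copy()
            DPm[p, d] = 0.0
            return self.s12(DPm)
        if self._base_s12 is None:
            self._base_s12 = self.s12(self.DP)
        g = self.params.gamma
        S = self._base_s12.copy()
        # Removing DP[p,d] removes gamma*E_pd + gamma^2*(PairSim[:,p] e_d^T + e_p DisSim[d,:]).
        if p not in self._pair_cols:
            e = np.zeros((self.DP.shape[0], 1))
            e[p, 0] = 1.0
            self._pair_cols[p] = _pair_matmul(self.pair_sim, e).ravel()
        S[:, d] -= g * g * self._pair_cols[p]
        S[p, :] -= g * g * self.dis_values[d, :]
        S[p, d] -= g
        return S


def _percentiles_for_fold(
    S: np.ndarray, test_edges: np.ndarray, candidate_mask: np.ndarray
) -> list[float]:
    cand = S[candidate_mask]
    return [percentile_among(S[p, d], cand) for p, d in test_edges]


def _default_fold_scorer(network: DiseaseLMPairNetwork, pair_sim, dis_sim, params: KatzParams):
    scorer = _KatzCVScorer(pair_sim, network.DP, dis_sim, params)
    DP = network.DP.astype(float)

    def fold_scorer(test_edges: np.ndarray) -> np.ndarray:
        if test_edges.shape[0] == 1 and params.K == 2:
            p, d = test_edges[0]
            return scorer.s12_single_masked(int(p), int(d))
        DPm = DP.copy()
        DPm[test_edges[:, 0], test_edges[:, 1]] = 0.0
        return scorer.s12(DPm)

    return fold_scorer


def loocv(
    network: DiseaseLMPairNetwork,
    pair_sim,
    dis_sim,
    params: KatzParams,
    per_disease: bool = False,
    fold_scorer=None,
) -> CVResult:
    """Leave-one-out CV over the known disease–pair edges.

    Candidates are, globally, all cells without a known association (or, with
    ``per_disease``, the unknown cells of the held-out edge's disease column).
    ``fold_scorer`` overrides how a masked fold is scored (it receives the
    array of held-out (pair, disease) index rows and must return a full S12).
    """
    edges = np.argwhere(network.DP != 0)
    if edges.shape[0] < 2:
        raise ValueError("LOOCV needs at least 2 known edges")
    candidate_mask = network.DP == 0
    if fold_scorer is None:
        fold_scorer = _default_fold_scorer(network, pair_sim, dis_sim, params)
    pcts: list[float] = []
    for p, d in edges:
        S = fold_scorer(np.array([[p, d]]))
        if per_disease:
            cand = S[candidate_mask[:, d], d]
        else:
            cand = S[candidate_mask]
        pcts.append(percentile_among(S[p, d], cand))
    return _result_from_percentiles([pcts])


def kfold_cv(
    network: DiseaseLMPairNetwork,
    pair_sim,
    dis_sim,
    params: KatzParams,
    cv: CVConfig,
    fold_scorer=None,
) -> CVResult:
    """Repeated k-fold CV with random equal partitions of the known edges."""
    edges = np.argwhere(network.DP != 0)
    n_edges = edges.shape[0]
    if cv.scheme == "kfold" and cv.k > n_edges:
        raise ValueError(f"k={cv.k} exceeds the number of known edges ({n_edges})")
    candidate_mask = network.DP == 0
    if fold_scorer is None:
        fold_scorer = _default_fold_scorer(network, pair_sim, dis_sim, params)
    per_repeat: list[list[float]] = []
    for rep in range(cv.repeats):
        rng = np.random.default_rng(np.random.SeedSequence([cv.seed, rep]))
        perm = rng.permutation(n_edges)
        folds = np.array_split(perm, cv.k)
        pcts: list[float] = []
        for fold in folds:
            test = edges[fold]
            S = fold_scorer(test)
            pcts.extend(_percentiles_for_fold(S, test, candidate_mask))
        per_repeat.append(pcts)
    return _result_from_percentiles(per_repeat)


def _result_from_percentiles(per_repeat: list[list[float]]) -> CVResult:
    aucs = tuple(float(np.mean(p)) for p in per_repeat)
    pooled = np.concatenate([np.asarray(p) for p in per_repeat])
    # Percentiles of candidates against their own distribution are uniform; a
    # midpoint grid is the exact pooled negative background.
    n_grid = 1000
    grid = (np.arange(n_grid) + 0.5) / n_grid
    _, points = roc_auc(pooled, grid)
    return CVResult(per_repeat_auc=aucs, roc_points=points)
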