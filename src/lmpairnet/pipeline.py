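"""End-to-end orchestration: tables → networks → similarities → predictions.

``prepare_model`` performs every step up to (and including) the pair similarity;
``predict_associations`` runs the KATZ scorer on a prepared model and ranks all
candidate cells.  ``run_pipeline`` is the disk-facing wrapper used by the CLI:
it reads the input TSVs, writes the ranked predictions and a run log with full
parameter/seed/input provenance, and removes partial outputs on failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .disease_similarity import (
    SimilarityMatrix,
    disease_gip_similarity,
    integrated_disease_similarity,
    semantic_similarity_matrix,
)
from .evaluation import CVConfig, CVResult, kfold_cv, loocv
from .gene_similarity import (
    PairSimilarity,
    functional_similarity,
    gene_disease_sets,
    gene_gip_similarity,
    integrated_gene_similarity,
    lmpair_similarity,
)
from .io import (
    AssociationTable,
    DiseaseDAG,
    KIND_LNC_DISEASE,
    KIND_LNC_MIR,
    KIND_MIR_DISEASE,
    PredictionRecord,
    read_association_table,
    read_disease_dag,
    write_predictions,
)
from .katz import KatzParams, ScoreMatrix, katz_score, rank_predictions
from .network import (
    DEFAULT_MAX_PAIRS,
    BipartiteNetwork,
    DiseaseLMPairNetwork,
    TripartiteNetwork,
    build_bipartite,
    build_disease_lmpair_network,
    build_tripartite,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the end-to-end run."""

    delta: float = 0.5
    gamma: float = 0.01
    K: int = 2
    pair_method: str = "average"
    gip_scope: str = "restricted"
    funsim_base: str = "semantic"
    pairs_mode: str = "full"
    max_pairs: int = DEFAULT_MAX_PAIRS

    def __post_init__(self) -> None:
        if self.gip_scope not in ("restricted", "full"):
            raise ValueError("gip_scope must be 'restricted' or 'full'")
        if self.funsim_base not in ("semantic", "integrated"):
            raise ValueError("funsim_base must be 'semantic' or 'integrated'")


@dataclass(frozen=True)
class PreparedModel:
    """Networks and similarity layers ready for scoring."""

    g1: BipartiteNetwork
    g2: BipartiteNetwork
    g3: BipartiteNetwork
    tripartite: TripartiteNetwork
    network: DiseaseLMPairNetwork
    dis_sem: SimilarityMatrix
    dis_sim: SimilarityMatrix
    lnc_sim: SimilarityMatrix
    mir_sim: SimilarityMatrix
    pair_sim: PairSimilarity
    settings: dict = field(default_factory=dict)


def prepare_model(
    lnc_disease: AssociationTable,
    mir_disease: AssociationTable,
    lnc_mir: AssociationTable,
    dag: DiseaseDAG,
    delta: float = 0.5,
    pair_method: str = "average",
    gip_scope: str = "restricted",
    funsim_base: str = "semantic",
    pairs_mode: str = "full",
    max_pairs: int = DEFAULT_MAX_PAIRS,
) -> PreparedModel:
    """Build all networks and similarity layers from the three tables + DAG."""
    g1 = build_bipartite(lnc_disease)
    g2 = build_bipartite(mir_disease)
    g3 = build_bipartite(lnc_mir)
    tri = build_tripartite(g1, g2, g3)
    net = build_disease_lmpair_network(tri, pairs=pairs_mode, max_pairs=max_pairs)

    diseases = tri.disease_ids
    dis_sem = semantic_similarity_matrix(dag, diseases, delta=delta)
    lnc_rows = tri.lnc_ids if gip_scope == "restricted" else None
    mir_rows = tri.mir_ids if gip_scope == "restricted" else None
    dis_gip = disease_gip_similarity(g1, g2, diseases, lnc_rows=lnc_rows, mir_rows=mir_rows)
    dis_sim = integrated_disease_similarity(dis_sem, dis_gip)

    fun_base = dis_sem if funsim_base == "semantic" else dis_sim
    lnc_sets = gene_disease_sets(g1, tri.lnc_ids, diseases)
    mir_sets = gene_disease_sets(g2, tri.mir_ids, diseases)
    lnc_fun = functional_similarity(tri.lnc_ids, lnc_sets, fun_base)
    mir_fun = functional_similarity(tri.mir_ids, mir_sets, fun_base)

    y1 = _gene_profiles(g1, tri.lnc_ids, diseases, gip_scope)
    y2 = _gene_profiles(g2, tri.mir_ids, diseases, gip_scope)
    lnc_gip = SimilarityMatrix(tri.lnc_ids, gene_gip_similarity(y1))
    mir_gip = SimilarityMatrix(tri.mir_ids, gene_gip_similarity(y2))
    lnc_sim = integrated_gene_similarity(lnc_fun, lnc_gip)
    mir_sim = integrated_gene_similarity(mir_fun, mir_gip)

    pair_sim = lmpair_similarity(lnc_sim, mir_sim, method=pair_method)
    if pairs_mode != "full":
        # Structured/row-major identities only hold for the full cross product.
        pair_sim = _restrict_pair_sim(pair_sim, net)
    settings = {
        "delta": delta,
        "pair_method": pair_method,
        "gip_scope": gip_scope,
        "funsim_base": funsim_base,
        "pairs_mode": pairs_mode,
    }
    return PreparedModel(
        g1, g2, g3, tri, net, dis_sem, dis_sim, lnc_sim, mir_sim, pair_sim, settings
    )


def _gene_profiles(net: BipartiteNetwork, genes, diseases, gip_scope: str):
    lidx = net.left_index()
    rows = [lidx[g] for g in genes]
    if gip_scope == "restricted":
        ridx = net.right_index()
        cols = [ridx[d] for d in diseases]
        return net.adjacency[np.ix_(rows, cols)].astype(float)
    return net.adjacency[rows, :].astype(float)


def _restrict_pair_sim(pair_sim: PairSimilarity, net: DiseaseLMPairNetwork) -> PairSimilarity:
    full_index = {p: i for i, p in enumerate(pair_sim.pair_ids)}
    keep = np.array([full_index[p] for p in net.pair_ids], dtype=int)
    dense = pair_sim.values()[np.ix_(keep, keep)]
    return PairSimilarity(
        method=pair_sim.method,
        lnc_sim=pair_sim.lnc_sim,
        mir_sim=pair_sim.mir_sim,
        pair_ids=net.pair_ids,
        dense=dense,
    )


def predict_associations(
    model: PreparedModel, params: KatzParams | None = None
) -> tuple[ScoreMatrix, list[PredictionRecord]]:
    """Score every (pair, disease) cell and rank them."""
    params = params or KatzParams()
    scores = katz_score(
        model.pair_sim,
        model.network.DP,
        model.dis_sim,
        params,
        pair_ids=model.network.pair_ids,
        disease_ids=model.network.disease_ids,
    )
    return scores, rank_predictions(scores, model.network.known_edges)


def cross_validate(
    model: PreparedModel,
    params: KatzParams,
    cv: CVConfig,
    per_disease: bool = False,
    strict_masking: bool = False,
) -> CVResult:
    """Cross-validate a prepared model.

    By default only the disease–pair adjacency is masked per fold and the
    similarity layers stay fixed.  With ``strict_masking`` each fold also
    removes the held-out triangles' disease–gene edges from the two gene-level
    association networks and recomputes every similarity layer, closing the
    information path from held-out edges into the similarities (slower).
    """
    fold_scorer = _strict_fold_scorer(model, params) if strict_masking else None
    if cv.scheme == "loocv":
        return loocv(
            model.network, model.pair_sim, model.dis_sim, params,
            per_disease=per_disease, fold_scorer=fold_scorer,
        )
    return kfold_cv(model.network, model.pair_sim, model.dis_sim, params, cv,
                    fold_scorer=fold_scorer)


def _strict_fold_scorer(model: PreparedModel, params: KatzParams):
    """Per-fold scorer that rebuilds the similarity layers from masked networks."""
    from .katz import katz_s12

    tri = model.tripartite
    net = model.network
    s = model.settings
    g1_lidx = model.g1.left_index()
    g1_ridx = model.g1.right_index()
    g2_lidx = model.g2.left_index()
    g2_ridx = model.g2.right_index()
    DP = net.DP.astype(float)

    def fold_scorer(test_edges: np.ndarray) -> np.ndarray:
        a1 = model.g1.adjacency.copy()
        a2 = model.g2.adjacency.copy()
        for p, d in test_edges:
            l, m = net.pair_ids[int(p)]
            dis = net.disease_ids[int(d)]
            a1[g1_lidx[l], g1_ridx[dis]] = 0
            a2[g2_lidx[m], g2_ridx[dis]] = 0
        g1m = BipartiteNetwork(model.g1.left_ids, model.g1.right_ids, a1)
        g2m = BipartiteNetwork(model.g2.left_ids, model.g2.right_ids, a2)

        diseases = tri.disease_ids
        lnc_rows = tri.lnc_ids if s.get("gip_scope", "restricted") == "restricted" else None
        mir_rows = tri.mir_ids if s.get("gip_scope", "restricted") == "restricted" else None
        dis_gip = disease_gip_similarity(g1m, g2m, diseases, lnc_rows=lnc_rows, mir_rows=mir_rows)
        dis_sim = integrated_disease_similarity(model.dis_sem, dis_gip)
        fun_base = model.dis_sem if s.get("funsim_base", "semantic") == "semantic" else dis_sim
        lnc_fun = functional_similarity(
            tri.lnc_ids, gene_disease_sets(g1m, tri.lnc_ids, diseases), fun_base,
            warn_empty=False,
        )
        mir_fun = functional_similarity(
            tri.mir_ids, gene_disease_sets(g2m, tri.mir_ids, diseases), fun_base,
            warn_empty=False,
        )
        y1 = _gene_profiles(g1m, tri.lnc_ids, diseases, s.get("gip_scope", "restricted"))
        y2 = _gene_profiles(g2m, tri.mir_ids, diseases, s.get("gip_scope", "restricted"))
        lnc_sim = integrated_gene_similarity(
            lnc_fun, SimilarityMatrix(tri.lnc_ids, gene_gip_similarity(y1))
        )
        mir_sim = integrated_gene_similarity(
            mir_fun, SimilarityMatrix(tri.mir_ids, gene_gip_similarity(y2))
        )
        pair_sim = lmpair_similarity(lnc_sim, mir_sim, method=s.get("pair_method", "average"))
        if s.get("pairs_mode", "full") != "full":
            pair_sim = _restrict_pair_sim(pair_sim, net)
        DPm = DP.copy()
        DPm[test_edges[:, 0], test_edges[:, 1]] = 0.0
        return katz_s12(pair_sim, DPm, dis_sim, params)

    return fold_scorer


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunPaths:
    lnc_disease: Path
    mir_disease: Path
    lnc_mir: Path
    dag: Path


def load_inputs(paths: RunPaths) -> tuple[AssociationTable, AssociationTable, AssociationTable, DiseaseDAG]:
    for name, p in asdict(paths).items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing {name} input file: {p}")
    return (
        read_association_table(paths.lnc_disease, KIND_LNC_DISEASE),
        read_association_table(paths.mir_disease, KIND_MIR_DISEASE),
        read_association_table(paths.lnc_mir, KIND_LNC_MIR),
        read_disease_dag(paths.dag),
    )


def run_pipeline(
    paths: RunPaths,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    cv: CVConfig | None = None,
) -> dict:
    """Full disk-to-disk run: predictions TSV, optional CV summary, run log.

    Returns a summary dict (also written as ``run_log.json``).  Partial outputs
    are removed if any stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        tables = load_inputs(paths)
        model = prepare_model(
            *tables,
            delta=config.delta,
            pair_method=config.pair_method,
            gip_scope=config.gip_scope,
            funsim_base=config.funsim_base,
            pairs_mode=config.pairs_mode,
            max_pairs=config.max_pairs,
        )
        params = KatzParams(gamma=config.gamma, K=config.K)
        _, records = predict_associations(model, params)
        pred_path = out / "predictions.tsv"
        write_predictions(records, pred_path)
        written.append(pred_path)

        summary: dict = {
            "parameters": {
                "delta": config.delta,
                "gamma": config.gamma,
                "K": config.K,
                "pair_method": config.pair_method,
                "gip_scope": config.gip_scope,
                "funsim_base": config.funsim_base,
                "pairs_mode": config.pairs_mode,
            },
            "inputs": {name: _sha256(Path(p)) for name, p in asdict(paths).items()},
            "network": {
                "n_diseases": model.network.n_diseases,
                "n_pairs": model.network.n_pairs,
                "n_known_edges": model.network.n_known,
            },
        }
        if cv is not None:
            result = cross_validate(model, params, cv)
            cv_path = out / "cv_results.tsv"
            with open(cv_path, "w", encoding="utf-8") as fh:
                fh.write("repeat\tauc\n")
                for i, auc in enumerate(result.per_repeat_auc):
                    fh.write(f"{i}\t{auc:.6f}\n")
            written.append(cv_path)
            roc_path = out / "roc_points.tsv"
            with open(roc_path, "w", encoding="utf-8") as fh:
                fh.write("fpr\ttpr\n")
                for fpr, tpr in result.roc_points:
                    fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
            written.append(roc_path)
            summary["cv"] = {
                "scheme": cv.scheme,
                "k": cv.k,
                "repeats": cv.repeats,
                "seed": cv.seed,
                "mean_auc": result.mean_auc,
                "std_auc": result.std_auc,
            }
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(log_path)
        return summary
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
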