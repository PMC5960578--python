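"""Synthetic association data with planted community structure.

The generator emulates the shape of curated lncRNA–disease, miRNA–disease and
lncRNA–miRNA association tables plus a MeSH-style disease hierarchy, without
matching any real database's marginals.  Diseases, lncRNAs and miRNAs are
partitioned into communities; association edges are drawn independently with a
higher probability inside the matched community than across communities, so
(disease, lncRNA, miRNA) triangles concentrate within communities and the
resulting disease–pair associations carry recoverable block structure.  The
disease DAG is a rooted tree whose subtrees align with the disease communities,
so semantic similarity correlates with community membership (a ``random`` DAG
mode decouples them for ablation).

Defaults (30 diseases, 40 lncRNAs, 35 miRNAs, 3 communities, within/between
association probabilities 0.5/0.05, interaction probabilities 0.6/0.05) yield
hundreds of triangles and end-to-end runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import (
    KIND_LNC_DISEASE,
    KIND_LNC_MIR,
    KIND_MIR_DISEASE,
    AssociationTable,
    DiseaseDAG,
    association_table_from_edges,
    disease_dag_from_edges,
    write_association_table,
    write_disease_dag,
)

_MAX_RETRIES = 20


@dataclass(frozen=True)
class SyntheticConfig:
    """Sizes, planted-structure strengths and seed of a generated dataset."""

    n_diseases: int = 30
    n_lncRNAs: int = 40
    n_miRNAs: int = 35
    n_communities: int = 3
    p_within: float = 0.5
    p_between: float = 0.05
    p_lm_within: float = 0.6
    p_lm_between: float = 0.05
    dag_branching: int = 3
    dag_mode: str = "community"
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_lncRNAs, self.n_miRNAs, self.n_communities) < 1:
            raise ValueError("entity and community counts must be positive")
        if self.n_communities > min(self.n_diseases, self.n_lncRNAs, self.n_miRNAs):
            raise ValueError("more communities than entities of some class")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between <= p_within <= 1")
        if not (0.0 <= self.p_lm_between <= self.p_lm_within <= 1.0):
            raise ValueError("need 0 <= p_lm_between <= p_lm_within <= 1")
        if self.dag_branching < 1:
            raise ValueError("dag_branching must be >= 1")
        if self.dag_mode not in ("community", "random"):
            raise ValueError("dag_mode must be 'community' or 'random'")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated association tables, disease DAG and ground-truth communities."""

    lnc_disease: AssociationTable
    mir_disease: AssociationTable
    lnc_mir: AssociationTable
    dag: DiseaseDAG
    disease_communities: dict[str, int]
    lnc_communities: dict[str, int]
    mir_communities: dict[str, int]
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize the dataset as plain TSV files; returns the paths written."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "lnc_disease": out / "lncRNA_disease.tsv",
            "mir_disease": out / "miRNA_disease.tsv",
            "lnc_mir": out / "lncRNA_miRNA.tsv",
            "dag": out / "disease_dag.tsv",
            "ground_truth": out / "ground_truth.tsv",
        }
        write_association_table(self.lnc_disease, paths["lnc_disease"])
        write_association_table(self.mir_disease, paths["mir_disease"])
        write_association_table(self.lnc_mir, paths["lnc_mir"])
        write_disease_dag(self.dag, paths["dag"])
        with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
            fh.write("entity_id\tentity_class\tcommunity\n")
            for d, c in self.disease_communities.items():
                fh.write(f"{d}\tdisease\t{c}\n")
            for l, c in self.lnc_communities.items():
                fh.write(f"{l}\tlncRNA\t{c}\n")
            for m, c in self.mir_communities.items():
                fh.write(f"{m}\tmiRNA\t{c}\n")
        return paths


def _communities(n: int, k: int) -> np.ndarray:
    """Deterministic balanced assignment of n entities to k communities."""
    return np.arange(n) % k


def _planted_edges(
    rng: np.random.Generator,
    left_comm: np.ndarray,
    right_comm: np.ndarray,
    p_within: float,
    p_between: float,
) -> np.ndarray:
    same = left_comm[:, None] == right_comm[None, :]
    probs = np.where(same, p_within, p_between)
    return rng.random(probs.shape) < probs


def _community_tree(
    rng: np.random.Generator,
    diseases: list[str],
    comm: np.ndarray,
    branching: int,
    mode: str,
) -> DiseaseDAG:
    """Rooted tree over the diseases plus scaffold nodes (one anchor per community)."""
    root = "root"
    edges: list[tuple[str, str]] = []
    if mode == "community":
        groups: dict[int, list[str]] = {}
        for d, c in zip(diseases, comm):
            groups.setdefault(int(c), []).append(d)
        for c in sorted(groups):
            anchor = f"grp{c}"
            edges.append((anchor, root))
            attachable = [anchor]
            child_count = {anchor: 0}
            for d in groups[c]:
                open_parents = [a for a in attachable if child_count[a] < branching]
                parent = open_parents[rng.integers(len(open_parents))]
                edges.append((d, parent))
                child_count[parent] += 1
                attachable.append(d)
                child_count[d] = 0
        return disease_dag_from_edges(edges, extra_nodes=(root,))
    # random mode: one tree ignoring communities
    attachable = [root]
    child_count = {root: 0}
    for d in diseases:
        open_parents = [a for a in attachable if child_count[a] < branching]
        parent = open_parents[rng.integers(len(open_parents))]
        edges.append((d, parent))
        child_count[parent] += 1
        attachable.append(d)
        child_count[d] = 0
    return disease_dag_from_edges(edges, extra_nodes=(root,))


def _has_triangle(ld: np.ndarray, md: np.ndarray, lm: np.ndarray) -> bool:
    # triangle (d, l, m): ld[l, d] & md[m, d] & lm[l, m]
    for d in range(ld.shape[1]):
        l_idx = np.nonzero(ld[:, d])[0]
        m_idx = np.nonzero(md[:, d])[0]
        if l_idx.size and m_idx.size and lm[np.ix_(l_idx, m_idx)].any():
            return True
    return False


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; retries (bounded) until at least one triangle exists."""
    rng = np.random.default_rng(config.seed)
    diseases = [f"d{i:03d}" for i in range(config.n_diseases)]
    lncs = [f"l{i:03d}" for i in range(config.n_lncRNAs)]
    mirs = [f"m{i:03d}" for i in range(config.n_miRNAs)]
    d_comm = _communities(config.n_diseases, config.n_communities)
    l_comm = _communities(config.n_lncRNAs, config.n_communities)
    m_comm = _communities(config.n_miRNAs, config.n_communities)

    for _ in range(_MAX_RETRIES):
        ld = _planted_edges(rng, l_comm, d_comm, config.p_within, config.p_between)
        md = _planted_edges(rng, m_comm, d_comm, config.p_within, config.p_between)
        lm = _planted_edges(rng, l_comm, m_comm, config.p_lm_within, config.p_lm_between)
        if ld.any() and md.any() and lm.any() and _has_triangle(ld, md, lm):
            break
    else:
        raise RuntimeError(
            "no (disease, lncRNA, miRNA) triangle after "
            f"{_MAX_RETRIES} draws; increase p_within / p_lm_within"
        )

    dag = _community_tree(rng, diseases, d_comm, config.dag_branching, config.dag_mode)

    def _edges(mask: np.ndarray, left: list[str], right: list[str]) -> list[tuple[str, str]]:
        return [(left[i], right[j]) for i, j in zip(*np.nonzero(mask))]

    return SyntheticDataset(
        lnc_disease=association_table_from_edges(_edges(ld, lncs, diseases), KIND_LNC_DISEASE),
        mir_disease=association_table_from_edges(_edges(md, mirs, diseases), KIND_MIR_DISEASE),
        lnc_mir=association_table_from_edges(_edges(lm, lncs, mirs), KIND_LNC_MIR),
        dag=dag,
        disease_communities={d: int(c) for d, c in zip(diseases, d_comm)},
        lnc_communities={l: int(c) for l, c in zip(lncs, l_comm)},
        mir_communities={m: int(c) for m, c in zip(mirs, m_comm)},
        config=config,
    )


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """Density-matched no-structure variant of ``config``.

    Within and between probabilities are equalized at the expected mixed
    density of the structured configuration (one community in k matches), so
    the null differs from the structured dataset only in the absence of
    community structure, not in overall edge density.
    """
    f_in = 1.0 / config.n_communities
    p_assoc = f_in * config.p_within + (1 - f_in) * config.p_between
    p_lm = f_in * config.p_lm_within + (1 - f_in) * config.p_lm_between
    return replace(
        config,
        n_communities=1,
        p_within=p_assoc,
        p_between=p_assoc,
        p_lm_within=p_lm,
        p_lm_between=p_lm,
    )


def holdout_benchmark(config: SyntheticConfig, cv, params=None, pair_method: str = "average"):
    """Generate a dataset, run the full pipeline and cross-validate it.

    Thin convenience over :func:`generate` + the pipeline + k-fold CV; returns
    the :class:`~lmpairnet.evaluation.CVResult`.
    """
    from .evaluation import kfold_cv, loocv
    from .katz import KatzParams
    from .pipeline import prepare_model

    dataset = generate(config)
    model = prepare_model(
        dataset.lnc_disease,
        dataset.mir_disease,
        dataset.lnc_mir,
        dataset.dag,
        pair_method=pair_method,
    )
    params = params or KatzParams()
    if cv.scheme == "loocv":
        return loocv(model.network, model.pair_sim, model.dis_sim, params)
    return kfold_cv(model.network, model.pair_sim, model.dis_sim, params, cv)
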