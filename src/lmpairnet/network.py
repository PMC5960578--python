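"""Construction of the layered association networks.

The pipeline builds, in order:

1. three bipartite networks — lncRNA–disease, miRNA–disease and lncRNA–miRNA —
   straight from the association tables;
2. a triangle-filtered tripartite network over the shared entity sets: an edge
   survives only if it participates in at least one (disease, lncRNA, miRNA)
   triangle, i.e. all three pairwise associations co-occur;
3. the disease–pair bipartite network whose vertices are diseases and composite
   (lncRNA, miRNA) pairs; a disease is linked to a pair exactly when the
   corresponding triangle exists.  Its binary adjacency ``DP`` (pairs × diseases)
   is the training signal for the KATZ scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AssociationTable

# Guard against materializing an unreasonably large full pair cross product.
DEFAULT_MAX_PAIRS = 2_000_000


@dataclass(frozen=True)
class BipartiteNetwork:
    """A labeled two-mode graph with a binary adjacency view (left × right)."""

    left_ids: tuple[str, ...]
    right_ids: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.shape != (len(self.left_ids), len(self.right_ids)):
            raise ValueError("adjacency shape does not match id lists")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if len(set(self.left_ids)) != len(self.left_ids) or len(set(self.right_ids)) != len(
            self.right_ids
        ):
            raise ValueError("duplicate labels in bipartite network")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def left_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.left_ids)}

    def right_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.right_ids)}


def build_bipartite(table: AssociationTable) -> BipartiteNetwork:
    """Materialize the binary adjacency of an association table."""
    if len(table) == 0:
        raise ValueError("cannot build a bipartite network from an empty table")
    li = {v: i for i, v in enumerate(table.left_ids)}
    ri = {v: i for i, v in enumerate(table.right_ids)}
    adj = np.zeros((len(li), len(ri)), dtype=np.int8)
    for a, b in table.edges:
        adj[li[a], ri[b]] = 1
    return BipartiteNetwork(table.left_ids, table.right_ids, adj)


@dataclass(frozen=True)
class TripartiteNetwork:
    """Triangle-filtered disease–lncRNA–miRNA network.

    ``lnc_ids``/``mir_ids`` keep only genes incident to at least one retained
    disease edge; every retained edge belongs to at least one triangle.  The
    boolean matrices hold the retained edge sets:

    * ``A_ld`` — lncRNA × disease
    * ``A_md`` — miRNA × disease
    * ``A_lm`` — lncRNA × miRNA
    """

    lnc_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    A_ld: np.ndarray
    A_md: np.ndarray
    A_lm: np.ndarray

    @property
    def edges_ld(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (self.lnc_ids[i], self.disease_ids[j]) for i, j in zip(*np.nonzero(self.A_ld))
        )

    @property
    def edges_md(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (self.mir_ids[i], self.disease_ids[j]) for i, j in zip(*np.nonzero(self.A_md))
        )

    @property
    def edges_lm(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (self.lnc_ids[i], self.mir_ids[j]) for i, j in zip(*np.nonzero(self.A_lm))
        )

    def triangle_tensor(self) -> np.ndarray:
        """Boolean (lnc, mir, disease) tensor of triangles among retained edges."""
        return (
            self.A_ld[:, None, :].astype(bool)
            & self.A_md[None, :, :].astype(bool)
            & self.A_lm[:, :, None].astype(bool)
        )

    @property
    def n_triangles(self) -> int:
        return int(self.triangle_tensor().sum())


def _restrict(ids: tuple[str, ...], keep: set[str]) -> tuple[str, ...]:
    return tuple(v for v in ids if v in keep)


def build_tripartite(
    g1: BipartiteNetwork, g2: BipartiteNetwork, g3: BipartiteNetwork
) -> TripartiteNetwork:
    """Intersect the three bipartite layers and keep only triangle-supported edges.

    ``g1`` is lncRNA × disease, ``g2`` miRNA × disease, ``g3`` lncRNA × miRNA.
    Raises if the two disease vocabularies are disjoint or no triangle exists.
    """
    lnc_shared = _restrict(g1.left_ids, set(g3.left_ids))
    mir_shared = _restrict(g2.left_ids, set(g3.right_ids))
    dis_shared = _restrict(g1.right_ids, set(g2.right_ids))
    if not dis_shared:
        raise ValueError("no shared diseases between the two disease association networks")
    if not lnc_shared or not mir_shared:
        raise ValueError("no triangles: shared lncRNA or miRNA vocabulary is empty")

    g1_li, g1_ri = g1.left_index(), g1.right_index()
    g2_li, g2_ri = g2.left_index(), g2.right_index()
    g3_li, g3_ri = g3.left_index(), g3.right_index()

    A_ld = g1.adjacency[np.ix_([g1_li[v] for v in lnc_shared], [g1_ri[v] for v in dis_shared])]
    A_md = g2.adjacency[np.ix_([g2_li[v] for v in mir_shared], [g2_ri[v] for v in dis_shared])]
    A_lm = g3.adjacency[np.ix_([g3_li[v] for v in lnc_shared], [g3_ri[v] for v in mir_shared])]

    tri = (
        A_ld[:, None, :].astype(bool)
        & A_md[None, :, :].astype(bool)
        & A_lm[:, :, None].astype(bool)
    )
    if not tri.any():
        raise ValueError("no triangles across the three association layers")

    # Retain only edges participating in >=1 triangle, then prune gene vertices
    # with no retained disease edge.
    keep_ld = tri.any(axis=1)
    keep_md = tri.any(axis=0)
    keep_lm = tri.any(axis=2)
    lnc_mask = keep_ld.any(axis=1)
    mir_mask = keep_md.any(axis=1)

    lnc_ids = tuple(v for v, k in zip(lnc_shared, lnc_mask) if k)
    mir_ids = tuple(v for v, k in zip(mir_shared, mir_mask) if k)

    return TripartiteNetwork(
        lnc_ids=lnc_ids,
        mir_ids=mir_ids,
        disease_ids=tuple(dis_shared),
        A_ld=keep_ld[lnc_mask].astype(np.int8),
        A_md=keep_md[mir_mask].astype(np.int8),
        A_lm=keep_lm[np.ix_(lnc_mask, mir_mask)].astype(np.int8),
    )


@dataclass(frozen=True)
class DiseaseLMPairNetwork:
    """Bipartite network between diseases and composite (lncRNA, miRNA) pairs.

    ``pair_ids`` enumerates pairs row-major over (lncRNA, then miRNA); pair
    ``(l_i, m_j)`` has index ``i * n_mir + j`` in the full cross-product mode.
    ``DP`` is the binary pairs × diseases adjacency; ``DP[p, d] = 1`` iff the
    (disease, lncRNA, miRNA) triangle exists.
    """

    disease_ids: tuple[str, ...]
    pair_ids: tuple[tuple[str, str], ...]
    DP: np.ndarray
    lnc_ids: tuple[str, ...] = field(default=())
    mir_ids: tuple[str, ...] = field(default=())

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def known_edges(self) -> frozenset[tuple[int, int]]:
        """Set of (disease index, pair index) known associations."""
        return frozenset((int(d), int(p)) for p, d in zip(*np.nonzero(self.DP)))

    @property
    def n_known(self) -> int:
        return int(self.DP.sum())


def build_disease_lmpair_network(
    tri: TripartiteNetwork,
    pairs: str = "full",
    max_pairs: int = DEFAULT_MAX_PAIRS,
) -> DiseaseLMPairNetwork:
    """Assemble the disease–pair network and its adjacency ``DP``.

    ``pairs='full'`` enumerates the complete lncRNA × miRNA cross product;
    ``pairs='interacting'`` restricts pair vertices to those with a retained
    lncRNA–miRNA interaction edge.
    """
    n_l, n_m, n_d = len(tri.lnc_ids), len(tri.mir_ids), len(tri.disease_ids)
    tri_tensor = tri.triangle_tensor()
    if not tri_tensor.any():
        raise ValueError("tripartite network contains no triangles")

    if pairs == "full":
        if n_l * n_m > max_pairs:
            raise ValueError(
                f"full pair cross product has {n_l * n_m} pairs (> guard {max_pairs}); "
                "use pairs='interacting' to restrict to interacting pairs"
            )
        pair_ids = tuple((l, m) for l in tri.lnc_ids for m in tri.mir_ids)
        DP = tri_tensor.reshape(n_l * n_m, n_d).astype(np.int8)
    elif pairs == "interacting":
        li, mi = np.nonzero(tri.A_lm)
        pair_ids = tuple((tri.lnc_ids[i], tri.mir_ids[j]) for i, j in zip(li, mi))
        DP = tri_tensor[li, mi, :].astype(np.int8)
    else:
        raise ValueError(f"unknown pairs mode {pairs!r}")

    net = DiseaseLMPairNetwork(
        disease_ids=tri.disease_ids,
        pair_ids=pair_ids,
        DP=DP,
        lnc_ids=tri.lnc_ids,
        mir_ids=tri.mir_ids,
    )
    _assert_triangle_closure(net, tri)
    return net


def _assert_triangle_closure(net: DiseaseLMPairNetwork, tri: TripartiteNetwork) -> None:
    """Every known disease–pair edge must be backed by all three bipartite edges."""
    lix = {v: i for i, v in enumerate(tri.lnc_ids)}
    mix = {v: i for i, v in enumerate(tri.mir_ids)}
    p_idx, d_idx = np.nonzero(net.DP)
    for p, d in zip(p_idx, d_idx):
        l, m = net.pair_ids[p]
        i, j = lix[l], mix[m]
        if not (tri.A_ld[i, d] and tri.A_md[j, d] and tri.A_lm[i, j]):
            raise AssertionError(
                f"triangle closure violated for pair {net.pair_ids[p]} and disease "
                f"{net.disease_ids[d]}"
            )
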