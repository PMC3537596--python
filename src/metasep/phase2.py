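"""Phase 2: merging phase-1 clusters through shared repeats.

Clusters of unique l-mers from one genome are linked by the repeats of that
genome: for each cluster C_i, the repeat set R_i collects (a) repeat l-mers
seen in reads corresponding to C_i and (b) all unclustered l-mers of the
mates of those reads.  The weighted graph F (nodes = clusters, weight W_ij =
|R_i ∩ R_j|) is clustered with Markov Clustering (MCL), implemented here
from scratch: alternate expansion (matrix power) and inflation (entrywise
power r, column renormalisation) of the column-stochastic matrix until
convergence.  Inflation r sets granularity; it is tuned by descending a
schedule until every *big* m-cluster (enough unique-l-mer content to be a
genome) is *valid* (cleanly separated from every other big m-cluster under
the normalised inter-weight criterion W_ij / sqrt(W_ii W_jj) <= eps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._sorted import isin_sorted, unique_sorted
from .classify import LmerPartition
from .lmer_core import ReadPairSet
from .phase1 import Phase1Clusters, _map_reads, _window_node_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatProfile",
    "ClusterGraphF",
    "MClusterResult",
    "build_repeat_profile",
    "build_cluster_graph",
    "mcl",
    "is_valid",
    "tune_granularity",
    "merge_clusters",
    "DEFAULT_R_SCHEDULE",
]

DEFAULT_R_SCHEDULE = (5.0, 4.0, 3.0, 2.5, 2.0, 1.8, 1.5, 1.3, 1.2)


@dataclass
class RepeatProfile:
    """Per-cluster sets of repeat/unattached l-mers (sorted code arrays)."""

    R: list[np.ndarray]

    @property
    def n_clusters(self) -> int:
        return len(self.R)


@dataclass
class ClusterGraphF:
    """Weighted cluster graph: W[i, j] = |R_i ∩ R_j| (dense, symmetric).

    The diagonal is the default intra weight of a node, the total weight of
    its incident edges.
    """

    W: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def off_diagonal(self) -> np.ndarray:
        off = self.W.copy()
        np.fill_diagonal(off, 0.0)
        return off


@dataclass
class MClusterResult:
    """MCL partition of cluster indices with granularity diagnostics."""

    m_clusters: list[list[int]]
    r: float
    big: set[int] = field(default_factory=set)
    valid: set[int] = field(default_factory=set)
    accepted: bool = True


def build_repeat_profile(
    clusters: Phase1Clusters,
    reads: ReadPairSet,
    partition: LmerPartition,
) -> RepeatProfile:
    """Attribute repeats and unattached mate l-mers to phase-1 clusters.

    For every mate corresponding to cluster C_i: its windows whose canonical
    l-mers are repeats (partition.R) join R_i, and every window of its mate
    whose l-mer belongs to no cluster joins R_i as well.
    """
    l = partition.l
    mat, ok = reads.mate_window_matrix(l)
    nm = mat.shape[0]
    rm = clusters.read_map
    all_clustered = (
        unique_sorted(np.concatenate(clusters.clusters))
        if clusters.clusters
        else np.empty(0, dtype=np.int64)
    )
    in_R = isin_sorted(mat.ravel(), partition.R).reshape(mat.shape) & ok
    unclustered = ~isin_sorted(mat.ravel(), all_clustered).reshape(mat.shape) & ok

    parts: list[list[np.ndarray]] = [[] for _ in range(clusters.n_clusters)]
    assigned = np.flatnonzero(rm >= 0)
    for mate_idx in assigned:
        cid = rm[mate_idx]
        own = mat[mate_idx][in_R[mate_idx]]
        if own.size:
            parts[cid].append(own)
        partner = mate_idx ^ 1  # other mate of the same pair
        other = mat[partner][unclustered[partner]]
        if other.size:
            parts[cid].append(other)
    R = [
        unique_sorted(np.concatenate(p)) if p else np.empty(0, dtype=np.int64)
        for p in parts
    ]
    return RepeatProfile(R=R)


def build_cluster_graph(profile: RepeatProfile) -> ClusterGraphF:
    """W_ij = |R_i ∩ R_j| for i != j; diagonal = total incident weight."""
    k = profile.n_clusters
    if k < 1:
        raise ValueError("need at least one cluster")
    W = np.zeros((k, k), dtype=np.float64)
    if k > 1:
        codes = np.concatenate([r for r in profile.R]) if any(
            r.size for r in profile.R
        ) else np.empty(0, dtype=np.int64)
        owner = np.concatenate(
            [np.full(r.size, i, dtype=np.int64) for i, r in enumerate(profile.R)]
        ) if codes.size else np.empty(0, dtype=np.int64)
        if codes.size:
            order = np.argsort(codes, kind="stable")
            codes = codes[order]
            owner = owner[order]
            boundaries = np.flatnonzero(np.diff(codes)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [codes.size]))
            for s, e in zip(starts, ends):
                if e - s > 1:
                    grp = owner[s:e]
                    for a in range(e - s):
                        for b in range(a + 1, e - s):
                            W[grp[a], grp[b]] += 1.0
                            W[grp[b], grp[a]] += 1.0
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, W.sum(axis=1))
    return ClusterGraphF(W=W)


def mcl(
    F: ClusterGraphF | np.ndarray,
    r: float,
    expansion: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
    prune: float = 1e-8,
    keep_self_loops: bool = False,
) -> list[list[int]]:
    """Markov Clustering of a weighted graph; returns a partition of nodes.

    The adjacency (off-diagonal weights) gets a self-loop per node equal to
    its maximum incident edge weight (1 for isolated nodes), is column
    normalised, then expansion (matrix power) and inflation (entrywise power
    ``r`` followed by column renormalisation and pruning of entries below
    ``prune``) alternate until the matrix changes by less than ``tol`` or
    ``max_iter`` is reached (non-convergence interprets the current matrix,
    with a warning).  Attractors are rows with positive diagonal; each node
    joins the lowest-indexed attractor giving it mass, and attractor groups
    sharing nodes are merged.
    """
    if r <= 1:
        raise ValueError("inflation r must exceed 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    W = F.W if isinstance(F, ClusterGraphF) else np.asarray(F, dtype=float)
    n = W.shape[0]
    if n == 0:
        return []
    M = W.astype(float).copy()
    given = np.diag(M).copy()
    np.fill_diagonal(M, 0.0)
    loops = M.max(axis=1)
    if keep_self_loops:
        # honor caller-provided self-loops (e.g. intra weight of a quotient
        # graph), never below the max incident edge
        loops = np.maximum(loops, given)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(M, loops)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**r
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        M[M < prune] = 0.0
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    attractors = np.flatnonzero(np.diag(M) > 0)
    owner = np.full(n, -1, dtype=np.int64)
    for a in attractors:
        support = np.flatnonzero(M[a] > 0)
        for j in support:
            if owner[j] == -1:
                owner[j] = a
    # nodes with no attractor mass become singletons
    for j in range(n):
        if owner[j] == -1:
            owner[j] = j
    # merge attractors that share any node's support (overlapping rows)
    uf_parent = {int(a): int(a) for a in attractors}
    for o in np.unique(owner):
        uf_parent.setdefault(int(o), int(o))

    def find(x: int) -> int:
        while uf_parent[x] != x:
            uf_parent[x] = uf_parent[uf_parent[x]]
            x = uf_parent[x]
        return x

    for j in range(n):
        owners_j = [int(a) for a in attractors if M[a, j] > 0]
        for a in owners_j[1:]:
            ra, rb = find(owners_j[0]), find(a)
            if ra != rb:
                uf_parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for j in range(n):
        root = find(int(owner[j]))
        groups.setdefault(root, []).append(j)
    return [sorted(v) for _, v in sorted(groups.items())]


def _mcluster_weights(W_off: np.ndarray, m_clusters: list[list[int]]):
    """Intra weight per m-cluster and inter weights between m-clusters."""
    k = len(m_clusters)
    intra = np.zeros(k)
    inter = np.zeros((k, k))
    for i, mi in enumerate(m_clusters):
        sub = W_off[np.ix_(mi, mi)]
        intra[i] = sub.sum() / 2.0
        for j in range(i + 1, k):
            mj = m_clusters[j]
            inter[i, j] = inter[j, i] = W_off[np.ix_(mi, mj)].sum()
    return intra, inter


def is_valid(
    i: int,
    big: set[int],
    intra: np.ndarray,
    inter: np.ndarray,
    eps: float = 1e-3,
    normalization: str = "geometric",
) -> bool:
    """Is big m-cluster ``i`` cleanly separated from every other big one?

    Separation from j requires the normalised inter-weight
    W_ij / sqrt(W_ii W_jj) (or W_ij / (W_ii W_jj) with the ``product``
    alternative) to be at most ``eps``.  A zero inter-weight always counts
    as separated; a positive inter-weight with zero intra-weight never does.
    """
    for j in big:
        if j == i:
            continue
        w_ij = inter[i, j]
        if w_ij == 0:
            continue
        if intra[i] <= 0 or intra[j] <= 0:
            return False
        if normalization == "geometric":
            ratio = w_ij / np.sqrt(intra[i] * intra[j])
        elif normalization == "product":
            ratio = w_ij / (intra[i] * intra[j])
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        if ratio > eps:
            return False
    return True


def tune_granularity(
    F: ClusterGraphF,
    cluster_sizes: np.ndarray,
    min_big_size: int,
    r_schedule: tuple[float, ...] = DEFAULT_R_SCHEDULE,
    eps: float = 1e-3,
    normalization: str = "geometric",
    **mcl_kwargs,
) -> MClusterResult:
    """Descend the inflation schedule until all big m-clusters are valid.

    ``cluster_sizes[i]`` is the unique-l-mer content of phase-1 cluster i; an
    m-cluster is *big* when its total content reaches ``min_big_size``
    (the l-mer equivalent of the smallest genome the user expects).  The
    first (highest) r whose big m-clusters are all valid is accepted; an
    exhausted schedule accepts the last r with a warning.
    """
    if not r_schedule or any(r <= 1 for r in r_schedule) or list(
        r_schedule
    ) != sorted(r_schedule, reverse=True):
        raise ValueError("r_schedule must be non-empty, strictly descending, all > 1")
    cluster_sizes = np.asarray(cluster_sizes)
    W_off = F.off_diagonal()
    last: MClusterResult | None = None
    for r in r_schedule:
        m_clusters = mcl(F, r=r, **mcl_kwargs)
        sizes = np.array([cluster_sizes[m].sum() for m in m_clusters])
        big = {i for i in range(len(m_clusters)) if sizes[i] >= min_big_size}
        intra, inter = _mcluster_weights(W_off, m_clusters)
        valid = {
            i
            for i in big
            if is_valid(i, big, intra, inter, eps=eps, normalization=normalization)
        }
        last = MClusterResult(
            m_clusters=m_clusters, r=r, big=big, valid=valid, accepted=True
        )
        if valid == big:
            return last
    logger.warning(
        "granularity schedule exhausted; accepting r=%.2f with %d/%d big "
        "m-clusters valid",
        last.r,
        len(last.valid),
        len(last.big),
    )
    last.accepted = False
    return last


def merge_clusters(
    clusters: Phase1Clusters,
    m: MClusterResult,
    reads: ReadPairSet,
    l: int,
) -> Phase1Clusters:
    """Union phase-1 clusters within each m-cluster; recompute the read map."""
    covered = sorted(i for grp in m.m_clusters for i in grp)
    if covered != list(range(clusters.n_clusters)):
        raise ValueError("m-clusters must partition the phase-1 cluster indices")
    merged = [
        unique_sorted(np.concatenate([clusters.clusters[i] for i in grp]))
        for grp in m.m_clusters
    ]
    node_codes = (
        unique_sorted(np.concatenate(merged)) if merged else np.empty(0, dtype=np.int64)
    )
    membership = np.full(node_codes.shape[0], -1, dtype=np.int64)
    for cid, codes in enumerate(merged):
        membership[np.searchsorted(node_codes, codes)] = cid
    win = _window_node_matrix(reads, node_codes, l)
    read_map = _map_reads(win, membership, len(merged))
    out = Phase1Clusters(clusters=merged, read_map=read_map, frozen=[False] * len(merged))
    out.check_disjoint()
    return out
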