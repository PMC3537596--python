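"""Phase 1: clustering of unique l-mers via the read co-occurrence graph.

Nodes are the unique l-mers U; two nodes are joined when both l-mers occur
in the same read.  A truly unique l-mer can co-occur only with the at most
2(L - l) other l-mers overlapping its genomic locus, so nodes exceeding
that degree are undetected repeats and are pruned.  Clusters are grown from
a random seed read by repeatedly absorbing all unclustered nodes with at
least T in-cluster neighbors; a growth step larger than 2(L - (l + T) + 1)
nodes is impossible for a single genomic locus and signals a repeat, which
freezes the cluster.  T is chosen as large as possible while keeping the
expected number of Lander-Waterman coverage gaps below one.  Paired-end
links then consolidate clusters fragmented by residual coverage gaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._sorted import isin_sorted, unique_counts, unique_sorted
from .classify import LmerPartition
from .lmer_core import ReadPairSet

logger = logging.getLogger(__name__)

__all__ = [
    "UniqueGraph",
    "TSelection",
    "Phase1Clusters",
    "select_T",
    "build_graph",
    "prune_high_degree",
    "expand_clusters",
    "read_corresponds",
    "consolidate_paired",
]


@dataclass
class TSelection:
    """Chosen co-occurrence threshold T with its coverage diagnostics."""

    T: int
    Cov: float
    exp_gaps: float
    low_coverage: bool = False


def _cov(T: int, N: int, L: int, l: int, G: float) -> float:
    return 2 * N * (L - (l + T) + 1) / (G - L + 1)


def select_T(N: int, L: int, l: int, G: float) -> TSelection:
    """Largest T >= 1 keeping the expected number of coverage gaps below 1.

    At threshold T the effective coverage is Cov = 2N(L - (l + T) + 1) /
    (G - L + 1) and the expected gap count 2N exp(-Cov).  If even T = 1
    fails the bound, T = 1 is returned with a low-coverage warning flag.
    """
    if G <= L:
        raise ValueError("G must exceed L")
    if N < 1:
        raise ValueError("need at least one read pair")
    for T in range(L - l, 0, -1):
        cov = _cov(T, N, L, l, G)
        gaps = 2 * N * math.exp(-cov)
        if gaps < 1.0:
            return TSelection(T=T, Cov=cov, exp_gaps=gaps)
    cov = _cov(1, N, L, l, G)
    gaps = 2 * N * math.exp(-cov)
    logger.warning(
        "coverage too low: expected gaps %.2f >= 1 even at T=1", gaps
    )
    return TSelection(T=1, Cov=cov, exp_gaps=gaps, low_coverage=True)


@dataclass
class UniqueGraph:
    """Undirected graph over unique l-mers in CSR form.

    ``node_codes`` maps node index -> canonical l-mer code (sorted, so code
    -> index is a binary search).  ``indptr``/``indices`` is symmetric
    adjacency (each edge stored in both directions).
    """

    node_codes: np.ndarray  # int64, sorted
    indptr: np.ndarray  # int64, len n+1
    indices: np.ndarray  # int32
    degree_bound: int

    @property
    def n_nodes(self) -> int:
        return self.node_codes.shape[0]

    @property
    def n_edges(self) -> int:
        return self.indices.shape[0] // 2

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr).astype(np.int64)

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]

    def node_index_of(self, codes: np.ndarray) -> np.ndarray:
        """Node indices for canonical codes (-1 where not a node)."""
        if self.n_nodes == 0:
            return np.full(codes.shape, -1, dtype=np.int64)
        pos = np.searchsorted(self.node_codes, codes)
        pos = np.clip(pos, 0, self.n_nodes - 1)
        hit = self.node_codes[pos] == codes
        return np.where(hit, pos, -1)


def _window_node_matrix(
    reads: ReadPairSet, node_codes: np.ndarray, l: int
) -> np.ndarray:
    """(2N, W) matrix of node indices per mate window; -1 = not a U node."""
    mat, ok = reads.mate_window_matrix(l)
    pos = np.searchsorted(node_codes, mat)
    pos = np.clip(pos, 0, max(node_codes.size - 1, 0))
    if node_codes.size:
        hit = (node_codes[pos] == mat) & ok
    else:
        hit = np.zeros(mat.shape, dtype=bool)
    return np.where(hit, pos, -1).astype(np.int64)


def _pack_edges(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return (lo << 32) | hi


def build_graph(reads: ReadPairSet, partition: LmerPartition) -> UniqueGraph:
    """Edges between every pair of unique l-mers sharing a read.

    Deduplicated and unweighted.  Built per window offset d = 1..W-1 so the
    intermediate pair arrays stay bounded; pairs are packed into int64 keys
    for vectorised de-duplication.
    """
    l = partition.l
    win = _window_node_matrix(reads, partition.U, l)
    per_d_unique: list[np.ndarray] = []
    W = win.shape[1]
    for d in range(1, W):
        a = win[:, : W - d].ravel()
        b = win[:, d:].ravel()
        m = (a >= 0) & (b >= 0) & (a != b)
        if not m.any():
            continue
        per_d_unique.append(unique_sorted(_pack_edges(a[m], b[m])))
    if per_d_unique:
        keys = unique_sorted(np.concatenate(per_d_unique))
    else:
        keys = np.empty(0, dtype=np.int64)
    u = (keys >> 32).astype(np.int32)
    v = (keys & 0xFFFFFFFF).astype(np.int32)
    return _csr_from_edges(partition.U, u, v, degree_bound=2 * (reads.L - l))


def _csr_from_edges(
    node_codes: np.ndarray, u: np.ndarray, v: np.ndarray, degree_bound: int
) -> UniqueGraph:
    # sort both edge directions as packed (src, dst) keys: a plain int64
    # sort groups the adjacency by source much faster than argsort would
    n = node_codes.shape[0]
    fwd = (u.astype(np.int64) << 32) | v.astype(np.int64)
    rev = (v.astype(np.int64) << 32) | u.astype(np.int64)
    keys = np.sort(np.concatenate([fwd, rev]))
    src = (keys >> 32).astype(np.int64)
    dst = (keys & 0xFFFFFFFF).astype(np.int32)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=indptr[1:])
    return UniqueGraph(
        node_codes=node_codes,
        indptr=indptr,
        indices=dst,
        degree_bound=degree_bound,
    )


def _gather_adjacency(graph: UniqueGraph, nodes: np.ndarray) -> np.ndarray:
    """Concatenated neighbor lists of the given nodes."""
    if nodes.size == 0:
        return np.empty(0, dtype=np.int32)
    starts = graph.indptr[nodes]
    ends = graph.indptr[nodes + 1]
    lens = ends - starts
    total = int(lens.sum())
    out = np.empty(total, dtype=np.int64)
    # offsets of each node's block in the output
    offs = np.zeros(nodes.size, dtype=np.int64)
    np.cumsum(lens[:-1], out=offs[1:])
    idx = np.repeat(starts - offs, lens) + np.arange(total)
    return graph.indices[idx]


def prune_high_degree(
    graph: UniqueGraph, L: int, l: int, partition: LmerPartition | None = None
) -> tuple[UniqueGraph, LmerPartition | None]:
    """Iteratively remove nodes exceeding the 2(L - l) degree bound.

    Truly unique l-mers cannot have more than 2(L - l) distinct neighbors,
    so offenders are undetected repeats.  Removal lowers neighbors' degrees,
    so the scan iterates to a fixpoint.  Removed l-mers move from U to R in
    the returned partition (when one is supplied).
    """
    bound = 2 * (L - l)
    alive = np.ones(graph.n_nodes, dtype=bool)
    deg = graph.degrees()
    while True:
        over = np.flatnonzero(alive & (deg > bound))
        if over.size == 0:
            break
        alive[over] = False
        nbrs = _gather_adjacency(graph, over)
        nbrs = nbrs[alive[nbrs]]
        np.add.at(deg, nbrs, -1)
    removed_codes = graph.node_codes[~alive]
    if removed_codes.size == 0:
        return graph, partition
    # rebuild CSR on surviving nodes
    keep_codes = graph.node_codes[alive]
    remap = np.full(graph.n_nodes, -1, dtype=np.int64)
    remap[np.flatnonzero(alive)] = np.arange(keep_codes.shape[0])
    src = np.repeat(np.arange(graph.n_nodes), np.diff(graph.indptr))
    dst = graph.indices.astype(np.int64)
    m = alive[src] & alive[dst] & (src < dst)
    u = remap[src[m]].astype(np.int32)
    v = remap[dst[m]].astype(np.int32)
    pruned = _csr_from_edges(keep_codes, u, v, degree_bound=bound)
    logger.info(
        "degree pruning removed %d of %d nodes", removed_codes.size, graph.n_nodes
    )
    new_part = partition.move_to_R(removed_codes) if partition is not None else None
    return pruned, new_part


@dataclass
class Phase1Clusters:
    """Disjoint clusters of unique l-mers plus the mate-level read map.

    ``clusters[i]`` is a sorted array of canonical l-mer codes.  ``read_map``
    has one entry per mate (interleaved pair order); -1 = unassigned.
    ``frozen[i]`` marks clusters whose expansion hit the repeat cap.
    """

    clusters: list[np.ndarray]
    read_map: np.ndarray
    frozen: list[bool] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=np.int64)

    def check_disjoint(self) -> None:
        if not self.clusters:
            return
        allc = np.concatenate(self.clusters)
        if np.unique(allc).size != allc.size:
            raise AssertionError("phase-1 clusters are not disjoint")


def read_corresponds(read: str, cluster_codes: np.ndarray, l: int) -> bool:
    """True iff at least half of the read's windows lie in the cluster.

    The threshold is (L - l + 1)/2 as a real number: with 61 windows a read
    needs >= 30.5, i.e. >= 31 windows in the cluster.
    """
    from .lmer_core import encode_seq, window_codes

    if len(read) < l:
        raise ValueError("read shorter than l")
    codes, ok = window_codes(encode_seq(read), l)
    W = codes.shape[0]
    inside = isin_sorted(codes[ok], np.asarray(cluster_codes, dtype=np.int64)).sum()
    return bool(inside >= W / 2)


def _correspondence_counts(
    win: np.ndarray, membership: np.ndarray, n_clusters: int
) -> np.ndarray:
    """(n_mates, n_clusters) counts of in-cluster windows per mate."""
    nm, W = win.shape
    cl = np.where(win >= 0, membership[np.maximum(win, 0)], -1)
    rows = np.repeat(np.arange(nm, dtype=np.int64), W)
    flat = cl.ravel()
    m = flat >= 0
    counts = np.bincount(
        rows[m] * n_clusters + flat[m], minlength=nm * n_clusters
    )
    return counts.reshape(nm, n_clusters)


def _map_reads(win: np.ndarray, membership: np.ndarray, n_clusters: int) -> np.ndarray:
    """Mate-level read map by the >=-half rule (ties -> lowest cluster id)."""
    if n_clusters == 0:
        return np.full(win.shape[0], -1, dtype=np.int64)
    W = win.shape[1]
    counts = _correspondence_counts(win, membership, n_clusters)
    best = counts.argmax(axis=1)
    ok = counts[np.arange(win.shape[0]), best] >= W / 2
    return np.where(ok, best, -1)


def expand_clusters(
    graph: UniqueGraph,
    reads: ReadPairSet,
    T: int,
    l: int,
    rng_seed: int = 0,
    min_frozen_size: int = 10,
) -> Phase1Clusters:
    """Grow clusters of unique l-mers from random seed reads.

    Each cluster starts from the (unclustered) unique l-mers of a seed read
    drawn by a seeded RNG among reads that correspond to no cluster yet.  An
    iteration absorbs every unclustered node with >= T neighbors inside the
    cluster; if more than 2(L - (l + T) + 1) candidates appear at once the
    expansion has run into an unremoved repeat and the cluster is frozen at
    its pre-step membership.  Frozen clusters smaller than
    ``min_frozen_size`` are dissolved back to unclustered.  Seeding repeats
    until every read corresponds to some cluster or has no unclustered
    unique l-mers.
    """
    L = reads.L
    if T < 1 or T > L - l:
        raise ValueError(f"T must be in [1, L - l], got T={T}")
    cap = 2 * (L - (l + T) + 1)
    rng = np.random.default_rng(rng_seed)
    win = _window_node_matrix(reads, graph.node_codes, l)
    W = win.shape[1]
    nm = win.shape[0]
    n = graph.n_nodes

    membership = np.full(n, -1, dtype=np.int64)
    cnt = np.zeros(n, dtype=np.int32)  # in-current-cluster neighbor counts
    clusters: list[np.ndarray] = []
    frozen_flags: list[bool] = []

    # mates eligible as seeds: have >=1 unclustered U node
    pool_mask = (win >= 0).any(axis=1)
    pool = np.flatnonzero(pool_mask)

    while pool.size:
        seed_mate = int(rng.choice(pool))
        seeds = win[seed_mate]
        seeds = unique_sorted(seeds[(seeds >= 0)])
        seeds = seeds[membership[seeds] == -1]
        pool = pool[pool != seed_mate]
        if seeds.size == 0:
            continue
        cid = len(clusters)
        members: list[np.ndarray] = []
        touched: list[np.ndarray] = []
        frozen = False
        frontier = seeds
        while frontier.size:
            membership[frontier] = cid
            members.append(frontier)
            nbrs = _gather_adjacency(graph, frontier)
            np.add.at(cnt, nbrs, 1)
            touched.append(nbrs)
            cand = unique_sorted(nbrs[(membership[nbrs] == -1) & (cnt[nbrs] >= T)])
            if cand.size > cap:
                frozen = True  # repeat signature: stop at pre-step membership
                break
            frontier = cand
        member_arr = np.concatenate(members) if members else np.empty(0, dtype=np.int64)
        if touched:
            cnt[np.concatenate(touched)] = 0
        if frozen and member_arr.size < min_frozen_size:
            membership[member_arr] = -1  # dissolve tiny frozen cluster
            continue
        clusters.append(np.sort(graph.node_codes[member_arr]))
        frozen_flags.append(frozen)
        if pool.size:
            # drop mates that now correspond to this cluster or have no
            # unclustered U nodes left
            sub = win[pool]
            valid = sub >= 0
            in_cluster = np.zeros(sub.shape, dtype=bool)
            in_cluster[valid] = membership[sub[valid]] == cid
            corresponds = in_cluster.sum(axis=1) >= W / 2
            unclustered_left = np.zeros(sub.shape, dtype=bool)
            unclustered_left[valid] = membership[sub[valid]] == -1
            keep = ~corresponds & unclustered_left.any(axis=1)
            pool = pool[keep]

    # order clusters deterministically by size (desc), then first code
    order = sorted(
        range(len(clusters)), key=lambda i: (-clusters[i].size, int(clusters[i][0]))
    )
    clusters = [clusters[i] for i in order]
    frozen_flags = [frozen_flags[i] for i in order]
    relabel = np.full(len(order), -1, dtype=np.int64)
    for new, old in enumerate(order):
        relabel[old] = new
    membership = np.where(membership >= 0, relabel[membership], -1)

    read_map = _map_reads(win, membership, len(clusters))
    result = Phase1Clusters(clusters=clusters, read_map=read_map, frozen=frozen_flags)
    result.check_disjoint()
    return result


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def consolidate_paired(
    clusters: Phase1Clusters,
    reads: ReadPairSet,
    min_links: int = 3,
    l: int | None = None,
) -> Phase1Clusters:
    """Merge clusters bridged by at least ``min_links`` read pairs.

    A pair links two clusters when its two mates correspond to them; merges
    are transitive (union-find).  The read map is refreshed against the
    merged clusters.
    """
    k = clusters.n_clusters
    if k <= 1:
        return clusters
    rm = clusters.read_map
    c1 = rm[0::2]
    c2 = rm[1::2]
    m = (c1 >= 0) & (c2 >= 0) & (c1 != c2)
    if m.any():
        keys = _pack_edges(c1[m], c2[m])
        uk, nk = unique_counts(keys)
    else:
        uk = np.empty(0, dtype=np.int64)
        nk = uk
    uf = _UnionFind(k)
    for key, links in zip(uk, nk):
        if links >= min_links:
            uf.union(int(key >> 32), int(key & 0xFFFFFFFF))
    roots = [uf.find(i) for i in range(k)]
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(r, []).append(i)
    if len(groups) == k:
        return clusters
    merged: list[np.ndarray] = []
    merged_frozen: list[bool] = []
    relabel = np.full(k, -1, dtype=np.int64)
    for new, (_, idxs) in enumerate(sorted(groups.items())):
        merged.append(
            unique_sorted(np.concatenate([clusters.clusters[i] for i in idxs]))
        )
        merged_frozen.append(any(clusters.frozen[i] for i in idxs if clusters.frozen))
        for i in idxs:
            relabel[i] = new
    new_map = np.where(rm >= 0, relabel[np.maximum(rm, 0)], -1)
    # previously unassigned mates may now pass the >=-half rule
    if l is not None:
        node_codes = unique_sorted(np.concatenate(merged)) if merged else np.empty(0, np.int64)
        win = _window_node_matrix(reads, node_codes, l)
        membership = np.full(node_codes.shape[0], -1, dtype=np.int64)
        for cid, codes in enumerate(merged):
            membership[np.searchsorted(node_codes, codes)] = cid
        unass = np.flatnonzero(new_map == -1)
        if unass.size:
            sub_map = _map_reads(win[unass], membership, len(merged))
            new_map[unass] = sub_map
    out = Phase1Clusters(clusters=merged, read_map=new_map, frozen=merged_frozen)
    out.check_disjoint()
    return out
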