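"""Final iterative assignment of reads to the merged clusters.

Three steps repeat until a fixpoint: (1) every unassigned mate
corresponding to a cluster (at least half of its windows inside) is
assigned — a mate corresponding to several clusters goes to the one holding
the largest fraction of its l-mers, ties to the lowest cluster id; (2)
unassigned mates whose partner is assigned inherit the partner's cluster;
(3) each cluster's l-mer set absorbs all l-mers of its newly assigned
mates (including former repeats, so augmented l-mers may belong to several
clusters at once).  Augmentation persists across rounds, so the assigned
set and every cluster's l-mer set grow monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sorted import isin_sorted, unique_sorted
from .classify import LmerPartition
from .lmer_core import ReadPairSet
from .phase1 import Phase1Clusters

__all__ = ["ReadAssignment", "assign_reads"]


@dataclass
class ReadAssignment:
    """Mate-level assignment: ``assign[m]`` = final cluster id or -1."""

    mate_ids: list[str]
    assign: np.ndarray
    iterations_run: int

    @property
    def n_assigned(self) -> int:
        return int((self.assign >= 0).sum())

    def as_dict(self) -> dict[str, int | None]:
        return {
            rid: (int(c) if c >= 0 else None)
            for rid, c in zip(self.mate_ids, self.assign)
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcluster_id\n")
            for rid, c in zip(self.mate_ids, self.assign):
                fh.write(f"{rid}\t{int(c) if c >= 0 else 'NA'}\n")


def assign_reads(
    reads: ReadPairSet,
    final_clusters: Phase1Clusters,
    partition: LmerPartition | None = None,
    max_rounds: int = 10,
) -> ReadAssignment:
    """Iterate correspondence / mate propagation / l-mer augmentation.

    ``partition`` fixes the l-mer length when the cluster list is empty;
    otherwise l is taken from the partition or inferred from the clusters'
    origin (the window matrices are cached on ``reads``).
    """
    l = partition.l if partition is not None else None
    if l is None:
        if not reads._win_cache:
            raise ValueError("cannot infer l: pass a partition")
        l = next(iter(reads._win_cache))
    mat, ok = reads.mate_window_matrix(l)
    nm, W = mat.shape
    k = final_clusters.n_clusters
    assign = np.full(nm, -1, dtype=np.int64)
    if k == 0:
        return ReadAssignment(reads.mate_ids(), assign, 1)
    cluster_sets = [c.copy() for c in final_clusters.clusters]
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        changed = False
        newly = np.zeros(nm, dtype=bool)
        # step 1: correspondence of unassigned mates to (augmented) clusters
        unass = np.flatnonzero(assign == -1)
        if unass.size:
            sub = mat[unass]
            sub_ok = ok[unass]
            counts = np.zeros((unass.size, k), dtype=np.int64)
            for cid, codes in enumerate(cluster_sets):
                # a cluster smaller than W/2 l-mers can never host half of a
                # mate's windows, so scanning it cannot change any assignment
                if codes.size < W / 2:
                    continue
                inside = isin_sorted(sub.ravel(), codes).reshape(sub.shape) & sub_ok
                counts[:, cid] = inside.sum(axis=1)
            best = counts.argmax(axis=1)  # ties -> lowest cluster id
            hit = counts[np.arange(unass.size), best] >= W / 2
            if hit.any():
                assign[unass[hit]] = best[hit]
                newly[unass[hit]] = True
                changed = True
        # step 2: mate propagation
        unass = np.flatnonzero(assign == -1)
        partner = unass ^ 1
        prop = assign[partner] >= 0
        if prop.any():
            assign[unass[prop]] = assign[partner[prop]]
            newly[unass[prop]] = True
            changed = True
        # step 3: augment cluster l-mer sets with newly assigned reads' l-mers
        for cid in range(k):
            mates = np.flatnonzero(newly & (assign == cid))
            if mates.size == 0:
                continue
            codes = mat[mates][ok[mates]]
            # growth alone does not force another round; new assignments do
            cluster_sets[cid] = unique_sorted(np.concatenate([cluster_sets[cid], codes]))
        if not changed:
            break
    return ReadAssignment(reads.mate_ids(), assign, rounds)
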