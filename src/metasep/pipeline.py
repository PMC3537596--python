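"""End-to-end orchestration: load -> count -> abundance bins -> per-bin
phase 1 -> global cluster linkage -> per-bin MCL merging -> read assignment.

Phase 1 (l-mer classification and unique-l-mer clustering) runs separately
inside each abundance bin, so repeats of low-abundance genomes are detected
at their own depth.  Cluster linkage (repeat profiles and the weighted
cluster graph) is computed from *all* reads, but MCL and merging run on
each bin's clusters separately; the final clusters from all bins together
drive the read assignment.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._sorted import unique_sorted
from . import abundance as ab
from . import classify as cl
from . import phase1 as p1
from . import phase2 as p2
from .assignment import ReadAssignment, assign_reads
from .evaluate import EvaluationReport, evaluate_assignment
from .lmer_core import LmerCountTable, ReadPairSet, count_lmers, histogram

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline_on_reads", "run_pipeline"]


@dataclass
class RunConfig:
    """Tunables of the full pipeline; all recorded in the run manifest."""

    l: int = 20
    genome_size: float | None = None  # override for the total-size estimate
    T: int | None = None  # override for the expansion threshold
    K_err: int | None = None
    K_repeat: int | None = None
    mcl_schedule: tuple[float, ...] = p2.DEFAULT_R_SCHEDULE
    validity_eps: float = 1e-3
    validity_normalization: str = "geometric"
    min_big_size: int | None = None  # default: l-mer content of a 100 kb genome
    min_links: int = 3
    min_frozen_size: int = 10
    abundance_gate: float = 0.03
    no_abundance: bool = False
    max_bins: int = 8
    max_assign_rounds: int = 10
    seed: int = 0

    def resolved_min_big_size(self) -> int:
        if self.min_big_size is not None:
            return self.min_big_size
        return 100_000 - self.l + 1


@dataclass
class PipelineResult:
    assignment: ReadAssignment
    final_clusters: p1.Phase1Clusters
    report: EvaluationReport | None
    manifest: dict

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _phase1_for_bin(
    reads: ReadPairSet,
    config: RunConfig,
    bin_seed: int,
    manifest: dict,
    counts: LmerCountTable | None = None,
) -> tuple[p1.Phase1Clusters, cl.LmerPartition]:
    """Classify l-mers and cluster unique l-mers within one read bin."""
    l = config.l
    if counts is None:
        counts = count_lmers(reads, l)
    hist = histogram(counts)
    K_err = config.K_err if config.K_err is not None else cl.select_error_threshold(hist)
    lam_hat = cl.estimate_lambda(hist, K_err)
    K_repeat = (
        config.K_repeat
        if config.K_repeat is not None
        else cl.select_repeat_threshold(hist, lam_hat, K_err)
    )
    partition = cl.partition_lmers(counts, K_err, K_repeat, lam_hat)
    G = config.genome_size or cl.estimate_G(counts, partition, reads)
    graph = p1.build_graph(reads, partition)
    graph, partition = p1.prune_high_degree(graph, reads.L, l, partition)
    if config.T is not None:
        tsel = p1.TSelection(T=config.T, Cov=float("nan"), exp_gaps=float("nan"))
    else:
        tsel = p1.select_T(reads.N, reads.L, l, G)
    manifest.update(
        {
            "K_err": int(K_err),
            "K_repeat": int(K_repeat),
            "lam_hat": float(lam_hat),
            "G_estimate": float(G),
            "T": int(tsel.T),
            "exp_gaps": float(tsel.exp_gaps),
            "n_U": int(partition.U.size),
            "n_R": int(partition.R.size),
            "n_discarded": int(partition.discarded.size),
        }
    )
    if tsel.low_coverage:
        # degraded mode: too few reads to expand safely; one cluster per bin
        logger.warning("bin has insufficient coverage; emitting a single cluster")
        clusters = [partition.U.copy()]
        membership = np.zeros(partition.U.size, dtype=np.int64)
        win = p1._window_node_matrix(reads, partition.U, l)
        read_map = p1._map_reads(win, membership, 1)
        return (
            p1.Phase1Clusters(clusters=clusters, read_map=read_map, frozen=[False]),
            partition,
        )
    clusters = p1.expand_clusters(
        graph,
        reads,
        T=tsel.T,
        l=l,
        rng_seed=bin_seed,
        min_frozen_size=config.min_frozen_size,
    )
    clusters = p1.consolidate_paired(clusters, reads, min_links=config.min_links, l=l)
    manifest["n_phase1_clusters"] = clusters.n_clusters
    return clusters, partition


def run_pipeline_on_reads(
    reads: ReadPairSet,
    config: RunConfig | None = None,
    origin_mate_genomes: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full separation pipeline on an in-memory read set.

    ``origin_mate_genomes`` (one genome label per mate, interleaved) enables
    the evaluation report.
    """
    config = config or RunConfig()
    t0 = time.time()
    manifest: dict = {"config": asdict(config), "stages": {}}
    l = config.l

    counts = count_lmers(reads, l)
    manifest["n_distinct_lmers"] = len(counts)

    if config.no_abundance:
        bins = ab.AbundanceBins(
            pair_bins=[np.arange(reads.N, dtype=np.int64)],
            lam=[float("nan")],
            gate_rate=1.0,
            gated=False,
        )
    else:
        bins = ab.gate_and_bin(
            reads,
            counts,
            gate=config.abundance_gate,
            seed=config.seed,
            l=l,
            max_bins=config.max_bins,
        )
    manifest["abundance"] = {
        "gated": bins.gated,
        "gate_rate": bins.gate_rate,
        "n_bins": bins.n_bins,
        "bin_sizes": [int(p.size) for p in bins.pair_bins],
        "bin_lambda": bins.lam,
    }

    # phase 1 per bin
    all_clusters: list[np.ndarray] = []
    cluster_bin: list[int] = []
    global_map = np.full(reads.n_mates, -1, dtype=np.int64)
    partitions = []
    for b, pair_idx in enumerate(bins.pair_bins):
        whole = pair_idx.size == reads.N
        sub = reads if whole else reads.subset(pair_idx)
        bm: dict = {}
        clusters_b, part_b = _phase1_for_bin(
            sub, config, config.seed + 7 * b, bm, counts=counts if whole else None
        )
        manifest["stages"][f"bin{b}"] = bm
        offset = len(all_clusters)
        mate_global = np.empty(2 * pair_idx.size, dtype=np.int64)
        mate_global[0::2] = 2 * pair_idx
        mate_global[1::2] = 2 * pair_idx + 1
        assigned = clusters_b.read_map >= 0
        global_map[mate_global[assigned]] = clusters_b.read_map[assigned] + offset
        all_clusters.extend(clusters_b.clusters)
        cluster_bin.extend([b] * clusters_b.n_clusters)
        partitions.append(part_b)

    global_clusters = p1.Phase1Clusters(
        clusters=all_clusters,
        read_map=global_map,
        frozen=[False] * len(all_clusters),
    )
    # global partition: union of per-bin classes (for linkage and assignment)
    U_all = unique_sorted(np.concatenate([p.U for p in partitions]))
    R_all = unique_sorted(np.concatenate([p.R for p in partitions])) if any(
        p.R.size for p in partitions
    ) else np.empty(0, dtype=np.int64)
    disc_all = unique_sorted(np.concatenate([p.discarded for p in partitions])) if any(
        p.discarded.size for p in partitions
    ) else np.empty(0, dtype=np.int64)
    global_partition = cl.LmerPartition(
        l=l,
        U=U_all,
        R=R_all,
        discarded=disc_all,
        K_err=partitions[0].K_err,
        K_repeat=partitions[0].K_repeat,
        lam_hat=partitions[0].lam_hat,
    )

    # phase 2: linkage from all reads; MCL and merging per bin
    profile = p2.build_repeat_profile(global_clusters, reads, global_partition)
    F = p2.build_cluster_graph(profile)
    sizes = global_clusters.sizes()
    cluster_bin_arr = np.asarray(cluster_bin)
    final_clusters: list[np.ndarray] = []
    manifest["phase2"] = {}
    for b in range(bins.n_bins):
        idxs = np.flatnonzero(cluster_bin_arr == b)
        if idxs.size == 0:
            continue
        Fb = p2.ClusterGraphF(W=F.W[np.ix_(idxs, idxs)].copy())
        mres = p2.tune_granularity(
            Fb,
            cluster_sizes=sizes[idxs],
            min_big_size=config.resolved_min_big_size(),
            r_schedule=tuple(config.mcl_schedule),
            eps=config.validity_eps,
            normalization=config.validity_normalization,
        )
        manifest["phase2"][f"bin{b}"] = {
            "r": mres.r,
            "accepted": mres.accepted,
            "n_m_clusters": len(mres.m_clusters),
            "n_big": len(mres.big),
            "n_valid": len(mres.valid),
        }
        for grp in mres.m_clusters:
            final_clusters.append(
                unique_sorted(np.concatenate([all_clusters[idxs[i]] for i in grp]))
            )

    final = p1.Phase1Clusters(
        clusters=final_clusters,
        read_map=np.full(reads.n_mates, -1, dtype=np.int64),
        frozen=[False] * len(final_clusters),
    )
    assignment = assign_reads(
        reads, final, global_partition, max_rounds=config.max_assign_rounds
    )
    manifest["n_final_clusters"] = len(final_clusters)
    manifest["final_cluster_lmers"] = [int(c.size) for c in final_clusters]
    manifest["n_assigned_mates"] = assignment.n_assigned
    manifest["iterations_run"] = assignment.iterations_run

    report = None
    if origin_mate_genomes is not None:
        report = evaluate_assignment(assignment, origin_mate_genomes)
        manifest["evaluation"] = {
            "separability": report.separability,
            "broken": sorted(report.broken),
            "mean_sensitivity": report.mean_sensitivity,
            "mean_precision": report.mean_precision,
        }
    manifest["runtime_s"] = round(time.time() - t0, 2)
    return PipelineResult(
        assignment=assignment,
        final_clusters=final,
        report=report,
        manifest=manifest,
    )


def run_pipeline(
    path1: str | Path,
    path2: str | Path | None,
    fmt: str = "fastq",
    config: RunConfig | None = None,
    truth_tsv: str | Path | None = None,
) -> PipelineResult:
    """File-level entry point: load reads (and optional truth) and run."""
    from .lmer_core import load_reads

    reads = load_reads(path1, path2, fmt=fmt)
    origin = None
    if truth_tsv is not None:
        genome_of: dict[str, str] = {}
        with open(truth_tsv) as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                genome_of[parts[0]] = parts[1]
        labels = sorted(set(genome_of.values()))
        lab_idx = {g: i for i, g in enumerate(labels)}
        origin = np.array(
            [lab_idx[genome_of[rid]] for rid in reads.ids for _ in (0, 1)],
            dtype=np.int64,
        )
    return run_pipeline_on_reads(reads, config, origin)
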