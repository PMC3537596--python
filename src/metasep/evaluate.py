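"""Evaluation of a read clustering against truth labels.

A genome maps to the cluster holding *more than half* of its reads; a
genome with no such cluster is *broken* and excluded from separability.
Separability is the fraction of unordered pairs of non-broken genomes whose
mapped clusters differ.  Per-cluster sensitivity is the unweighted mean
over the genomes mapped to the cluster of (reads of the genome in the
cluster / all reads of the genome) — unweighted so a small genome sharing a
cluster with a large one still counts fully.  Per-cluster precision is
reported as the correct fraction, 1 - (wrongly assigned reads / reads in
the cluster); unassigned reads count against sensitivity but are in no
cluster, so they do not enter precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import ReadAssignment

__all__ = [
    "EvaluationReport",
    "map_genomes",
    "separability",
    "sensitivity_precision",
    "evaluate_assignment",
]


@dataclass
class EvaluationReport:
    """Summary of clustering quality against truth labels."""

    genome_to_cluster: dict[int, int]
    broken: set[int]
    separability: float | None
    per_cluster: pd.DataFrame
    mean_sensitivity: float
    std_sensitivity: float
    mean_precision: float
    std_precision: float

    def summary(self) -> str:
        sep = "NA" if self.separability is None else f"{100 * self.separability:.1f}%"
        return (
            f"genomes: {len(self.genome_to_cluster) + len(self.broken)} "
            f"({len(self.broken)} broken); separability: {sep}; "
            f"sensitivity: {100 * self.mean_sensitivity:.2f} "
            f"(sd {100 * self.std_sensitivity:.2f}); "
            f"precision: {100 * self.mean_precision:.2f} "
            f"(sd {100 * self.std_precision:.2f})"
        )


def map_genomes(
    assign: np.ndarray, origin: np.ndarray
) -> tuple[dict[int, int], set[int]]:
    """Map each genome to the cluster holding > 1/2 of its reads.

    ``assign`` and ``origin`` are parallel per-read arrays (cluster id or -1;
    genome id).  Genomes without a majority cluster are *broken* — strictly
    more than half is required.  Several genomes may map to one cluster.
    """
    assign = np.asarray(assign)
    origin = np.asarray(origin)
    mapping: dict[int, int] = {}
    broken: set[int] = set()
    for g in np.unique(origin):
        sel = origin == g
        total = int(sel.sum())
        clustered = assign[sel]
        clustered = clustered[clustered >= 0]
        if clustered.size:
            vals, cnts = np.unique(clustered, return_counts=True)
            best = int(cnts.argmax())
            if cnts[best] > total / 2:
                mapping[int(g)] = int(vals[best])
                continue
        broken.add(int(g))
    return mapping, broken


def separability(mapping: dict[int, int], broken: set[int]) -> float | None:
    """Fraction of non-broken genome pairs mapped to different clusters."""
    genomes = sorted(mapping)
    if len(genomes) < 2:
        return None
    total = 0
    separated = 0
    for a in range(len(genomes)):
        for b in range(a + 1, len(genomes)):
            total += 1
            if mapping[genomes[a]] != mapping[genomes[b]]:
                separated += 1
    return separated / total


def sensitivity_precision(
    assign: np.ndarray,
    origin: np.ndarray,
    mapping: dict[int, int],
) -> pd.DataFrame:
    """Per-cluster sensitivity (unweighted over genomes) and precision."""
    assign = np.asarray(assign)
    origin = np.asarray(origin)
    rows = []
    clusters = sorted(set(mapping.values()))
    for c in clusters:
        genomes = [g for g, cc in mapping.items() if cc == c]
        in_cluster = assign == c
        n_in = int(in_cluster.sum())
        if n_in == 0:
            continue
        sens = [
            float((in_cluster & (origin == g)).sum() / max((origin == g).sum(), 1))
            for g in genomes
        ]
        own = np.isin(origin, genomes)
        wrong = int((in_cluster & ~own).sum())
        rows.append(
            {
                "cluster": c,
                "genomes": ",".join(str(g) for g in genomes),
                "n_reads": n_in,
                "sensitivity": float(np.mean(sens)),
                "wrong_ratio": wrong / n_in,
                "precision": 1.0 - wrong / n_in,
            }
        )
    return pd.DataFrame(rows)


def evaluate_assignment(
    assignment: ReadAssignment | np.ndarray, origin: np.ndarray
) -> EvaluationReport:
    """Full report: genome map, separability, per-cluster metrics."""
    assign = (
        assignment.assign if isinstance(assignment, ReadAssignment) else assignment
    )
    mapping, broken = map_genomes(assign, origin)
    sep = separability(mapping, broken)
    per_cluster = sensitivity_precision(assign, origin, mapping)
    if len(per_cluster):
        ms, ss = per_cluster["sensitivity"].mean(), per_cluster["sensitivity"].std(ddof=0)
        mp, sp = per_cluster["precision"].mean(), per_cluster["precision"].std(ddof=0)
    else:
        ms = ss = mp = sp = float("nan")
    return EvaluationReport(
        genome_to_cluster=mapping,
        broken=broken,
        separability=sep,
        per_cluster=per_cluster,
        mean_sensitivity=float(ms),
        std_sensitivity=float(ss),
        mean_precision=float(mp),
        std_precision=float(sp),
    )
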