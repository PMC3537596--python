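"""Synthetic metagenome communities with planted repeat structure.

Stand-in for a read simulator such as MetaSim: genomes are i.i.d.-uniform
random circular sequences with repeats planted by copying segments, and
paired-end reads are sampled under the Lander-Waterman model (uniform
fragment starts, so the number of reads covering a fixed l-mer is Poisson).

Repeat vocabulary (matching the separation algorithm's):

* *unique* l-mer — one copy across all genomes of the community;
* *individual repeat* — several copies, all in one genome;
* *common repeat* — copies in two or more genomes (the main obstacle to
  separating genomes).

Every read carries a truth label (source genome, position, strand) and the
planted l-mer classes are recomputed from the final genome sequences by
exact counting, so they are valid even where planted units collide.

Defaults mirror short-insert Illumina libraries: 80 bp reads, insert
(fragment) length ~ Normal(500, 20), substitution errors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._sorted import unique_counts, unique_sorted
from .lmer_core import ReadPairSet, window_codes

__all__ = [
    "CommunitySpec",
    "CommunityTruth",
    "ReadOrigin",
    "synthesize_community",
    "sample_reads",
    "lmer_observation_stats",
    "write_community",
]

LMER_UNIQUE = 0
LMER_INDIVIDUAL = 1
LMER_COMMON = 2
_CLASS_NAMES = {LMER_UNIQUE: "unique", LMER_INDIVIDUAL: "individual", LMER_COMMON: "common"}


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community.

    ``coverage`` is the *effective* per-l-mer coverage lambda at l-mer length
    ``l`` for an abundance-1 genome; a genome with abundance multiplier ``a``
    is sequenced at effective coverage ``a * coverage``.

    ``individual_repeat_fraction[j]`` is the fraction of genome j's length
    duplicated within genome j (so the total repeat content, counting both
    copies, is about twice that).  ``common_repeat_fraction[(i, j)]`` is the
    fraction of genome j's length overwritten by segments copied from genome
    i.  Copies are placed on a non-overlapping grid of ``repeat_unit_length``
    slots.
    """

    genome_lengths: list[int]
    abundances: list[float] | None = None
    individual_repeat_fraction: float | list[float] = 0.0
    common_repeat_fraction: float | dict[tuple[int, int], float] = 0.0
    repeat_unit_length: int = 400
    L: int = 80
    insert_mean: float = 500.0
    insert_sd: float = 20.0
    error_rate: float = 0.0
    error_ramp: float = 0.0  # added to error_rate linearly toward the 3' end
    coverage: float = 20.0
    l: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.genome_lengths = [int(g) for g in self.genome_lengths]
        if self.abundances is None:
            self.abundances = [1.0] * len(self.genome_lengths)
        if len(self.abundances) != len(self.genome_lengths):
            raise ValueError("abundances must match genome_lengths")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for g in self.genome_lengths:
            if g <= 2 * self.insert_mean:
                raise ValueError(
                    f"genome length {g} must exceed twice the insert mean "
                    f"({self.insert_mean})"
                )
        for f in self.indiv_fractions() + list(self.common_fractions().values()):
            if not 0 <= f < 1:
                raise ValueError(f"repeat fraction {f} outside [0, 1)")
        if not 0 <= self.error_rate < 1 or self.error_ramp < 0:
            raise ValueError("invalid error model")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_lengths)

    def indiv_fractions(self) -> list[float]:
        f = self.individual_repeat_fraction
        if isinstance(f, (int, float)):
            return [float(f)] * self.n_genomes
        if len(f) != self.n_genomes:
            raise ValueError("per-genome repeat fractions must match genome count")
        return [float(x) for x in f]

    def common_fractions(self) -> dict[tuple[int, int], float]:
        f = self.common_repeat_fraction
        if isinstance(f, (int, float)):
            if float(f) == 0.0:
                return {}
            return {
                (i, j): float(f)
                for i in range(self.n_genomes)
                for j in range(self.n_genomes)
                if i < j
            }
        return {tuple(k): float(v) for k, v in f.items()}


@dataclass
class ReadOrigin:
    """Truth labels of sampled read pairs (arrays indexed by pair)."""

    genome: np.ndarray  # int32, source genome index
    pos: np.ndarray  # int64, fragment start (0-based, on the forward strand)
    strand: np.ndarray  # int8, +1 or -1: strand of mate 1

    def mate_genomes(self) -> np.ndarray:
        """Genome label per mate, interleaved (2N,)."""
        return np.repeat(self.genome, 2)


@dataclass
class CommunityTruth:
    """Synthesized genomes plus exact l-mer truth classes."""

    spec: CommunitySpec
    genomes: list[np.ndarray]  # 2-bit base codes, circular
    lmer_codes: np.ndarray = field(default=None)  # sorted distinct canonical codes
    lmer_class: np.ndarray = field(default=None)  # int8 class per code
    copy_counts: np.ndarray = field(default=None)  # (n_genomes, n_distinct) copies

    def genome_strings(self) -> list[str]:
        return ["".join("ACGT"[b] for b in g) for g in self.genomes]

    def class_of(self, query: np.ndarray) -> np.ndarray:
        """Truth class for an array of canonical codes (-1 where unknown)."""
        pos = np.searchsorted(self.lmer_codes, query)
        pos = np.clip(pos, 0, len(self.lmer_codes) - 1)
        hit = self.lmer_codes[pos] == query
        return np.where(hit, self.lmer_class[pos], -1).astype(np.int8)

    def codes_of_class(self, cls: int) -> np.ndarray:
        return self.lmer_codes[self.lmer_class == cls]


def _circular_window_codes(genome: np.ndarray, l: int) -> np.ndarray:
    """Canonical codes of all G windows of a circular genome."""
    ext = np.concatenate([genome, genome[: l - 1]])
    codes, valid = window_codes(ext, l)
    return codes[valid]


def _count_truth(genomes: list[np.ndarray], l: int):
    """Exact per-genome copy counts and classes of all distinct l-mers."""
    per_genome = [_circular_window_codes(g, l) for g in genomes]
    all_codes = unique_sorted(np.concatenate(per_genome))
    copy = np.zeros((len(genomes), all_codes.shape[0]), dtype=np.int32)
    for j, codes in enumerate(per_genome):
        u, c = unique_counts(codes)
        pos = np.searchsorted(all_codes, u)
        copy[j, pos] = c
    total = copy.sum(axis=0)
    presence = (copy > 0).sum(axis=0)
    cls = np.full(all_codes.shape[0], LMER_UNIQUE, dtype=np.int8)
    cls[(total > 1) & (presence == 1)] = LMER_INDIVIDUAL
    cls[presence > 1] = LMER_COMMON
    return all_codes, cls, copy


def synthesize_community(spec: CommunitySpec) -> CommunityTruth:
    """Generate genomes with planted repeats and exact l-mer truth classes.

    Individual repeats: for each genome, segments of ``repeat_unit_length``
    are copied onto other (disjoint) grid slots of the same genome.  Common
    repeats: segments of genome i overwrite grid slots of genome j.  Slots
    are drawn without replacement, so planted units never overlap each other.
    """
    rng = np.random.default_rng(spec.seed)
    genomes = [
        rng.integers(0, 4, size=g, dtype=np.uint8) for g in spec.genome_lengths
    ]
    u = spec.repeat_unit_length
    # per-genome shuffled grid of non-overlapping slots
    slot_pools = []
    for g in spec.genome_lengths:
        slots = np.arange(g // u) * u
        rng.shuffle(slots)
        slot_pools.append(list(slots))

    def take_slots(j: int, n: int) -> list[int]:
        pool = slot_pools[j]
        if len(pool) < n:
            raise ValueError(
                f"genome {j}: repeat fractions too high to place {n} "
                f"non-overlapping units of {u} bp"
            )
        return [pool.pop() for _ in range(n)]

    for j, frac in enumerate(spec.indiv_fractions()):
        n_units = int(round(frac * spec.genome_lengths[j] / u))
        if n_units == 0:
            continue
        donors = take_slots(j, n_units)
        dests = take_slots(j, n_units)
        for d, t in zip(donors, dests):
            genomes[j][t : t + u] = genomes[j][d : d + u]
    for (i, j), frac in spec.common_fractions().items():
        n_units = int(round(frac * spec.genome_lengths[j] / u))
        if n_units == 0:
            continue
        donors = take_slots(i, n_units)
        dests = take_slots(j, n_units)
        for d, t in zip(donors, dests):
            genomes[j][t : t + u] = genomes[i][d : d + u]

    codes, cls, copy = _count_truth(genomes, spec.l)
    return CommunityTruth(
        spec=spec, genomes=genomes, lmer_codes=codes, lmer_class=cls, copy_counts=copy
    )


def _apply_errors(bases: np.ndarray, spec: CommunitySpec, rng) -> np.ndarray:
    """Substitution errors, optionally ramping linearly toward the 3' end."""
    if spec.error_rate == 0 and spec.error_ramp == 0:
        return bases
    L = bases.shape[1]
    rate = spec.error_rate + spec.error_ramp * (np.arange(L) / max(L - 1, 1))
    hit = rng.random(bases.shape) < rate[None, :]
    shift = rng.integers(1, 4, size=bases.shape, dtype=np.uint8)
    out = bases.copy()
    out[hit] = (out[hit] + shift[hit]) % 4
    return out


def sample_reads(
    truth: CommunityTruth, spec: CommunitySpec | None = None
) -> tuple[ReadPairSet, ReadOrigin]:
    """Sample paired-end reads at the spec's effective coverage.

    The number of pairs per genome is set so that the effective per-l-mer
    coverage equals ``coverage * abundance``: on a circular genome of length
    G, lambda = 2 N (L - l + 1) / G.  Fragment starts are uniform; fragment
    length ~ Normal(insert_mean, insert_sd) truncated at L; mate 1 is the 5'
    end of the fragment on a uniformly random strand and mate 2 the reverse
    complement of the 3' end.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed + 1)
    L, l = spec.L, spec.l
    per_genome_N = [
        max(1, int(round(spec.coverage * a * g / (2 * (L - l + 1)))))
        for g, a in zip(spec.genome_lengths, spec.abundances)
    ]
    gen_idx = np.repeat(np.arange(spec.n_genomes, dtype=np.int32), per_genome_N)
    N = gen_idx.shape[0]
    frag = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=N)).astype(np.int64)
    frag = np.maximum(frag, L)
    glen = np.asarray(spec.genome_lengths, dtype=np.int64)[gen_idx]
    start = (rng.random(N) * glen).astype(np.int64)
    strand = np.where(rng.random(N) < 0.5, 1, -1).astype(np.int8)

    offs = np.arange(L, dtype=np.int64)
    m1 = np.empty((N, L), dtype=np.uint8)
    m2 = np.empty((N, L), dtype=np.uint8)
    for j, g in enumerate(truth.genomes):
        sel = np.flatnonzero(gen_idx == j)
        if sel.size == 0:
            continue
        G = g.shape[0]
        left = g[(start[sel, None] + offs[None, :]) % G]
        right_start = start[sel] + frag[sel] - L
        right = g[(right_start[:, None] + offs[None, :]) % G]
        right_rc = (3 - right)[:, ::-1]
        fwd = strand[sel] == 1
        m1[sel[fwd]] = left[fwd]
        m2[sel[fwd]] = right_rc[fwd]
        # on the minus strand the fragment is sequenced from its 3' end
        m1[sel[~fwd]] = right_rc[~fwd]
        m2[sel[~fwd]] = left[~fwd]

    m1 = _apply_errors(m1, spec, rng)
    m2 = _apply_errors(m2, spec, rng)

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    mates1 = [bytes(lut[row]).decode() for row in m1]
    mates2 = [bytes(lut[row]).decode() for row in m2]
    ids = [f"r{k}" for k in range(N)]
    reads = ReadPairSet(ids=ids, mates1=mates1, mates2=mates2, L=L)
    origin = ReadOrigin(genome=gen_idx, pos=start, strand=strand)
    return reads, origin


def simulate(spec: CommunitySpec) -> tuple[CommunityTruth, ReadPairSet, ReadOrigin]:
    """Convenience: synthesize a community and sample reads from it."""
    truth = synthesize_community(spec)
    reads, origin = sample_reads(truth, spec)
    return truth, reads, origin


def lmer_observation_stats(truth: CommunityTruth, l: int | None = None) -> dict:
    """Per-genome and community-wide l-mer uniqueness statistics.

    Returns exact counts of distinct/unique/total l-mers per genome and for
    the community, the fraction of l-mers that lose uniqueness to common
    repeats, 1 - n_uniq / sum_j n_j_uniq, and per-genome common-repeat
    fractions (distinct common l-mers of genome j / distinct l-mers of j).
    """
    if l is None or l == truth.spec.l:
        codes, cls, copy = truth.lmer_codes, truth.lmer_class, truth.copy_counts
    else:
        codes, cls, copy = _count_truth(truth.genomes, l)
    S = copy.shape[0]
    present = copy > 0
    per_genome = []
    for j in range(S):
        pj = present[j]
        n_dist = int(pj.sum())
        n_tot = int(copy[j].sum())
        n_uniq_within = int((copy[j] == 1).sum())
        n_common = int((pj & (cls == LMER_COMMON)).sum())
        per_genome.append(
            {
                "n_dist": n_dist,
                "n_tot": n_tot,
                "n_uniq_within": n_uniq_within,
                "n_common": n_common,
                "common_fraction": n_common / n_dist if n_dist else 0.0,
            }
        )
    n_uniq = int((cls == LMER_UNIQUE).sum())
    sum_uniq_within = sum(g["n_uniq_within"] for g in per_genome)
    return {
        "n_dist": int(codes.shape[0]),
        "n_uniq": n_uniq,
        "n_individual": int((cls == LMER_INDIVIDUAL).sum()),
        "n_common": int((cls == LMER_COMMON).sum()),
        "lost_unique_fraction": (
            1.0 - n_uniq / sum_uniq_within if sum_uniq_within else 0.0
        ),
        "per_genome": per_genome,
    }


def write_community(
    truth: CommunityTruth,
    reads: ReadPairSet,
    origin: ReadOrigin,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genomes (FASTA), reads (paired FASTQ) and truth tables (TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genomes"] = outdir / "genomes.fasta"
    with open(paths["genomes"], "w") as fh:
        for j, s in enumerate(truth.genome_strings()):
            fh.write(f">genome{j}\n")
            for k in range(0, len(s), 80):
                fh.write(s[k : k + 80] + "\n")
    for mate in (1, 2):
        p = outdir / f"reads_{mate}.fastq"
        paths[f"reads_{mate}"] = p
        seqs = reads.mates1 if mate == 1 else reads.mates2
        with open(p, "w") as fh:
            for rid, s in zip(reads.ids, seqs):
                fh.write(f"@{rid}/{mate}\n{s}\n+\n{'I' * len(s)}\n")
    paths["read_truth"] = outdir / "read_truth.tsv"
    with open(paths["read_truth"], "w") as fh:
        fh.write("read_id\tgenome\tpos\tstrand\n")
        for rid, g, p, s in zip(reads.ids, origin.genome, origin.pos, origin.strand):
            fh.write(f"{rid}\tgenome{g}\t{p}\t{'+' if s > 0 else '-'}\n")
    paths["lmer_truth"] = outdir / "lmer_truth.tsv"
    from .lmer_core import decode_lmer

    with open(paths["lmer_truth"], "w") as fh:
        fh.write("lmer\tclass\n")
        for c, k in zip(truth.lmer_codes, truth.lmer_class):
            fh.write(f"{decode_lmer(int(c), truth.spec.l)}\t{_CLASS_NAMES[int(k)]}\n")
    return paths
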