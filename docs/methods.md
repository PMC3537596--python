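# Methods

## Model

Reads are modeled by the Lander–Waterman process: read start positions are
uniform, so the number of reads covering any fixed locus is Poisson. For N
pairs of length L and a genome of length G, a single-copy l-mer is covered
by x(w) ~ Poisson(λ), λ = α(L − l + 1) with α = 2N/(G − L + 1); an l-mer
with n copies (possibly spread over several genomes with per-genome depths
λ_j) counts at Σ_j λ_j n_j(w). Everything in the pipeline — error
filtering, the unique/repeat split, the expansion threshold T, genome-size
estimation, and abundance binning — derives from this model.

Three empirical facts about bacterial genomes motivate the design: almost
all 20-mers of a genome are single-copy; in a community of sufficiently
distant species almost all 20-mers remain unique community-wide; and most
repeats are genome-specific rather than shared. Separation quality
therefore degrades with the fraction of *common* repeats (shared between
genomes), which is the operative variable that phylogenetic closeness
controls.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| l | 20 | l-mer length; large enough that random 20-mer collisions are negligible (4²⁰ ≫ community size), small enough that an 80 bp read carries 61 windows |
| K_err | first histogram valley | counts below it are error artifacts; 1 (no filtering) when the histogram rises from its first bin |
| λ̂ | histogram mode above K_err | single-copy Poisson mean; a truncated-Poisson MLE refinement exists (`refine_lambda_mle`) but the mode is the default |
| K_repeat | sustained 2× rule | smallest count > λ̂ where observed n(i) ≥ 2·y(i) for two consecutive counts, y(i) the Poisson(λ̂) pmf scaled to match the peak; the two-bin guard suppresses single-bin noise |
| T | largest T with 2N·e^(−Cov(T)) < 1 | minimum in-cluster neighbors to join a growing cluster; Cov(T) = 2N(L−(l+T)+1)/(G−L+1) |
| degree bound | 2(L − l) = 120 | maximum possible neighbor count of a truly unique l-mer; pruning above it removes undetected repeats |
| growth cap | 2(L−(l+T)+1) | largest possible one-step frontier for a single locus; exceeding it freezes the cluster (repeat signature) |
| min_links | 3 | read pairs required to consolidate two phase-1 clusters; one chimeric pair must not merge genomes |
| MCL inflation schedule | 5.0 … 1.2 (descending) | granularity tuning; expansion 2, tol 1e-6, max 200 iterations, per-entry pruning at 1e-8, self-loops = max incident weight |
| validity ε | 1e-3 | a big m-cluster is valid when W_ij/√(W_ii·W_jj) ≤ ε against every other big m-cluster; W_ij/(W_ii·W_jj) available as a config alternative |
| min_big_size | l-mer content of 100 kb | user's smallest expected genome; decides which m-clusters count as "big" |
| abundance gate | 3% | maximum acceptable expected l-mer misclassification rate for an abundance split |

## Numerical and procedural choices

* **Canonical (strand-merged) l-mers.** Reads come from both strands;
  forward-only counting would halve the per-orientation coverage and break
  the λ = α(L−l+1) calibration. l-mers are 2-bit packed into int64 (l ≤ 31).
* **Mode ties** (Poisson with integer λ has two modes) break toward the
  larger count.
* **Validity direction.** The acceptance condition for an inflation value is
  *separation*: every big m-cluster's normalized inter-weight must stay at
  or below ε. Zero inter-weight always counts as separated; positive
  inter-weight with zero intra-weight never does. The m-cluster intra
  weight is the total weight of F-edges inside the m-cluster.
* **Expansion details.** Candidates join all at once per iteration (the cap
  formula counts both read ends); a frozen cluster below 10 l-mers is
  dissolved back to unclustered; seed reads are drawn by a seeded RNG and a
  seed read leaves the pool once used, guaranteeing termination. Clusters
  are relabeled by size for determinism.
* **Read correspondence** uses the real-valued threshold (L−l+1)/2: with 61
  windows a mate needs ≥ 31 inside the cluster.
* **Assignment augmentation persists across rounds**, so cluster l-mer sets
  and the assigned read set grow monotonically; a read corresponding to
  several clusters takes the largest-fraction one, ties to the lowest id.
* **Genome-size estimate** G ≈ |U| + Σ_{w∈R} round(x(w)/λ̂) + l − 1 feeds
  the T selection when the user gives no --genome-size.
* **Abundance binning** fits the mixture to error-filtered counts of
  distinct l-mers (each weighted equally), estimates component genome sizes
  from mixture weights, scans K exactly over 1…⌈λ₂+6√λ₂⌉ for the minimum
  expected misclassification, and splits recursively while the gate passes.
  A component carrying < 5% of the l-mers is rejected as spurious: a sliver
  can pass a *rate* gate simply by being small, not by being separable.
* **Degraded bins.** A bin too shallow for safe expansion (expected gaps ≥ 1
  even at T = 1) is emitted as a single cluster with a warning.

## The synthetic-data generator

`simdata` emulates a paired-end Illumina metagenome simulator: genomes are
i.i.d.-uniform random *circular* sequences (bacterial chromosomes are
circular; this also removes coverage edge effects, so the Poisson model
holds exactly at every position). Repeats are planted by copying
`repeat_unit_length` (400 bp) segments on a non-overlapping grid — within a
genome for individual repeats, across genomes for common repeats — and the
truth classes are recomputed from the final sequences by exact counting, so
collisions and junction effects are labeled correctly. Reads: fragment
length ~ Normal(500, 20) truncated at L = 80, uniform starts, random
strand, substitution errors at a uniform rate with an optional linear 3'
ramp. Everything is deterministic under the spec seed.

What the generator does *not* emulate: real genomic composition (GC skew,
coding structure), repeat families at copy number > 2, indels, quality
scores, and the long-tailed repeat spectra of real bacteria. A green
end-to-end test therefore establishes that the machinery separates genomes
whose only structure is the planted repeat content at the stated rates —
not performance on real communities, where common-repeat fractions vary
continuously with phylogenetic distance.

## Statistical notes

* Counts of *overlapping* l-mers share covering reads and are strongly
  correlated; a chi-square goodness-of-fit over all of them is wildly
  anti-conservative. The Poisson-fidelity check therefore tests l-mers
  spaced more than L apart (disjoint covering read sets, hence independent
  counts), pooled across simulation replicates to reach the target sample
  size.
* At small scales (~20 kb) the histogram mode can miss λ by 2, which makes
  the 2× rule fire early and punch false-repeat holes into U; phase-1 then
  fragments and paired-end consolidation plus MCL merging repair it. At
  ≥100 kb the mode is accurate and K_repeat lands between λ and 2λ.

## Known limitations

* Common repeats shared by two genomes at even a few percent of genome
  length create strong inter-genome linkage; granularity tuning then merges
  the genomes (they are "not separated") — consistent with the method's
  stated domain: genomes separable when common repeats are rarer than
  genome-specific ones.
* Exact in-memory counting and an explicit co-occurrence graph target
  desk-scale data (tens of Mb of genome); there is no disk-based or
  sketched counting path.
* End-to-end test scales: the acceptance suite runs the two-genome
  benchmarks at 50–100 kb genomes instead of 0.5 Mb to fit a CPU-minute
  budget; coverage, repeat fractions, error rates and all pass thresholds
  are unchanged. Per-criterion pass fractions were measured at this scale.
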