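"""Abundance-based pre-binning of reads via a Poisson mixture on l-mer counts.

When the community mixes genomes of very different sequencing depths, the
count histogram is a mixture of Poisson distributions (one component per
abundance level, weighted by genome size).  Fitting the mixture by EM and
thresholding counts at the crossover K splits l-mers — and then reads, by
majority vote over their l-mers — into abundance bins before the unique
l-mer clustering runs per bin.

The split is only applied when it is safe: the expected fraction of
misclassified l-mers at the optimal K,

    [G2 P(X2 <= K-1) + G1 P(X1 >= K)] / (G1 + G2),  X_j ~ Poisson(lambda_j),

must not exceed the gate (3% by default).  Nearby abundances (ratio ~1:2)
fail the gate and are left to the core algorithm, which tolerates them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .lmer_core import LmerCountTable, ReadPairSet, count_lmers, histogram
from .classify import select_error_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "PoissonMixtureFit",
    "AbundanceBins",
    "fit_poisson_mixture",
    "expected_misclassification",
    "optimal_split_K",
    "gate_and_bin",
    "run_integrated",
]


@dataclass
class PoissonMixtureFit:
    """EM fit of a k-component Poisson mixture to l-mer counts.

    ``lam`` is sorted ascending; ``weight`` are the mixture weights (the
    share of distinct l-mers per component, a proxy for relative genome
    size).  ``responsibilities[i, j]`` is the posterior of component j for
    the i-th distinct l-mer (aligned with the count table's codes).
    """

    k: int
    lam: np.ndarray
    weight: np.ndarray
    loglik: float
    responsibilities: np.ndarray
    n_obs: int
    loglik_path: list[float] = field(default_factory=list)


def fit_poisson_mixture(
    counts: LmerCountTable | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> PoissonMixtureFit:
    """Fit a k-component Poisson mixture to the observed counts by EM.

    Observations are the counts of the distinct l-mers, weighted equally.
    Components are initialised at quantiles of the counts with a small
    seeded perturbation; a component whose weight collapses below 1e-6 is
    dropped and the fit restarts with k - 1 components.
    """
    x = counts.counts if isinstance(counts, LmerCountTable) else np.asarray(counts)
    if k < 1:
        raise ValueError("k must be >= 1")
    vals, mult = np.unique(x, return_counts=True)
    if vals.size < k:
        raise ValueError(f"need >= {k} distinct count values, have {vals.size}")
    n = float(mult.sum())
    if k == 1:
        lam = np.array([float((vals * mult).sum() / n)])
        ll = float((mult * stats.poisson.logpmf(vals, lam[0])).sum())
        resp_vals = np.ones((vals.size, 1))
    else:
        rng = np.random.default_rng(seed)
        q = np.quantile(np.repeat(vals, mult), (np.arange(k) + 0.5) / k)
        lam = np.maximum(q * (1 + 0.05 * rng.standard_normal(k)), 0.1)
        w = np.full(k, 1.0 / k)
        ll = -np.inf
        path = []
        for _ in range(max_iter):
            logp = stats.poisson.logpmf(vals[:, None], lam[None, :]) + np.log(w)[None, :]
            norm = logsumexp(logp, axis=1)
            resp_vals = np.exp(logp - norm[:, None])
            new_ll = float((mult * norm).sum())
            wsum = (mult[:, None] * resp_vals).sum(axis=0)
            if (wsum / n < 1e-6).any():
                keep = wsum / n >= 1e-6
                logger.warning(
                    "mixture component collapsed; refitting with k=%d", int(keep.sum())
                )
                return fit_poisson_mixture(
                    x, int(keep.sum()), seed=seed, max_iter=max_iter, tol=tol
                )
            w = wsum / n
            lam = (mult[:, None] * resp_vals * vals[:, None]).sum(axis=0) / wsum
            lam = np.maximum(lam, 1e-9)
            path.append(new_ll)
            if np.isfinite(ll) and abs(new_ll - ll) < tol:
                ll = new_ll
                break
            ll = new_ll
        order = np.argsort(lam)
        lam = lam[order]
        w = w[order]
        resp_vals = resp_vals[:, order]
    if k == 1:
        w = np.array([1.0])
        path = [ll]
    # expand responsibilities from distinct count values to distinct l-mers
    if isinstance(counts, LmerCountTable):
        idx = np.searchsorted(vals, counts.counts)
        resp = resp_vals[idx]
        n_obs = len(counts)
    else:
        idx = np.searchsorted(vals, x)
        resp = resp_vals[idx]
        n_obs = x.size
    return PoissonMixtureFit(
        k=lam.size,
        lam=lam,
        weight=w,
        loglik=ll,
        responsibilities=resp,
        n_obs=n_obs,
        loglik_path=path,
    )


def expected_misclassification(
    lam1: float, lam2: float, G1: float, G2: float, K: int
) -> float:
    """Expected misclassified-l-mer rate of the count threshold K.

    l-mers with counts < K go to the low-abundance genome, >= K to the
    high-abundance one; the expected error mass is G2 P(X2 <= K-1) +
    G1 P(X1 >= K), normalised by G1 + G2 to a rate in [0, 1].
    """
    if not lam1 < lam2:
        raise ValueError(f"need lam1 < lam2, got {lam1}, {lam2}")
    if G1 <= 0 or G2 <= 0 or K < 1:
        raise ValueError("G1, G2 must be positive and K >= 1")
    err = G2 * stats.poisson.cdf(K - 1, lam2) + G1 * stats.poisson.sf(K - 1, lam1)
    return float(err / (G1 + G2))


def optimal_split_K(lam1: float, lam2: float, G1: float, G2: float) -> int:
    """K minimising the expected misclassification (exact scan)."""
    kmax = int(np.ceil(lam2 + 6 * np.sqrt(lam2))) + 1
    ks = np.arange(1, kmax + 1)
    err = G2 * stats.poisson.cdf(ks - 1, lam2) + G1 * stats.poisson.sf(ks - 1, lam1)
    return int(ks[err.argmin()])


@dataclass
class AbundanceBins:
    """Read bins by abundance; a single bin when the gate refuses to split.

    ``pair_bins[b]`` are pair indices of bin b; ``lam[b]`` its abundance
    estimate; ``gate_rate`` the expected misclassification rate of the
    first (top-level) split; ``gated`` whether any split was applied.
    """

    pair_bins: list[np.ndarray]
    lam: list[float]
    gate_rate: float
    gated: bool

    @property
    def n_bins(self) -> int:
        return len(self.pair_bins)


def _split_once(
    reads: ReadPairSet,
    pair_idx: np.ndarray,
    counts: LmerCountTable,
    gate: float,
    seed: int,
):
    """Try one binary abundance split; (None, rate) if the gate refuses."""
    hist = histogram(counts)
    K_err = select_error_threshold(hist)
    kept = counts.counts >= K_err
    if int(np.unique(counts.counts[kept]).size) < 2:
        return None, 1.0
    filt = LmerCountTable(l=counts.l, codes=counts.codes[kept], counts=counts.counts[kept])
    fit = fit_poisson_mixture(filt, k=2, seed=seed)
    if fit.k < 2:
        return None, 1.0
    lam1, lam2 = float(fit.lam[0]), float(fit.lam[1])
    if not lam1 < lam2 * (1 - 1e-9):
        return None, 1.0
    if fit.weight.min() < 0.05:
        # a spurious sliver component can slip under the misclassification
        # gate simply because it is small; a real genome is not a sliver
        return None, 1.0
    G1 = float(fit.weight[0] * len(filt))
    G2 = float(fit.weight[1] * len(filt))
    K = optimal_split_K(lam1, lam2, G1, G2)
    rate = expected_misclassification(lam1, lam2, G1, G2, K)
    if rate > gate:
        return None, rate
    # classify l-mers by max responsibility, reads by majority vote
    comp = fit.responsibilities.argmax(axis=1)
    low_codes = filt.codes[comp == 0]
    sub = reads.subset(pair_idx)
    mat, ok = sub.mate_window_matrix(counts.l)
    known = np.zeros(mat.shape, dtype=bool)
    pos = np.searchsorted(filt.codes, mat)
    pos = np.clip(pos, 0, len(filt.codes) - 1)
    known = (filt.codes[pos] == mat) & ok
    lowpos = np.searchsorted(low_codes, mat)
    lowpos = np.clip(lowpos, 0, max(low_codes.size - 1, 0))
    is_low = known & (low_codes.size > 0) & (low_codes[lowpos] == mat)
    n_low = is_low.reshape(len(pair_idx), -1).sum(axis=1)
    n_known = known.reshape(len(pair_idx), -1).sum(axis=1)
    to_low = n_low * 2 > n_known  # majority of classified l-mers; ties -> high
    return (pair_idx[to_low], pair_idx[~to_low], lam1, lam2), rate


def gate_and_bin(
    reads: ReadPairSet,
    counts: LmerCountTable,
    gate: float = 0.03,
    seed: int = 0,
    l: int | None = None,
    min_bin_pairs: int = 500,
    max_bins: int = 8,
) -> AbundanceBins:
    """Bin read pairs by abundance, recursively, while the gate allows.

    Fits a 2-component mixture to the (error-filtered) l-mer counts; if the
    expected misclassification at the optimal threshold exceeds ``gate``,
    everything stays in one bin.  Otherwise the split is applied and each
    side is re-examined (binary recursive splitting), stopping at
    ``min_bin_pairs`` pairs or ``max_bins`` bins.
    """
    l = l or counts.l
    all_pairs = np.arange(reads.N, dtype=np.int64)
    split, rate = _split_once(reads, all_pairs, counts, gate, seed)
    if split is None:
        return AbundanceBins(
            pair_bins=[all_pairs], lam=[float("nan")], gate_rate=float(rate), gated=False
        )
    low, high, lam1, lam2 = split
    result: list[tuple[np.ndarray, float]] = []
    work = [(low, lam1), (high, lam2)]
    while work:
        pairs, lam_est = work.pop()
        if pairs.size < min_bin_pairs or len(result) + len(work) + 1 >= max_bins:
            result.append((pairs, lam_est))
            continue
        sub_counts = count_lmers(reads.subset(pairs), l)
        split2, _ = _split_once(reads, pairs, sub_counts, gate, seed)
        if split2 is None:
            result.append((pairs, lam_est))
            continue
        lo, hi, l1, l2 = split2
        if lo.size == 0 or hi.size == 0:
            result.append((pairs, lam_est))
            continue
        work.append((lo, l1))
        work.append((hi, l2))
    result.sort(key=lambda t: t[1])
    return AbundanceBins(
        pair_bins=[p for p, _ in result],
        lam=[float(x) for _, x in result],
        gate_rate=float(rate),
        gated=True,
    )


def run_integrated(reads: ReadPairSet, config=None):
    """Full pipeline with abundance pre-binning; see ``pipeline.run_pipeline``.

    Kept as the module-level entry point; delegates to the pipeline module
    (phase 1 per bin, cluster linkage from all reads, MCL per bin).
    """
    from .pipeline import RunConfig, run_pipeline_on_reads

    config = config or RunConfig()
    return run_pipeline_on_reads(reads, config)
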