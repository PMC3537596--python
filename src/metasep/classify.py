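"""Classification of l-mers into sequencing-error artifacts, unique l-mers
and repeats from their count distribution.

Under the Lander-Waterman model, the count x(w) of a single-copy l-mer is
Poisson with parameter lambda = alpha (L - l + 1), alpha = 2N / (G - L + 1);
an l-mer with n copies has a Poisson(n * lambda) count.  The classifier
works purely on the count histogram n(i):

* ``K_err`` — error l-mers produce a spike of low counts; the threshold is
  the first valley of the histogram (counts below it are discarded);
* ``lam_hat`` — since most l-mers are single-copy, the histogram mode above
  the error band estimates lambda;
* ``K_repeat`` — the smallest count at which the observed histogram exceeds
  twice the expected single-copy histogram y(i) (Poisson pmf scaled to the
  observed peak), sustained over two consecutive counts; counts >= K_repeat
  are classified as repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._sorted import isin_sorted, setdiff_sorted, union_sorted
from .lmer_core import CountHistogram, LmerCountTable, ReadPairSet, histogram

__all__ = [
    "CoverageModel",
    "LmerPartition",
    "estimate_lambda",
    "refine_lambda_mle",
    "select_error_threshold",
    "select_repeat_threshold",
    "partition_lmers",
    "classify_lmers",
    "estimate_G",
]


@dataclass
class CoverageModel:
    """Effective-coverage bookkeeping for a read set against a genome size."""

    N: int
    L: int
    G: float
    l: int

    @property
    def alpha(self) -> float:
        """Per-position read-start rate, 2N / (G - L + 1)."""
        return 2 * self.N / (self.G - self.L + 1)

    @property
    def lam(self) -> float:
        """Effective per-l-mer coverage, alpha * (L - l + 1)."""
        return self.alpha * (self.L - self.l + 1)


@dataclass
class LmerPartition:
    """Disjoint split of all distinct l-mers into {discarded, U, R}.

    Membership is defined purely by count thresholds: x < K_err discarded
    (presumed errors), K_err <= x < K_repeat unique (U), x >= K_repeat
    repeats (R).  High-degree pruning later moves some l-mers from U to R.
    """

    l: int
    U: np.ndarray  # sorted codes
    R: np.ndarray
    discarded: np.ndarray
    K_err: int
    K_repeat: int
    lam_hat: float

    @property
    def n_total(self) -> int:
        return self.U.size + self.R.size + self.discarded.size

    def in_U(self, codes: np.ndarray) -> np.ndarray:
        return isin_sorted(codes, self.U)

    def in_R(self, codes: np.ndarray) -> np.ndarray:
        return isin_sorted(codes, self.R)

    def move_to_R(self, codes: np.ndarray) -> "LmerPartition":
        """New partition with the given U members reclassified as repeats."""
        codes = np.asarray(codes, dtype=np.int64)
        return LmerPartition(
            l=self.l,
            U=setdiff_sorted(self.U, codes),
            R=union_sorted(self.R, codes),
            discarded=self.discarded,
            K_err=self.K_err,
            K_repeat=self.K_repeat,
            lam_hat=self.lam_hat,
        )


def estimate_lambda(hist: CountHistogram, K_err: int) -> float:
    """Estimate lambda as the histogram mode at counts >= K_err.

    Most l-mers are single-copy, so the peak of n(i) above the error band
    sits at the Poisson parameter.  Ties are broken toward the larger count.
    """
    cand = [(i, n) for i, n in hist.n_of.items() if i >= K_err]
    if not cand:
        raise ValueError(
            f"no l-mer counts at or above K_err={K_err}: coverage too low "
            "or error l-mers dominate"
        )
    # max by frequency, then by count value (larger wins a tie)
    best = max(cand, key=lambda t: (t[1], t[0]))
    return float(best[0])


def refine_lambda_mle(hist: CountHistogram, K_err: int, lam0: float) -> float:
    """Optional left-truncated-Poisson MLE refinement of the mode estimate.

    Maximises the likelihood of counts conditioned on x >= K_err.  Kept as
    an alternative; the mode is the default estimator.
    """
    vals = np.array([i for i in hist.n_of if i >= K_err], dtype=float)
    mult = np.array([hist.n_of[int(i)] for i in vals], dtype=float)
    if vals.size == 0:
        raise ValueError("no counts above K_err")

    def nll(lam: float) -> float:
        logp = stats.poisson.logpmf(vals, lam)
        tail = stats.poisson.sf(K_err - 1, lam)
        return -(mult * (logp - np.log(max(tail, 1e-300)))).sum()

    res = optimize.minimize_scalar(
        nll, bounds=(max(0.1, lam0 / 4), lam0 * 4), method="bounded"
    )
    return float(res.x)


def select_error_threshold(hist: CountHistogram) -> int:
    """Error-count threshold K_err: the first valley of the histogram.

    Error l-mers form a spike of low counts while single-copy l-mers peak
    near lambda; scanning i = 1, 2, ... the first i with n(i) < n(i+1) is the
    valley between the two.  Returns 1 (discard nothing) when the histogram
    rises immediately (error-free data) or never rises (no visible peak).
    """
    n = hist.dense()
    m = min(hist.n_of)
    if m >= hist.max_count or n[m] < n[m + 1]:
        return 1  # rising (or flat single-bin) from the start: no error spike
    for i in range(m, hist.max_count):
        if n[i] < n[i + 1]:
            return i
    return 1


def select_repeat_threshold(
    hist: CountHistogram, lam_hat: float, K_err: int = 1
) -> int:
    """Repeat-count threshold K_repeat via the sustained 2x rule.

    y(i) is the expected single-copy histogram: the Poisson(lam_hat) pmf
    scaled so that y(mode) matches the observed peak (the peak is almost
    entirely single-copy l-mers).  K_repeat is the smallest count i >
    lam_hat with n(i) >= 2 y(i) holding at both i and i+1 (the two-bin
    guard suppresses single-bin noise).  If no count qualifies, nothing is
    classified as a repeat by count: K_repeat = max_count + 1.
    """
    if lam_hat <= 0:
        raise ValueError("lam_hat must be positive")
    n = hist.dense()
    mode = int(estimate_lambda(hist, K_err))
    scale = n[mode] / stats.poisson.pmf(mode, lam_hat)
    start = int(np.floor(lam_hat)) + 1
    y = scale * stats.poisson.pmf(np.arange(hist.max_count + 2), lam_hat)
    ok = n >= 2 * np.maximum(y, 1e-300)
    ok &= n > 0
    for i in range(start, hist.max_count):
        if ok[i] and ok[i + 1]:
            return i
    return hist.max_count + 1


def partition_lmers(
    counts: LmerCountTable,
    K_err: int,
    K_repeat: int,
    lam_hat: float = float("nan"),
) -> LmerPartition:
    """Split all distinct l-mers into {discarded, U, R} by count thresholds."""
    if not 1 <= K_err < K_repeat:
        raise ValueError(f"need 1 <= K_err < K_repeat, got {K_err}, {K_repeat}")
    x = counts.counts
    return LmerPartition(
        l=counts.l,
        U=counts.codes[(x >= K_err) & (x < K_repeat)],
        R=counts.codes[x >= K_repeat],
        discarded=counts.codes[x < K_err],
        K_err=K_err,
        K_repeat=K_repeat,
        lam_hat=lam_hat,
    )


def classify_lmers(counts: LmerCountTable) -> LmerPartition:
    """Full automatic classification: K_err, lam_hat, K_repeat, partition."""
    hist_ = histogram(counts)
    K_err = select_error_threshold(hist_)
    lam_hat = estimate_lambda(hist_, K_err)
    K_repeat = select_repeat_threshold(hist_, lam_hat, K_err)
    return partition_lmers(counts, K_err, K_repeat, lam_hat)


def estimate_G(
    counts: LmerCountTable, partition: LmerPartition, reads: ReadPairSet
) -> float:
    """Total genome length estimate from the partition.

    Unique l-mers count one position each; each repeat contributes its
    estimated copy number round(x(w) / lam_hat); l - 1 closes the last
    window.  Used to evaluate the coverage model and the expansion
    threshold T when the user does not supply a genome size.
    """
    if not np.isfinite(partition.lam_hat) or partition.lam_hat <= 0:
        raise ValueError("partition carries no positive lam_hat")
    if partition.U.size == 0 and partition.R.size == 0:
        raise ValueError("empty partition: nothing to estimate from")
    xr = counts.lookup_codes(partition.R).astype(float)
    copies = np.maximum(np.rint(xr / partition.lam_hat), 1.0)
    return float(partition.U.size + copies.sum() + counts.l - 1)
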