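"""Read ingestion and exact canonical l-mer counting.

l-mers (substrings of length ``l``, default 20) are the atomic unit of the
whole separation pipeline.  Each window of each mate sequence is reduced to
its *canonical* form — the lexicographic minimum of the l-mer and its reverse
complement — so counting is strand-independent.  Windows containing an
ambiguous base (``N``) are skipped, not expanded.

l-mers are manipulated as 2-bit-packed integer codes (A=0, C=1, G=2, T=3,
most-significant base first), which keeps counting and all downstream set
operations vectorised; ``l`` up to 31 fits an int64.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from ._sorted import unique_counts

__all__ = [
    "ReadPairSet",
    "LmerCountTable",
    "CountHistogram",
    "load_reads",
    "count_lmers",
    "histogram",
    "encode_seq",
    "window_codes",
    "decode_lmer",
    "revcomp",
]

MAX_L = 31  # 2 bits per base in an int64

# ASCII -> 2-bit base code; 4 marks anything that is not A/C/G/T (N, separators)
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of 2-bit base codes (4 = N)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_codes(bases: np.ndarray, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical integer codes of all length-``l`` windows of ``bases``.

    Parameters
    ----------
    bases
        uint8 array of 2-bit base codes (4 for ambiguous/separator positions).
    l
        Window length, 1 <= l <= 31.

    Returns
    -------
    codes, valid
        ``codes[i]`` is the canonical (min of forward and reverse-complement)
        integer code of the window starting at ``i``; ``valid[i]`` is False
        where the window contains a non-ACGT position (its code is
        meaningless there).
    """
    if not 1 <= l <= MAX_L:
        raise ValueError(f"l must be in [1, {MAX_L}], got {l}")
    n = bases.shape[0]
    if n < l:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - l + 1
    b = (bases & 3).astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    for j in range(l):
        col = b[j : j + m]
        fwd |= col << (2 * (l - 1 - j))
        rev |= (3 - col) << (2 * j)
    codes = np.minimum(fwd, rev)
    bad = np.cumsum(np.concatenate(([0], (bases == 4).astype(np.int64))))
    valid = (bad[l:] - bad[:-l]) == 0
    return codes, valid


def decode_lmer(code: int, l: int) -> str:
    """Decode a 2-bit-packed l-mer code back to its DNA string."""
    out = []
    for j in range(l):
        out.append("ACGT"[(code >> (2 * (l - 1 - j))) & 3])
    return "".join(out)


@dataclass
class ReadPairSet:
    """A set of paired-end reads of fixed length.

    Attributes
    ----------
    ids : list of str
        One identifier per pair; mate-level identifiers are ``f"{id}/1"`` and
        ``f"{id}/2"``.
    mates1, mates2 : list of str
        The two mate sequences of each pair, all of length exactly ``L``.
    L : int
        Read length in bp.
    """

    ids: list[str]
    mates1: list[str]
    mates2: list[str]
    L: int
    _win_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.mates1) != len(self.mates2) or len(self.ids) != len(self.mates1):
            raise ValueError("ids, mates1 and mates2 must have equal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("read ids must be unique")
        allowed = set("ACGTNacgtn")
        for s in self.mates1 + self.mates2:
            if len(s) != self.L:
                raise ValueError(
                    "variable read lengths are unsupported: the coverage model "
                    f"assumes fixed L={self.L}, got a read of length {len(s)}"
                )
            if not allowed.issuperset(s):
                raise ValueError(f"read contains non-ACGTN characters: {s[:20]}...")

    @property
    def N(self) -> int:
        """Number of read pairs."""
        return len(self.ids)

    @property
    def n_mates(self) -> int:
        return 2 * len(self.ids)

    def mate_ids(self) -> list[str]:
        """Mate-level identifiers in interleaved order (pair k -> 2k, 2k+1)."""
        out = []
        for rid in self.ids:
            out.append(rid + "/1")
            out.append(rid + "/2")
        return out

    def iter_mates(self) -> Iterator[str]:
        """Yield mate sequences interleaved: pair k contributes 2k and 2k+1."""
        for s1, s2 in zip(self.mates1, self.mates2):
            yield s1
            yield s2

    def mate_window_matrix(self, l: int) -> tuple[np.ndarray, np.ndarray]:
        """Canonical window codes of every mate as a (2N, L-l+1) matrix.

        Returns ``(codes, valid)``; invalid windows (containing N) carry an
        arbitrary code and ``valid`` False.  Cached per ``l``.
        """
        if l in self._win_cache:
            return self._win_cache[l]
        if l > self.L:
            raise ValueError(f"l={l} exceeds read length L={self.L}")
        w = self.L - l + 1
        nm = self.n_mates
        # one buffer: mates separated by a sentinel (code 4) so windows
        # never straddle two reads
        buf = np.full(nm * (self.L + 1), 4, dtype=np.uint8)
        for k, seq in enumerate(self.iter_mates()):
            start = k * (self.L + 1)
            buf[start : start + self.L] = encode_seq(seq)
        codes, valid = window_codes(buf, l)
        # windows starting inside mate k: offsets [k*(L+1), k*(L+1)+w)
        starts = np.arange(nm) * (self.L + 1)
        idx = starts[:, None] + np.arange(w)[None, :]
        mat = codes[idx]
        ok = valid[idx]
        self._win_cache[l] = (mat, ok)
        return mat, ok

    def subset(self, pair_indices: np.ndarray) -> "ReadPairSet":
        """New ReadPairSet restricted to the given pair indices."""
        return ReadPairSet(
            ids=[self.ids[i] for i in pair_indices],
            mates1=[self.mates1[i] for i in pair_indices],
            mates2=[self.mates2[i] for i in pair_indices],
            L=self.L,
        )


@dataclass
class LmerCountTable:
    """Canonical l-mer -> observed count x(w), stored as parallel arrays.

    ``codes`` is sorted ascending; ``counts[i]`` is the number of read
    windows whose canonical form equals ``codes[i]``.
    """

    l: int
    codes: np.ndarray  # int64, sorted, unique
    counts: np.ndarray  # int64, positive

    def __len__(self) -> int:
        return self.codes.shape[0]

    def get(self, lmer: str) -> int:
        """Count of an l-mer given as a string (canonicalised first)."""
        if len(lmer) != self.l:
            raise ValueError(f"expected a {self.l}-mer, got length {len(lmer)}")
        c = min(lmer.upper(), revcomp(lmer.upper()))
        code = 0
        for ch in c:
            code = (code << 2) | int(_BASE_CODE[ord(ch)])
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def to_dict(self) -> dict[str, int]:
        """Materialise as {l-mer string: count} (debug/small tables only)."""
        return {decode_lmer(int(c), self.l): int(x) for c, x in zip(self.codes, self.counts)}

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        pos = np.searchsorted(self.codes, query)
        pos = np.clip(pos, 0, len(self.codes) - 1)
        hit = self.codes[pos] == query
        out = np.where(hit, self.counts[pos], 0)
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Dump as 2-column TSV (lmer, count) for debugging."""
        with open(path, "w") as fh:
            for c, x in zip(self.codes, self.counts):
                fh.write(f"{decode_lmer(int(c), self.l)}\t{int(x)}\n")


@dataclass
class CountHistogram:
    """n(i): number of distinct l-mers observed exactly i times."""

    n_of: dict[int, int]
    max_count: int

    def dense(self) -> np.ndarray:
        """n as a dense array indexed by count, length max_count + 2."""
        arr = np.zeros(self.max_count + 2, dtype=np.int64)
        for i, n in self.n_of.items():
            arr[i] = n
        return arr

    @property
    def n_distinct(self) -> int:
        return sum(self.n_of.values())


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_records(path: str | Path, fmt: str) -> list[tuple[str, str]]:
    with _open_maybe_gzip(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def load_reads(
    path1: str | Path,
    path2: str | Path | None = None,
    fmt: str = "fastq",
) -> ReadPairSet:
    """Load paired-end reads from two mate files or one interleaved file.

    Parameters
    ----------
    path1, path2
        Mate files (``path2`` omitted for interleaved input).  Gzip input is
        detected from a ``.gz`` suffix.
    fmt
        ``"fastq"`` or ``"fasta"`` (quality scores are ignored).

    Pairing is positional: record k of file 1 with record k of file 2, or
    records 2k/2k+1 of an interleaved file.  The read length L is inferred
    from the first record and must be shared by every read.
    """
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"unsupported format {fmt!r}")
    rec1 = _read_records(path1, fmt)
    if not rec1:
        raise ValueError(f"no records in {path1}")
    if path2 is not None:
        rec2 = _read_records(path2, fmt)
        if len(rec1) != len(rec2):
            raise ValueError(
                f"mate files disagree: {len(rec1)} vs {len(rec2)} records"
            )
    else:
        if len(rec1) % 2 != 0:
            raise ValueError("interleaved input must contain an even number of records")
        rec2 = rec1[1::2]
        rec1 = rec1[0::2]
    L = len(rec1[0][1])
    ids = []
    for (i1, _), (i2, _) in zip(rec1, rec2):
        rid = i1
        for suf in ("/1", "/2", ".1", ".2", "_1", "_2"):
            if rid.endswith(suf):
                rid = rid[: -len(suf)]
                break
        ids.append(rid)
    if len(set(ids)) != len(ids):  # fall back to positional ids
        ids = [f"read{k}" for k in range(len(rec1))]
    return ReadPairSet(
        ids=ids,
        mates1=[s for _, s in rec1],
        mates2=[s for _, s in rec2],
        L=L,
    )


def count_lmers(reads: ReadPairSet, l: int) -> LmerCountTable:
    """Tally canonical l-mer counts x(w) over all windows of all mates.

    Every mate contributes its L - l + 1 windows; windows containing an
    ambiguous base are skipped.
    """
    if not 0 < l <= reads.L:
        raise ValueError(f"l must satisfy 0 < l <= L={reads.L}, got {l}")
    mat, ok = reads.mate_window_matrix(l)
    vals = mat[ok]
    codes, counts = unique_counts(vals)
    return LmerCountTable(l=l, codes=codes, counts=counts.astype(np.int64))


def histogram(table: LmerCountTable) -> CountHistogram:
    """Count-of-counts n(i) of an l-mer table."""
    if len(table) == 0:
        raise ValueError("empty l-mer count table")
    vals, mult = unique_counts(table.counts)
    return CountHistogram(
        n_of={int(v): int(m) for v, m in zip(vals, mult)},
        max_count=int(vals.max()),
    )
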