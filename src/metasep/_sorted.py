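"""Small helpers for sets represented as sorted unique int64 arrays."""

from __future__ import annotations

import numpy as np


def isin_sorted(query: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    """Membership of ``query`` values in a sorted unique array."""
    if sorted_arr.size == 0:
        return np.zeros(query.shape, dtype=bool)
    pos = np.searchsorted(sorted_arr, query)
    pos = np.clip(pos, 0, sorted_arr.size - 1)
    return sorted_arr[pos] == query


def union_sorted(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.union1d(a, b)


def setdiff_sorted(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a \\ b for sorted unique arrays, preserving order."""
    return a[~isin_sorted(a, b)]


def unique_sorted(a: np.ndarray) -> np.ndarray:
    """Sorted distinct values (sort-based: much faster than np.unique here)."""
    if a.size == 0:
        return a
    s = np.sort(a)
    keep = np.empty(s.size, dtype=bool)
    keep[0] = True
    np.not_equal(s[1:], s[:-1], out=keep[1:])
    return s[keep]


def unique_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distinct values and their multiplicities."""
    if a.size == 0:
        return a, np.empty(0, dtype=np.int64)
    s = np.sort(a)
    keep = np.empty(s.size, dtype=bool)
    keep[0] = True
    np.not_equal(s[1:], s[:-1], out=keep[1:])
    idx = np.flatnonzero(keep)
    counts = np.diff(np.append(idx, s.size))
    return s[idx], counts
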