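"""Half-open interval algebra on a single sequence axis.

All functions operate on integer intervals ``[start, end)`` given as an
``(n, 2)`` array-like. They are the building blocks for the genome
partition (exon / intron / intergenic tiling) and for depth-track masks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_array", "merge", "subtract", "complement", "total_length"]


def as_array(intervals) -> np.ndarray:
    """Coerce to an (n, 2) int64 array and validate start < end."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("empty or inverted interval (start >= end)")
    return arr


def merge(intervals) -> np.ndarray:
    """Union of intervals: sorted, overlapping/adjacent runs coalesced."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [arr[0].copy()]
    for start, end in arr[1:]:
        if start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append(np.array([start, end]))
    return np.array(out, dtype=np.int64)


def subtract(a, b) -> np.ndarray:
    """Set difference a \\ b. Both inputs are merged first."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def complement(intervals, length: int) -> np.ndarray:
    """Intervals of [0, length) not covered by the input."""
    return subtract([(0, int(length))], intervals)


def total_length(intervals) -> int:
    arr = as_array(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())
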