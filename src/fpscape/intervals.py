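"""Arithmetic on sorted, half-open genomic intervals.

All functions operate on a single chromosome at a time and expect / return
``(n, 2)`` integer arrays of ``[start, end)`` pairs sorted by start.  These
helpers back the segmentation and annotation layers; they are deliberately
minimal (merge / complement / subtract / overlap) and vectorised with
``numpy.searchsorted``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "complement",
    "subtract",
    "intersect",
    "total_length",
    "overlap_lengths",
    "locate",
]


def as_intervals(iv) -> np.ndarray:
    """Coerce to a sorted ``(n, 2)`` int64 interval array."""
    arr = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("interval end < start")
    if arr.size:
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
    return arr


def merge(iv, gap: int = 0) -> np.ndarray:
    """Union of intervals, merging any that overlap or lie within `gap` bp."""
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def complement(iv, length: int) -> np.ndarray:
    """Complement of the merged interval set within ``[0, length)``."""
    arr = merge(iv)
    edges = np.concatenate([[0], arr.ravel(), [length]])
    pairs = edges.reshape(-1, 2)
    return pairs[pairs[:, 1] > pairs[:, 0]]


def subtract(iv, remove) -> np.ndarray:
    """Remove ``remove`` from ``iv`` (both merged first)."""
    a = merge(iv)
    b = merge(remove)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return (
        np.asarray(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)
    )


def intersect(a, b) -> np.ndarray:
    """Intersection of two interval sets."""
    a = merge(a)
    if len(a) == 0:
        return a
    # a \ (a \ b) == a & b
    return subtract(a, subtract(a, b))


def total_length(iv) -> int:
    arr = merge(iv)
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


def overlap_lengths(starts, ends, iv) -> np.ndarray:
    """Covered length of each query ``[starts[i], ends[i])`` by interval set `iv`.

    Queries need not be sorted.  `iv` is merged first so covered lengths are
    well defined.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    arr = merge(iv)
    if len(arr) == 0:
        return np.zeros(len(starts), dtype=np.int64)
    ivs, ive = arr[:, 0], arr[:, 1]
    cum = np.concatenate([[0], np.cumsum(ive - ivs)])
    out = np.zeros(len(starts), dtype=np.int64)
    lo = np.searchsorted(ive, starts, side="right")
    hi = np.searchsorted(ivs, ends, side="left")
    for i in range(len(starts)):
        if lo[i] >= hi[i]:
            continue
        full = cum[hi[i]] - cum[lo[i]]
        # trim partial overlap at both ends
        full -= max(0, starts[i] - ivs[lo[i]])
        full -= max(0, ive[hi[i] - 1] - ends[i])
        out[i] = full
    return out


def locate(positions, iv) -> np.ndarray:
    """Index of the interval containing each position, or -1 outside all.

    Intervals must be sorted and non-overlapping (not merged here, so interval
    identity — e.g. domain index — is preserved).
    """
    positions = np.asarray(positions, dtype=np.int64)
    arr = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return np.full(len(positions), -1, dtype=np.int64)
    idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
    idx = np.clip(idx, 0, len(arr) - 1)
    inside = (positions >= arr[idx, 0]) & (positions < arr[idx, 1])
    return np.where(inside, idx, -1)
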