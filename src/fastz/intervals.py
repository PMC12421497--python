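"""Half-open genomic interval arithmetic on (n, 2) integer arrays.

All coordinates are 0-based, half-open [start, end), matching BED. Conversion
from 1-based formats (VCF, GFF3) happens at I/O boundaries only.
"""

from __future__ import annotations

import numpy as np


def as_interval_array(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("interval end < start")
    return arr


def merge(intervals) -> np.ndarray:
    """Sort and merge overlapping or abutting intervals."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_span(intervals) -> int:
    arr = merge(intervals)
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


def subtract(intervals, mask) -> np.ndarray:
    """Remove every base covered by `mask` from `intervals`."""
    base = merge(intervals)
    cut = merge(mask)
    if len(base) == 0 or len(cut) == 0:
        return base
    out = []
    j = 0
    for s, e in base:
        cur = s
        while j < len(cut) and cut[j][1] <= cur:
            j += 1
        k = j
        while k < len(cut) and cut[k][0] < e:
            cs, ce = cut[k]
            if cs > cur:
                out.append([cur, cs])
            cur = max(cur, ce)
            k += 1
        if cur < e:
            out.append([cur, e])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def contains(intervals, positions) -> np.ndarray:
    """Boolean mask: which positions fall inside any interval."""
    arr = merge(intervals)
    pos = np.asarray(positions, dtype=np.int64)
    if len(arr) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(pos.shape, dtype=bool)
    res[ok] = pos[ok] < arr[idx[ok], 1]
    return res


def expand(intervals, flank: int) -> np.ndarray:
    """Extend both ends by `flank` bp (clipped at 0) and merge."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr.copy()
    arr[:, 0] = np.maximum(arr[:, 0] - flank, 0)
    arr[:, 1] = arr[:, 1] + flank
    return merge(arr)
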