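"""Exact interval algebra on 0-based half-open coordinates.

All functions operate on parallel ``starts``/``ends`` integer arrays for a
single chromosome.  Inputs need not be sorted unless stated; outputs are
sorted, merged and therefore canonical, which keeps downstream set operations
(shore/shelf derivation, context classification) order-independent.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "subtract_intervals",
    "clip_intervals",
    "overlaps_any",
    "total_length",
]


def _as_arrays(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have equal length")
    if np.any(e <= s):
        raise ValueError("intervals must satisfy end > start")
    return s, e


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals: sorted, non-overlapping, book-ended runs fused."""
    s, e = _as_arrays(starts, ends)
    if s.size == 0:
        return s, e
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    # a new run starts wherever the start exceeds the running max of prior ends
    run_end = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    out_s = s[idx]
    out_e = np.append(run_end[idx[1:] - 1], run_end[-1])
    return out_s, out_e


def subtract_intervals(a_starts, a_ends, b_starts, b_ends):
    """A minus B.  Returns merged intervals covering bases in A but not B."""
    a_s, a_e = merge_intervals(*_as_arrays(a_starts, a_ends)) if len(a_starts) else (
        np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    if len(b_starts) == 0 or a_s.size == 0:
        return a_s, a_e
    b_s, b_e = merge_intervals(b_starts, b_ends)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = s
        # advance to first B interval that could overlap [cur, e)
        while j > 0 and b_e[j - 1] > cur:
            j -= 1
        while j < b_s.size and b_s[j] < e:
            if b_e[j] <= cur:
                j += 1
                continue
            if b_s[j] > cur:
                out_s.append(cur)
                out_e.append(min(b_s[j], e))
            cur = max(cur, b_e[j])
            if cur >= e:
                break
            j += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return (np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64))


def clip_intervals(starts, ends, length: int):
    """Clip to [0, length); intervals that fall entirely outside are dropped."""
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    s = np.clip(s, 0, length)
    e = np.clip(e, 0, length)
    keep = e > s
    return s[keep], e[keep]


def overlaps_any(q_starts, q_ends, ref_starts, ref_ends) -> np.ndarray:
    """For each query interval, whether it overlaps ≥1 bp of the reference set.

    The reference set is merged internally; queries may be unsorted.
    """
    q_s = np.asarray(q_starts, dtype=np.int64)
    q_e = np.asarray(q_ends, dtype=np.int64)
    if len(ref_starts) == 0:
        return np.zeros(q_s.size, dtype=bool)
    r_s, r_e = merge_intervals(ref_starts, ref_ends)
    # candidate: last reference starting before the query end
    idx = np.searchsorted(r_s, q_e, side="left") - 1
    hit = idx >= 0
    hit[hit] = r_e[idx[hit]] > q_s[hit]
    return hit


def total_length(starts, ends) -> int:
    s, e = merge_intervals(starts, ends) if len(starts) else (np.array([]), np.array([]))
    return int(np.sum(e - s)) if s.size else 0
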