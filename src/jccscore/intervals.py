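"""Sorted half-open interval arithmetic on (start, end) integer tuples.

All functions take and return lists of 0-based half-open ``(start, end)``
tuples. Inputs need not be sorted unless stated; outputs are sorted and
non-overlapping.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/adjacent runs coalesced."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals)) if intervals else 0


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two merged interval lists."""
    a, b = merge(a) if a else [], merge(b) if b else []
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b of two interval lists."""
    a = merge(a) if a else []
    b = merge(b) if b else []
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def gaps(intervals: Sequence[Interval]) -> list[Interval]:
    """Holes between consecutive merged intervals (within the outer span)."""
    m = merge(intervals)
    return [(m[i][1], m[i + 1][0]) for i in range(len(m) - 1) if m[i][1] < m[i + 1][0]]


def overlaps_any(start: int, end: int, intervals: Sequence[Interval]) -> bool:
    """True if [start, end) overlaps any interval in a merged, sorted list."""
    import bisect

    idx = bisect.bisect_right([s for s, _ in intervals], start)
    if idx > 0 and intervals[idx - 1][1] > start:
        return True
    return idx < len(intervals) and intervals[idx][0] < end
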