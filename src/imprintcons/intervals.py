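"""Half-open interval arithmetic on ``(start, end)`` pairs.

All coordinates in this package are 0-based, half-open (BED convention).
These helpers operate on plain tuples so that every module can share one
well-tested primitive instead of ad hoc loops.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def union(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or abutting intervals into a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def subtract(span: Interval, blocks: Sequence[Interval]) -> list[Interval]:
    """Return ``span`` minus the (disjoint, sorted) ``blocks``."""
    out: list[Interval] = []
    cur = span[0]
    for s, e in blocks:
        if e <= span[0] or s >= span[1]:
            continue
        s, e = max(s, span[0]), min(e, span[1])
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_with_set(iv: Interval, blocks: Sequence[Interval]) -> int:
    """Total overlap of ``iv`` with a disjoint interval list."""
    return sum(overlap_length(iv, b) for b in blocks)


def contains(blocks: Sequence[Interval], iv: Interval) -> bool:
    """True when ``iv`` is fully covered by the union of ``blocks``."""
    remaining = subtract(iv, union(blocks))
    return not remaining


def clip(iv: Interval, lo: int, hi: int) -> Interval | None:
    s, e = max(iv[0], lo), min(iv[1], hi)
    return (s, e) if e > s else None
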