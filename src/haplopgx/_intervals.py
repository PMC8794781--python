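"""Half-open interval arithmetic shared across modules.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention. Conversion to 1-based (VCF/GTF) happens only at the file
boundary.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list.

    Zero-length and inverted intervals are dropped.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect_size(interval: Interval, merged: Sequence[Interval]) -> int:
    """Number of bases of ``interval`` covered by a merged interval list."""
    s0, e0 = interval
    covered = 0
    for s, e in merged:
        if e <= s0:
            continue
        if s >= e0:
            break
        covered += min(e, e0) - max(s, s0)
    return covered


def contains_point(merged: Sequence[Interval], point: int) -> bool:
    for s, e in merged:
        if s <= point < e:
            return True
        if s > point:
            return False
    return False


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]
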