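"""Minimal half-open interval algebra used by the mapping module.

All intervals are (start, end) pairs with 0-based, half-open coordinates.
"""

from __future__ import annotations

__all__ = ["merge", "intersect", "subtract", "union", "total_length", "overlaps"]

Interval = tuple[int, int]


def _normalise(ivs: list[Interval]) -> list[Interval]:
    return sorted((int(s), int(e)) for s, e in ivs if e > s)


def merge(ivs: list[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into maximal runs."""
    out: list[Interval] = []
    for s, e in _normalise(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union(a: list[Interval], b: list[Interval]) -> list[Interval]:
    return merge(list(a) + list(b))


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Remove every region of ``b`` from ``a``."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_length(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in merge(ivs))


def overlaps(a: Interval, b: Interval) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])
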