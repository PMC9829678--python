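"""Half-open interval algebra on (start, end) tuples.

Used for core-region computation and segment/truth overlap metrics.
All intervals are 0-based half-open; inputs need not be sorted.
"""

from __future__ import annotations

__all__ = ["merge", "intersect", "subtract", "total_length", "overlap_length"]

Interval = tuple[int, int]


def _validate(ivs: list[Interval]) -> list[Interval]:
    out = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"degenerate interval [{s}, {e})")
        out.append((int(s), int(e)))
    return sorted(out)


def merge(ivs: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = _validate(ivs)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two interval unions."""
    a, b = merge(a), merge(b)
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


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b of two interval unions."""
    a, b = merge(a), merge(b)
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
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in merge(ivs))


def overlap_length(a: Interval, b: Interval) -> int:
    """Length of the overlap of two single intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
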