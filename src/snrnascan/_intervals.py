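"""Arithmetic on 1-based inclusive intervals on a single chromosome.

All functions take and return lists of ``(start, end)`` tuples with
``start <= end``. Kept internal: the BED-facing code converts to/from
0-based half-open at the I/O boundary.
"""

from __future__ import annotations


def merge(intervals: list[tuple[int, int]], join_adjacent: bool = True) -> list[tuple[int, int]]:
    """Union of intervals; adjacent intervals (gap 0) merge when requested."""
    if not intervals:
        return []
    slack = 1 if join_adjacent else 0
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e})")
        if out and s <= out[-1][1] + slack:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(base: list[tuple[int, int]], remove: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference base \\ remove."""
    remove = merge(remove, join_adjacent=False)
    out = []
    for s, e in merge(base, join_adjacent=False):
        cur = s
        for rs, re_ in remove:
            if re_ < cur or rs > e:
                continue
            if rs > cur:
                out.append((cur, rs - 1))
            cur = max(cur, re_ + 1)
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


def pad(intervals: list[tuple[int, int]], buffer: int) -> list[tuple[int, int]]:
    return [(s - buffer, e + buffer) for s, e in intervals]


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in intervals)
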