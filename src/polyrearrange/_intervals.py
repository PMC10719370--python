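"""Half-open interval helpers (sort-and-sweep; no tree needed at these sizes)."""

from __future__ import annotations

from typing import Iterable


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and non-overlapping.

    Abutting intervals ([0,10) and [10,20)) are merged.
    """
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by the union of half-open intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap length of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for empty intervals."""
    ov = overlap_len(a, b)
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)
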