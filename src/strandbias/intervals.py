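"""Half-open genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``.
GTF input (1-based, inclusive) is converted on read. Interval lists passed
between functions here are plain ``(start, end)`` tuples; :class:`GenomicInterval`
carries chromosome and strand for API-level objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

Interval = tuple[int, int]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a disjoint sorted list."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            if e > le:
                out[-1] = (ls, e)
        else:
            out.append((s, e))
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b for disjoint sorted interval lists."""
    out: list[Interval] = []
    b = merge(b)
    j = 0
    for s, e in merge(a):
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def gaps(intervals: Sequence[Interval], span: Interval) -> list[Interval]:
    """Complement of ``intervals`` within ``span``."""
    return subtract([span], intervals)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def overlaps(a: Sequence[Interval], b: Sequence[Interval]) -> bool:
    """True if any interval of a intersects any interval of b."""
    a, b = merge(a), merge(b)
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i][1] <= b[j][0]:
            i += 1
        elif b[j][1] <= a[i][0]:
            j += 1
        else:
            return True
    return False


def span_distance(a: Interval, b: Interval) -> int:
    """Gap in bp between two intervals; 0 if they overlap or touch."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)
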