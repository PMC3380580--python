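"""Half-open genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)`` --
the BED convention.  Most of the arithmetic below operates on plain
``(start, end)`` integer pairs grouped per chromosome; :class:`GenomicInterval`
is the typed wrapper used at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "merge_pairs",
    "subtract_pairs",
    "intersect_pairs",
    "complement_pairs",
    "total_length",
    "clip_pair",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated half-open interval on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def pair(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open pairs as a sorted, disjoint list.

    Touching pairs (end == next start) are merged into one.
    """
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract_pairs(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b; both inputs may be unsorted/overlapping."""
    a = merge_pairs(a)
    b = merge_pairs(b)
    out: list[tuple[int, int]] = []
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
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_pairs(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two pair sets (merged, sorted output)."""
    a = merge_pairs(a)
    b = merge_pairs(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement_pairs(
    pairs: Sequence[tuple[int, int]], size: int
) -> list[tuple[int, int]]:
    """Complement of a pair set within ``[0, size)``."""
    merged = merge_pairs(pairs)
    if merged and (merged[0][0] < 0 or merged[-1][1] > size):
        raise ValueError("interval outside [0, size)")
    out: list[tuple[int, int]] = []
    cur = 0
    for s, e in merged:
        if s > cur:
            out.append((cur, s))
        cur = e
    if cur < size:
        out.append((cur, size))
    return out


def total_length(pairs: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a pair set (union, not sum of raw lengths)."""
    return sum(e - s for s, e in merge_pairs(pairs))


def clip_pair(start: int, end: int, size: int | None) -> tuple[int, int] | None:
    """Clip ``[start, end)`` to ``[0, size)``; None when nothing survives."""
    s = max(start, 0)
    e = end if size is None else min(end, size)
    if s >= e:
        return None
    return (s, e)
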