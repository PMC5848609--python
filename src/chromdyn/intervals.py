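"""Genomic interval primitives and interval algebra.

All coordinates are 0-based half-open ([start, end)), the native BED
convention. Intervals on different chromosomes never overlap and have no
defined distance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "ScoredInterval",
    "overlap_pairs",
    "nearest_k",
    "stitch_intervals",
    "from_one_based",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class ScoredInterval:
    """An interval carrying a signal value and a free-text class label."""

    interval: GenomicInterval
    score: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score}")


def from_one_based(chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval:
    """Convert 1-based inclusive coordinates (GFF/VCF dialects) to internal form."""
    return GenomicInterval(chrom, start - 1, end, strand)


def _by_chrom(intervals) -> dict:
    groups: dict[str, list[int]] = defaultdict(list)
    for i, iv in enumerate(intervals):
        groups[iv.chrom].append(i)
    return groups


def overlap_pairs(a, b) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]`` by >= 1 bp.

    Half-open semantics: ``[0, 10)`` and ``[10, 20)`` do not overlap.
    Output is sorted by ``(i, j)``.
    """
    groups_b = _by_chrom(b)
    pairs: list[tuple[int, int]] = []
    cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, idx_b in groups_b.items():
        idx = np.asarray(idx_b)
        starts = np.array([b[j].start for j in idx_b])
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends = np.array([b[j].end for j in idx_b])[order]
        # running max of ends lets us prune the left scan
        cummax_end = np.maximum.accumulate(ends)
        cache[chrom] = (idx[order], starts, ends, cummax_end)
    for i, iv in enumerate(a):
        entry = cache.get(iv.chrom)
        if entry is None:
            continue
        idx, starts, ends, cummax_end = entry
        hi = np.searchsorted(starts, iv.end, side="left")
        lo = np.searchsorted(cummax_end[:hi], iv.start, side="right")
        if lo >= hi:
            continue
        sel = ends[lo:hi] > iv.start
        for j in idx[lo:hi][sel]:
            pairs.append((i, int(j)))
    pairs.sort()
    return pairs


def nearest_k(query, subject, k: int):
    """For each query interval, its ``k`` nearest subject intervals.

    Distance is the gap between closest edges (0 on overlap); the sign is
    negative when the subject lies upstream (to the left) of the query.
    Ties on |distance| are broken by smaller subject start, then subject
    input order. Returns a list (per query) of ``(subject_index,
    signed_distance)`` tuples; queries on chromosomes with no subjects, or
    ranks beyond the number of same-chromosome subjects, are truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    groups = _by_chrom(subject)
    results = []
    for iv in query:
        idx_s = groups.get(iv.chrom, [])
        if not idx_s:
            results.append([])
            continue
        starts = np.array([subject[j].start for j in idx_s])
        ends = np.array([subject[j].end for j in idx_s])
        # gap between closest edges; 0 when overlapping
        left_gap = starts - iv.end  # >= 0 when subject downstream
        right_gap = iv.start - ends  # >= 0 when subject upstream
        dist = np.where((starts < iv.end) & (ends > iv.start), 0, np.maximum(left_gap, right_gap))
        signed = np.where(starts >= iv.end, dist, -dist)
        signed = np.where(dist == 0, 0, signed)
        order = sorted(
            range(len(idx_s)),
            key=lambda t: (dist[t], starts[t], idx_s[t]),
        )
        results.append([(idx_s[t], int(signed[t])) for t in order[:k]])
    return results


def stitch_intervals(intervals, max_gap: int):
    """Transitively merge intervals whose gap is <= ``max_gap``.

    Returns ``(merged, members)`` where ``merged`` is a sorted list of
    disjoint GenomicIntervals and ``members[i]`` lists the original indices
    merged into ``merged[i]``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    merged: list[GenomicInterval] = []
    members: list[list[int]] = []
    cur = None
    cur_members: list[int] = []
    for i in order:
        iv = intervals[i]
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= max_gap:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
            cur_members.append(i)
        else:
            if cur is not None:
                merged.append(cur)
                members.append(cur_members)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
            cur_members = [i]
    if cur is not None:
        merged.append(cur)
        members.append(cur_members)
    return merged, members
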