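"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open (BED convention):
an interval ``(chrom, start, end)`` covers bases ``start .. end-1``.
Two intervals overlap iff they share at least one base; intervals that
merely touch (``a.end == b.start``) do not overlap, but *are* merged by
:func:`merge_intervals` (bookended intervals cover a contiguous run of
bases).

The functions here are the overlap engine underneath promoter-hit
counting, FRIP and the track statistics; they are deliberately small and
are cross-checked against brute-force per-base oracles in the test
suite.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Interval",
    "merge_intervals",
    "coverage_bp",
    "intersection_bp",
    "overlaps_any",
    "IntervalIndex",
]


class Interval(NamedTuple):
    """A genomic interval, 0-based half-open, with optional BED extras."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None


def _merged_by_chrom(track: Iterable[Sequence]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge a track into per-chromosome sorted, disjoint start/end arrays.

    Bookended intervals (end == next start) are merged.
    """
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in track:
        by.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by.items():
        spans.sort()
        starts: list[int] = []
        ends: list[int] = []
        cs, ce = spans[0]
        for s, e in spans[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                starts.append(cs)
                ends.append(ce)
                cs, ce = s, e
        starts.append(cs)
        ends.append(ce)
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return out


def merge_intervals(track: Iterable[Sequence]) -> list[Interval]:
    """Return the minimal sorted, disjoint interval set covering the same bases.

    Sorted by (chrom, start); touching intervals are merged into one.
    """
    merged = _merged_by_chrom(track)
    out: list[Interval] = []
    for chrom in sorted(merged):
        starts, ends = merged[chrom]
        out.extend(Interval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def coverage_bp(track: Iterable[Sequence]) -> int:
    """Total number of distinct bases covered by the track."""
    total = 0
    for starts, ends in _merged_by_chrom(track).values():
        total += int((ends - starts).sum())
    return total


def intersection_bp(track_a: Iterable[Sequence], track_b: Iterable[Sequence]) -> int:
    """Number of bases covered by both tracks (two-pointer sweep on merged runs)."""
    a = _merged_by_chrom(track_a)
    b = _merged_by_chrom(track_b)
    total = 0
    for chrom in a.keys() & b.keys():
        sa, ea = a[chrom]
        sb, eb = b[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


class IntervalIndex:
    """Query-by-overlap index over a merged track.

    Because the merged runs on each chromosome are sorted and disjoint, a
    query ``[s, e)`` overlaps the track iff the last run starting before
    ``e`` ends after ``s`` — a single ``searchsorted`` per query batch.
    """

    def __init__(self, track: Iterable[Sequence]):
        self._merged = _merged_by_chrom(track)

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the queries on `chrom` overlap the track by >= 1 bp."""
        if chrom not in self._merged:
            return np.zeros(len(starts), dtype=bool)
        t_starts, t_ends = self._merged[chrom]
        pos = np.searchsorted(t_starts, ends, side="left") - 1
        return (pos >= 0) & (t_ends[np.clip(pos, 0, None)] > starts)


def overlaps_any(
    queries: Sequence[Sequence],
    subjects: Iterable[Sequence] | None = None,
    *,
    index: IntervalIndex | None = None,
) -> np.ndarray:
    """For each query interval, whether it overlaps >= 1 subject interval by >= 1 bp.

    Pass either `subjects` (a track, indexed on the fly) or a prebuilt `index`.
    Returns a boolean array aligned with `queries`.
    """
    if index is None:
        if subjects is None:
            raise ValueError("provide either subjects or a prebuilt index")
        index = IntervalIndex(subjects)
    out = np.zeros(len(queries), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, q in enumerate(queries):
        by_chrom.setdefault(q[0], []).append(i)
    for chrom, idx_list in by_chrom.items():
        idx = np.asarray(idx_list, dtype=np.intp)
        qs = np.fromiter((queries[i][1] for i in idx_list), dtype=np.int64, count=len(idx_list))
        qe = np.fromiter((queries[i][2] for i in idx_list), dtype=np.int64, count=len(idx_list))
        out[idx] = index.overlaps(chrom, qs, qe)
    return out
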