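"""Pairwise genomic-track comparison statistics.

Covers the statistics used when benchmarking one peak-set collection
against another: the base-level Jaccard statistic (shared covered bases
over bases covered by either track), an interval-level co-localization
Fisher test, mean peak length, and the fold-change classification of
peak-set sizes between collection versions.

The co-localization test builds an auditable interval-count 2x2 table:
with both tracks merged, n11 = merged-A intervals overlapping B,
n12 = |A| - n11, n21 = merged-B intervals overlapping A minus the n11
already counted (floored at 0), and n22 fills the remaining "slots" of
a genome of G bases divided into segments of the pooled mean merged
interval length mu, i.e. max(0, floor(G/mu) - n11 - n12 - n21). The
table is returned alongside the one-sided p so the construction can be
inspected; numeric agreement with any particular external interval
toolkit is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enrich import ContingencyTable, fisher_enrichment_p
from .intervals import Interval, coverage_bp, intersection_bp, merge_intervals, overlaps_any

__all__ = [
    "TrackComparison",
    "jaccard",
    "colocalization_fisher",
    "mean_peak_length",
    "classify_change",
]


@dataclass
class TrackComparison:
    """Base-level overlap summary of two tracks; co-localization fields optional."""

    jaccard: float
    intersection_bp: int
    union_bp: int
    empty_union: bool = False
    coloc_p: float | None = None
    coloc_table: ContingencyTable | None = None

    def __post_init__(self) -> None:
        if self.union_bp > 0 and abs(self.jaccard - self.intersection_bp / self.union_bp) > 1e-12:
            raise ValueError("jaccard inconsistent with intersection/union")


def jaccard(track_a: Sequence[Interval], track_b: Sequence[Interval]) -> TrackComparison:
    """Jaccard statistic of two tracks: shared bases / bases covered by either.

    Both tracks are merged first. An empty union yields jaccard 0 with
    `empty_union` flagged.
    """
    inter = intersection_bp(track_a, track_b)
    union = coverage_bp(track_a) + coverage_bp(track_b) - inter
    if union == 0:
        return TrackComparison(0.0, 0, 0, empty_union=True)
    return TrackComparison(inter / union, inter, union)


def colocalization_fisher(
    track_a: Sequence[Interval],
    track_b: Sequence[Interval],
    genome_bp: int,
) -> tuple[float, ContingencyTable]:
    """One-sided Fisher p for interval-level co-localization of two tracks.

    See the module docstring for the 2x2 construction. `genome_bp` must
    be at least the union span of the two tracks.
    """
    if not track_a or not track_b:
        raise ValueError("both tracks must be non-empty")
    a_merged = merge_intervals(track_a)
    b_merged = merge_intervals(track_b)
    union = coverage_bp(track_a) + coverage_bp(track_b) - intersection_bp(track_a, track_b)
    if genome_bp < union:
        raise ValueError(f"genome size {genome_bp} smaller than track union {union}")
    n11 = int(overlaps_any(a_merged, b_merged).sum())
    n_b_overlap = int(overlaps_any(b_merged, a_merged).sum())
    n12 = len(a_merged) - n11
    n21 = max(0, n_b_overlap - n11)
    pooled_bp = sum(iv.end - iv.start for iv in a_merged) + sum(iv.end - iv.start for iv in b_merged)
    mu = pooled_bp / (len(a_merged) + len(b_merged))
    n22 = max(0, int(genome_bp // mu) - n11 - n12 - n21)
    table = ContingencyTable(n11, n12, n21, n22)
    return fisher_enrichment_p(table, alternative="greater"), table


def mean_peak_length(track: Sequence[Interval]) -> float:
    """Arithmetic mean of interval lengths (bp). Errors on an empty track."""
    if not track:
        raise ValueError("mean peak length undefined for an empty track")
    return float(np.mean([iv.end - iv.start for iv in track]))


def classify_change(old_count: int | None, new_count: int) -> str:
    """Classify a peak-set size change between two collection versions.

    Absent before -> "New"; at least twofold up -> "Increase"; at least
    twofold down -> "Decrease"; anything smaller -> "Small changes".
    The twofold boundaries are inclusive. With old == new == 0 both
    twofold conditions hold vacuously; the Increase branch is checked
    first.
    """
    if new_count < 0:
        raise ValueError("new_count must be >= 0")
    if old_count is None:
        return "New"
    if old_count < 0:
        raise ValueError("old_count must be >= 0 or None")
    if new_count >= 2 * old_count:
        return "Increase"
    if new_count <= old_count / 2:
        return "Decrease"
    return "Small changes"
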