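"""Peak tracks, collection metadata, FRIP, QC filters and replica selection.

A DAP-seq collection is a set of named peak tracks (BED), one per
TF-experiment, described by a TSV manifest carrying the TF locus id, TF
family, genomic-library sample type (col = native leaf gDNA, colamp =
PCR-amplified methylation-free gDNA) and optionally the FRIP (fraction
of reads in peaks) QC statistic.

Quality control mirrors the collection-building rules: peak sets with
FRIP < 0.01 or fewer than 200 peaks are discarded, and where a
replicated experiment provides both an IDR-merged track and individual
replicas, the final track is the IDR set only when it is large (> 2000
peaks) or at least twice the largest replica — otherwise the replica
with the highest FRIP wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalIndex, merge_intervals, overlaps_any

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "PeakCollection",
    "ReplicaBundle",
    "RemovalRecord",
    "read_bed",
    "write_bed",
    "compute_frip",
    "filter_collection",
    "select_final_peakset",
    "read_collection",
    "write_manifest",
    "merge_intervals",
]

SAMPLE_TYPES = ("col", "colamp", "unknown")


@dataclass
class PeakSet:
    """One named peak track with its manifest metadata."""

    name: str
    peaks: list[Interval]
    tf_id: str = ""
    tf_family: str = ""
    sample_type: str = "unknown"
    frip: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"peak set {self.name}: sample_type must be one of {SAMPLE_TYPES}")
        if self.frip is not None and not (0.0 <= self.frip <= 1.0):
            raise ValueError(f"peak set {self.name}: frip {self.frip} outside [0, 1]")
        for p in self.peaks:
            if not p.chrom or p.start < 0 or p.start >= p.end:
                raise ValueError(f"peak set {self.name}: invalid peak {p}")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PeakCollection:
    """An ordered, uniquely named set of peak tracks (one collection version)."""

    version_label: str
    peak_sets: dict[str, PeakSet] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ps in self.peak_sets.items():
            if name != ps.name:
                raise ValueError(f"collection key {name!r} != peak set name {ps.name!r}")

    def add(self, ps: PeakSet) -> None:
        if ps.name in self.peak_sets:
            raise ValueError(f"duplicate peak set name {ps.name!r}")
        self.peak_sets[ps.name] = ps

    def __iter__(self):
        return iter(self.peak_sets.values())

    def __len__(self) -> int:
        return len(self.peak_sets)


@dataclass
class ReplicaBundle:
    """An IDR-merged peak set plus the individual replicas it came from.

    Every replica must carry a FRIP value; the IDR set may be empty.
    """

    idr_set: PeakSet
    replicas: list[PeakSet]

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("ReplicaBundle needs at least one replica")
        missing = [r.name for r in self.replicas if r.frip is None]
        if missing:
            raise ValueError(f"replicas without FRIP: {missing}")


@dataclass(frozen=True)
class RemovalRecord:
    name: str
    reason: str


def read_bed(path: str | Path) -> list[Interval]:
    """Parse a 3–6 column BED file (0-based half-open), preserving input order.

    `track`/`browser`/`#` lines are skipped. Name/score/strand columns are
    retained when present. Raises ``ValueError`` naming the line for
    non-integer or inverted coordinates.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            out.append(Interval(chrom, start, end, name=name, score=score, strand=strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED, emitting only the columns that are populated."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def compute_frip(reads: Sequence[Interval], peaks: Sequence[Interval]) -> float:
    """Fraction of reads overlapping >= 1 peak by >= 1 bp.

    A "read" is any aligned interval; alignment-format handling is left
    to the caller (convert alignments to intervals first).
    """
    if len(reads) == 0:
        raise ValueError("FRIP undefined for an empty read set")
    if len(peaks) == 0:
        return 0.0
    return float(overlaps_any(reads, peaks).sum()) / len(reads)


def filter_collection(
    coll: PeakCollection,
    min_frip: float = 0.01,
    min_peaks: int = 200,
) -> tuple[PeakCollection, list[RemovalRecord]]:
    """Apply the collection QC: drop sets with FRIP < `min_frip` or < `min_peaks` peaks.

    Both thresholds are inclusive on the keep side ("less than 0.01" is
    removed, "at least 200 peaks" retained). Sets without a FRIP value
    skip the FRIP criterion with a warning. Returns the filtered
    collection and a removal report.
    """
    kept = PeakCollection(version_label=coll.version_label, provenance=dict(coll.provenance))
    removed: list[RemovalRecord] = []
    for ps in coll:
        if ps.frip is None:
            logger.warning("peak set %s has no FRIP value; FRIP criterion skipped", ps.name)
        elif ps.frip < min_frip:
            removed.append(RemovalRecord(ps.name, f"FRIP<{min_frip:g}"))
            continue
        if len(ps) < min_peaks:
            removed.append(RemovalRecord(ps.name, f"peaks<{min_peaks}"))
            continue
        kept.add(ps)
    return kept, removed


def select_final_peakset(bundle: ReplicaBundle) -> tuple[PeakSet, str]:
    """Choose the final track for a replicated experiment.

    The IDR-merged set wins iff it has more than 2000 peaks, or its size
    at least twice exceeds the largest individual replica; otherwise the
    replica with the maximal FRIP wins (ties: larger peak count, then
    name order). A lone replica with an empty IDR set is returned with
    the label "single-replica". The returned label records which branch
    fired.
    """
    if len(bundle.replicas) == 1 and len(bundle.idr_set) == 0:
        return bundle.replicas[0], "single-replica"
    max_replica = max(len(r) for r in bundle.replicas)
    if len(bundle.idr_set) > 2000:
        return bundle.idr_set, "idr:>2000-peaks"
    if len(bundle.idr_set) >= 2 * max_replica:
        return bundle.idr_set, "idr:>=2x-max-replica"
    best = min(bundle.replicas, key=lambda r: (-r.frip, -len(r), r.name))
    return best, "replica:max-frip"


MANIFEST_COLUMNS = ["name", "tf_id", "tf_family", "sample_type", "frip", "bed_path"]


def read_collection(
    manifest_path: str | Path,
    version_label: str | None = None,
) -> PeakCollection:
    """Load a collection from a TSV manifest; BED paths resolve relative to it.

    Columns: name, tf_id, tf_family, sample_type, frip (blank allowed),
    bed_path.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {missing}")
    coll = PeakCollection(version_label=version_label or manifest_path.stem)
    for _, row in df.iterrows():
        bed_path = Path(row["bed_path"])
        if not bed_path.is_absolute():
            bed_path = manifest_path.parent / bed_path
        frip = float(row["frip"]) if row["frip"] != "" else None
        coll.add(
            PeakSet(
                name=row["name"],
                peaks=read_bed(bed_path),
                tf_id=row["tf_id"],
                tf_family=row["tf_family"],
                sample_type=row["sample_type"] or "unknown",
                frip=frip,
            )
        )
    if len(coll) == 0:
        raise ValueError(f"{manifest_path}: empty collection")
    return coll


def write_manifest(coll: PeakCollection, manifest_path: str | Path,
                   bed_paths: Mapping[str, str]) -> None:
    """Write the manifest TSV for a collection (bed_paths: name -> relative path)."""
    rows = []
    for ps in coll:
        rows.append({
            "name": ps.name,
            "tf_id": ps.tf_id,
            "tf_family": ps.tf_family,
            "sample_type": ps.sample_type,
            "frip": "" if ps.frip is None else f"{ps.frip:.4f}",
            "bed_path": bed_paths[ps.name],
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, sep="\t", index=False)
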