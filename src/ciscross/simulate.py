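"""Deterministic synthetic data: genomes, gene annotations, peak-set
collections with planted enrichment signal, and aligned-read intervals.

This generator stands in for a real DAP-seq-derived collection so that
the whole pipeline — annotation parsing, promoter construction, QC,
enrichment — is exercisable and testable offline. The default
dimensions emulate a desk-scale slice of an Arabidopsis-like setup:
five chromosomes, 2,000 non-overlapping genes (one gene per ~5 kb,
close to real gene density), 1,000 bp promoters, 100 peak tracks of 300
peaks with lengths 100–400 bp (bracketing the ~250 bp typical of
variable-width peak calling), and a 100-gene foreground.

A *planted* peak set models a true upstream regulator: each foreground
gene's promoter receives a peak with probability ``p_fg`` and each
background gene's with probability ``p_bg``; planted peaks are placed
fully inside the promoter so a hit is guaranteed regardless of the
promoter length in force. Sets with ``p_fg == p_bg`` carry no signal
and are absent from the truth record.

Randomness: one RNG stream per artifact, keyed off (seed, artifact
name), so adding a new output never perturbs existing ones, and the
same seed yields byte-identical files.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneRecord, GenomeAnnotation, build_promoters, write_gff3
from .intervals import Interval
from .peaks import PeakCollection, PeakSet, write_bed, write_manifest

__all__ = [
    "PlantedSignal",
    "FixtureSpec",
    "Fixture",
    "FixturePaths",
    "build_fixture",
    "generate_fixture",
    "generate_reads",
]

_TF_FAMILIES = (
    "AP2/ERF", "bZIP", "bHLH", "MYB", "NAC", "WRKY",
    "C2H2 (Zn)", "HD-ZIP", "ARF", "EIL", "GATA", "TCP",
)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream keyed off (seed, artifact label)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class PlantedSignal:
    """Per-gene peak-planting probabilities for one peak set."""

    set_name: str
    p_fg: float
    p_bg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fg <= 1.0 and 0.0 <= self.p_bg <= 1.0):
            raise ValueError(f"planting probabilities must lie in [0, 1]: {self}")


@dataclass(frozen=True)
class FixtureSpec:
    """Dimensions and signal of one synthetic dataset."""

    seed: int
    chrom_lengths: tuple[int, ...] = (2_000_000,) * 5
    n_genes: int = 2000
    gene_length: tuple[int, int] = (500, 2500)
    promoter_length: int = 1000
    n_peak_sets: int = 100
    peaks_per_set: int = 300
    peak_length: tuple[int, int] = (100, 400)
    n_foreground: int = 100
    planted: tuple[PlantedSignal, ...] = ()

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.peak_length[0] > self.promoter_length:
            raise ValueError("peaks must fit inside a promoter for planting")
        if self.n_foreground >= self.n_genes:
            raise ValueError("foreground must be a strict subset of the genes")


@dataclass
class Fixture:
    """In-memory synthetic dataset plus the planted-signal truth record."""

    spec: FixtureSpec
    annotation: GenomeAnnotation
    collection: PeakCollection
    foreground: list[str]
    truth: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class FixturePaths:
    """Files written by :func:`generate_fixture`."""

    gff3: Path
    chrom_sizes: Path
    manifest: Path
    gene_list: Path
    truth: Path
    bed_dir: Path


def _chrom_names(n: int) -> list[str]:
    return [f"Chr{i + 1}" for i in range(n)]


def _allocate_genes(spec: FixtureSpec) -> list[int]:
    """Gene counts per chromosome, proportional to length (largest remainder)."""
    lengths = np.asarray(spec.chrom_lengths, dtype=float)
    quota = spec.n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = spec.n_genes - int(counts.sum())
    for i in np.argsort(-(quota - counts))[:remainder]:
        counts[i] += 1
    return counts.tolist()


def _place_genes(spec: FixtureSpec) -> list[GeneRecord]:
    """One gene per equal-width slot, with a promoter-length margin on both
    sides so every promoter has full width and genes never overlap."""
    rng = _rng(spec.seed, "genes")
    gmin, gmax = spec.gene_length
    margin = spec.promoter_length
    genes: list[GeneRecord] = []
    for ci, (chrom, n_c) in enumerate(zip(_chrom_names(len(spec.chrom_lengths)),
                                          _allocate_genes(spec))):
        if n_c == 0:
            continue
        slot = spec.chrom_lengths[ci] // n_c
        if slot < gmax + 2 * margin + 1:
            raise ValueError(
                f"chromosome {chrom} too small to place {n_c} genes of up to {gmax} bp "
                f"with {margin} bp promoter margins without overlap"
            )
        for j in range(n_c):
            gene_len = int(rng.integers(gmin, gmax + 1))
            lo = j * slot + margin
            hi = j * slot + slot - gene_len - margin
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"AT{ci + 1}G{(j + 1) * 10:05d}", chrom,
                                    start, start + gene_len, strand))
    return genes


def _uniform_peaks(rng: np.random.Generator, spec: FixtureSpec, n: int) -> list[Interval]:
    lengths = np.asarray(spec.chrom_lengths, dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    plens = rng.integers(spec.peak_length[0], spec.peak_length[1] + 1, size=n)
    clens = np.asarray(spec.chrom_lengths)[chrom_idx]
    starts = (rng.random(n) * (clens - plens)).astype(np.int64)
    names = _chrom_names(len(spec.chrom_lengths))
    return [Interval(names[int(c)], int(s), int(s + l))
            for c, s, l in zip(chrom_idx, starts, plens)]


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the dataset in memory: annotation, collection, foreground, truth."""
    genes = _place_genes(spec)
    annotation = GenomeAnnotation(
        chrom_sizes={c: l for c, l in zip(_chrom_names(len(spec.chrom_lengths)),
                                          spec.chrom_lengths)},
        genes=genes,
    )
    promoters = build_promoters(annotation, spec.promoter_length)

    rng_fg = _rng(spec.seed, "foreground")
    all_ids = [g.id for g in genes]
    foreground = sorted(rng_fg.choice(all_ids, size=spec.n_foreground, replace=False).tolist())
    fg_set = set(foreground)

    planted_by_name = {p.set_name: p for p in spec.planted}
    rng_frip = _rng(spec.seed, "frip")
    collection = PeakCollection(version_label=f"synthetic-seed{spec.seed}")
    for i in range(spec.n_peak_sets):
        sample_type = "col" if i % 2 == 0 else "colamp"
        name = f"TF{i:03d}_{sample_type}"
        frip = round(float(rng_frip.uniform(0.02, 0.60)), 4)
        rng = _rng(spec.seed, f"peaks:{name}")
        if name in planted_by_name:
            sig = planted_by_name[name]
            pk: list[Interval] = []
            for gid in sorted(promoters.promoters):
                prob = sig.p_fg if gid in fg_set else sig.p_bg
                if rng.random() < prob:
                    prom = promoters.promoters[gid]
                    width = prom.end - prom.start
                    plen = int(rng.integers(spec.peak_length[0],
                                            min(spec.peak_length[1], width) + 1))
                    start = prom.start + int(rng.integers(0, width - plen + 1))
                    pk.append(Interval(prom.chrom, start, start + plen))
        else:
            pk = _uniform_peaks(rng, spec, spec.peaks_per_set)
        collection.add(PeakSet(
            name=name, peaks=pk,
            tf_id=f"AT{(i % len(spec.chrom_lengths)) + 1}G{90000 + i:05d}",
            tf_family=_TF_FAMILIES[i % len(_TF_FAMILIES)],
            sample_type=sample_type, frip=frip,
        ))

    truth = {p.set_name: (p.p_fg, p.p_bg) for p in spec.planted if p.p_fg != p.p_bg}
    return Fixture(spec=spec, annotation=annotation, collection=collection,
                   foreground=foreground, truth=truth)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixturePaths:
    """Build the dataset and write every file the pipeline consumes.

    Emits GFF3 + chromosome sizes, one BED per peak set, the collection
    manifest TSV, the foreground gene list and a truth TSV naming
    planted sets. Identical specs yield byte-identical files.
    """
    fx = build_fixture(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_dir = out_dir / "peaks"
    bed_dir.mkdir(exist_ok=True)

    paths = FixturePaths(
        gff3=out_dir / "genome.gff3",
        chrom_sizes=out_dir / "genome.chrom.sizes",
        manifest=out_dir / "manifest.tsv",
        gene_list=out_dir / "genes.txt",
        truth=out_dir / "truth.tsv",
        bed_dir=bed_dir,
    )
    write_gff3(fx.annotation, paths.gff3)
    with open(paths.chrom_sizes, "w") as fh:
        for chrom, length in fx.annotation.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    bed_paths: dict[str, str] = {}
    for ps in fx.collection:
        rel = f"peaks/{ps.name}.bed"
        write_bed(ps.peaks, out_dir / rel)
        bed_paths[ps.name] = rel
    write_manifest(fx.collection, paths.manifest, bed_paths)
    with open(paths.gene_list, "w") as fh:
        fh.writelines(g + "\n" for g in fx.foreground)
    with open(paths.truth, "w") as fh:
        fh.write("set_name\tp_fg\tp_bg\n")
        for name, (p_fg, p_bg) in sorted(fx.truth.items()):
            fh.write(f"{name}\t{p_fg:g}\t{p_bg:g}\n")
    return paths


def generate_reads(
    peaks: Sequence[Interval],
    genome: int | Mapping[str, int],
    n_reads: int,
    in_peak_fraction: float = 0.3,
    read_len: int = 50,
    seed: int = 0,
) -> list[Interval]:
    """Simulate aligned-read intervals with a controlled in-peak fraction.

    ceil(in_peak_fraction * n_reads) reads are placed overlapping a
    randomly chosen peak; the rest fall uniformly on the genome, so the
    resulting FRIP is at least `in_peak_fraction` (uniform reads may
    also land in peaks). `genome` is a chrom -> length mapping, or an
    int for a single-chromosome genome named "chr1".
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not (0.0 <= in_peak_fraction <= 1.0):
        raise ValueError("in_peak_fraction must lie in [0, 1]")
    sizes = {"chr1": int(genome)} if isinstance(genome, int) else dict(genome)
    if not sizes:
        raise ValueError("empty genome")
    if read_len <= 0 or read_len > min(sizes.values()):
        raise ValueError(f"read length {read_len} exceeds a chromosome length")
    for p in peaks:
        if p.chrom not in sizes:
            raise ValueError(f"peak chromosome {p.chrom!r} absent from genome")

    rng = _rng(seed, "reads")
    n_in = math.ceil(in_peak_fraction * n_reads)
    if n_in > 0 and len(peaks) == 0:
        raise ValueError("cannot place in-peak reads: peak set is empty")
    reads: list[Interval] = []
    for _ in range(n_in):
        p = peaks[int(rng.integers(0, len(peaks)))]
        clen = sizes[p.chrom]
        lo = max(0, p.start - read_len + 1)
        hi = min(clen - read_len, p.end - 1)
        start = int(rng.integers(lo, hi + 1))
        reads.append(Interval(p.chrom, start, start + read_len))
    chroms = sorted(sizes)
    lengths = np.asarray([sizes[c] for c in chroms], dtype=float)
    for _ in range(n_reads - n_in):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        start = int(rng.integers(0, sizes[chroms[ci]] - read_len + 1))
        reads.append(Interval(chroms[ci], start, start + read_len))
    return reads
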