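"""Genome annotation and strand-aware promoter construction.

Reads gene features from GFF3 (1-based inclusive; converted on read to
0-based half-open) together with a two-column chromosome-sizes file, and
derives per-gene upstream "promoter" windows: the L bp strictly upstream
of the gene's 5' boundary on its strand, clipped to the chromosome.
The set of genes with a non-empty promoter is the *universe* against
which enrichment foreground/background gene counts are formed.

Gene identifiers are matched case-insensitively after whitespace
trimming (AGI locus ids are conventionally upper-case; user input
varies), so ids are normalised with :func:`normalize_gene_id` on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .intervals import Interval

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "PromoterSet",
    "STANDARD_PROMOTER_LENGTHS",
    "normalize_gene_id",
    "read_chrom_sizes",
    "load_annotation",
    "build_promoters",
    "write_gff3",
]

#: Promoter lengths offered by the original service; other positive values
#: are accepted but logged as non-standard.
STANDARD_PROMOTER_LENGTHS = (500, 1000, 1500, 2000, 2500)


def normalize_gene_id(gene_id: str) -> str:
    """Canonical form of a gene id: whitespace-trimmed, upper-case."""
    return gene_id.strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    """One gene feature; coordinates 0-based half-open, strand '+' or '-'."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus the gene records drawn from them.

    `n_dropped` counts genes discarded because their chromosome was absent
    from the sizes file; `n_duplicates` counts duplicate gene ids skipped.
    """

    chrom_sizes: dict[str, int]
    genes: list[GeneRecord]
    n_dropped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.id}: chromosome {g.chrom!r} not in chrom_sizes")
            if not (0 <= g.start < g.end <= self.chrom_sizes[g.chrom]):
                raise ValueError(f"gene {g.id}: invalid coordinates [{g.start}, {g.end})")


@dataclass
class PromoterSet:
    """Per-gene upstream windows for one promoter length.

    `promoters` maps gene id -> Interval (with `name` = gene id and
    `strand` set); `universe` is the set of ids with a non-empty window.
    """

    length: int
    promoters: dict[str, Interval]
    universe: set[str] = field(default_factory=set)

    def to_bed(self, path: str | Path) -> None:
        """Write promoters as BED6 (name = gene id, score 0)."""
        rows = sorted(self.promoters.values(), key=lambda iv: (iv.chrom, iv.start, iv.name))
        with open(path, "w") as fh:
            for iv in rows:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a whitespace-separated two-column (name, length) file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'name length'")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer length {fields[1]!r}") from exc
            if length <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive length {length}")
            sizes[fields[0]] = length
    if not sizes:
        raise ValueError(f"{path}: no chromosome sizes found")
    return sizes


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def load_annotation(
    gff3_path: str | Path,
    chrom_sizes_path: str | Path,
    feature_type: str = "gene",
    on_duplicate: str = "first",
) -> GenomeAnnotation:
    """Load gene records of one feature type from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. Records on chromosomes missing from the sizes file are
    dropped (warned, counted). Duplicate gene ids keep the first record
    (``on_duplicate="first"``, warned and counted) or raise
    (``on_duplicate="error"``).

    Raises ``ValueError`` with a line number on any unparseable line,
    and if no gene of the requested type is found.
    """
    if on_duplicate not in ("first", "error"):
        raise ValueError(f"on_duplicate must be 'first' or 'error', got {on_duplicate!r}")
    chrom_sizes = read_chrom_sizes(chrom_sizes_path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    n_duplicates = 0
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                # tolerate space-separated toy files
                fields = line.split(None, 8)
            if len(fields) < 9:
                raise ValueError(f"{gff3_path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_field = fields[:9]
            if ftype != feature_type:
                continue
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"{gff3_path}: line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{gff3_path}: line {lineno}: invalid range {start}..{end}")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{gff3_path}: line {lineno}: gene feature needs strand '+'/'-', got {strand!r}"
                )
            attrs = _parse_gff3_attributes(attr_field)
            if "ID" not in attrs or not attrs["ID"]:
                raise ValueError(f"{gff3_path}: line {lineno}: missing ID attribute")
            gid = normalize_gene_id(attrs["ID"])
            if chrom not in chrom_sizes:
                logger.warning("gene %s on chromosome %s absent from chrom sizes; dropped", gid, chrom)
                n_dropped += 1
                continue
            if end > chrom_sizes[chrom]:
                raise ValueError(
                    f"{gff3_path}: line {lineno}: gene {gid} extends past chromosome "
                    f"{chrom} (length {chrom_sizes[chrom]})"
                )
            if gid in seen:
                if on_duplicate == "error":
                    raise ValueError(f"{gff3_path}: line {lineno}: duplicate gene id {gid}")
                logger.warning("duplicate gene id %s at line %d; keeping first occurrence", gid, lineno)
                n_duplicates += 1
                continue
            seen.add(gid)
            genes.append(GeneRecord(gid, chrom, start - 1, end, strand))
    if not genes:
        raise ValueError(f"{gff3_path}: no features of type {feature_type!r} found")
    return GenomeAnnotation(chrom_sizes, genes, n_dropped=n_dropped, n_duplicates=n_duplicates)


def build_promoters(ann: GenomeAnnotation, length: int) -> PromoterSet:
    """Construct the L bp strictly-upstream window for every gene.

    For '+' genes the window is [max(0, start - L), start); for '-'
    genes [end, min(chrom_len, end + L)). The TSS base itself is
    excluded. Genes whose window clips to zero width are excluded from
    the universe with a warning.
    """
    if length <= 0:
        raise ValueError(f"promoter length must be positive, got {length}")
    if length not in STANDARD_PROMOTER_LENGTHS:
        logger.warning("promoter length %d bp is non-standard (service offered %s)",
                       length, STANDARD_PROMOTER_LENGTHS)
    promoters: dict[str, Interval] = {}
    excluded: list[str] = []
    for g in ann.genes:
        chrom_len = ann.chrom_sizes[g.chrom]
        if g.strand == "+":
            s, e = max(0, g.start - length), g.start
        else:
            s, e = g.end, min(chrom_len, g.end + length)
        if e - s <= 0:
            excluded.append(g.id)
            continue
        promoters[g.id] = Interval(g.chrom, s, e, name=g.id, strand=g.strand)
    if excluded:
        logger.warning("%d gene(s) with empty promoter excluded from universe: %s%s",
                       len(excluded), ", ".join(excluded[:5]), "..." if len(excluded) > 5 else "")
    return PromoterSet(length=length, promoters=promoters, universe=set(promoters))


def write_gff3(ann: GenomeAnnotation, path: str | Path, feature_type: str = "gene") -> None:
    """Write gene records back to GFF3 (1-based inclusive), stable order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\tciscross\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
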