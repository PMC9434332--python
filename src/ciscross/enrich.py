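"""The enrichment core: which TFs' binding profiles are over-represented
in the promoters of an input gene list?

For each peak set in a collection, the genes of the universe are split
four ways — foreground (input) vs background (rest), promoter overlaps
a peak vs not — giving a 2x2 contingency table

                 overlap   no overlap
    foreground      a          b
    background      c          d

whose one-sided (enrichment) Fisher's exact p-value is
P(X >= a) for X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b).
p-values are corrected across all peak sets of the collection
(Benjamini-Hochberg FDR by default, Bonferroni optionally) and the peak
sets are ranked in ascending order of adjusted significance.

A gene counts once per peak set however many peaks fall in its
promoter; overlap means >= 1 shared base (half-open semantics: a peak
starting exactly at the promoter end does not overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import PromoterSet, normalize_gene_id
from .intervals import Interval, IntervalIndex
from .peaks import PeakCollection, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ListOverlap",
    "read_gene_list",
    "promoter_hits",
    "fisher_enrichment_p",
    "adjust_pvalues",
    "run_ciscross_main",
    "ciscross_light",
    "gene_to_tf_table",
    "compare_regulator_lists",
    "results_to_frame",
    "format_p",
]


class ContingencyTable(NamedTuple):
    """Counts (a, b, c, d): (fg hit, fg miss, bg hit, bg miss)."""

    a: int
    b: int
    c: int
    d: int


@dataclass
class EnrichmentResult:
    """One ranked row of the enrichment output for a single peak set."""

    peak_set_name: str
    tf_id: str
    tf_family: str
    table: ContingencyTable
    p_raw: float
    p_adj: float
    rank: int
    hit_genes: set[str]


@dataclass
class ListOverlap:
    """Overlap of two significant-regulator lists (Jaccard of name sets, in %)."""

    percent: float
    shared: set[str]
    only_a: set[str]
    only_b: set[str]
    n_a: int
    n_b: int
    both_empty: bool = False


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene id per line; '#' comments and blank lines ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


class _PromoterIndex:
    """Promoter intervals grouped per chromosome for batched overlap queries."""

    def __init__(self, promoters: PromoterSet):
        self.ids: list[str] = sorted(promoters.promoters)
        by_chrom: dict[str, list[int]] = {}
        for i, gid in enumerate(self.ids):
            by_chrom.setdefault(promoters.promoters[gid].chrom, []).append(i)
        self._groups: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
        for chrom, idx_list in by_chrom.items():
            idx = np.asarray(idx_list, dtype=np.intp)
            starts = np.asarray([promoters.promoters[self.ids[i]].start for i in idx_list], dtype=np.int64)
            ends = np.asarray([promoters.promoters[self.ids[i]].end for i in idx_list], dtype=np.int64)
            self._groups.append((chrom, idx, starts, ends))

    def hit_mask(self, peak_index: IntervalIndex) -> np.ndarray:
        mask = np.zeros(len(self.ids), dtype=bool)
        for chrom, idx, starts, ends in self._groups:
            mask[idx] = peak_index.overlaps(chrom, starts, ends)
        return mask

    def hit_ids(self, peak_index: IntervalIndex) -> set[str]:
        mask = self.hit_mask(peak_index)
        return {self.ids[i] for i in np.flatnonzero(mask)}


def promoter_hits(peak_set: PeakSet, promoters: PromoterSet) -> set[str]:
    """Gene ids whose promoter overlaps >= 1 peak of the set by >= 1 bp."""
    if not promoters.promoters:
        raise ValueError("empty promoter set")
    return _PromoterIndex(promoters).hit_ids(IntervalIndex(peak_set.peaks))


def fisher_enrichment_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact test p-value for the 2x2 table.

    ``alternative="greater"`` (the default, matching the enrichment
    question) returns the upper hypergeometric tail P(X >= a);
    ``"two-sided"`` is available as an option.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative count in table {table}")
    if alternative == "greater":
        n_pop = a + b + c + d
        k_success = a + c
        n_draw = a + b
        return float(min(1.0, stats.hypergeom.sf(a - 1, n_pop, k_success, n_draw)))
    if alternative == "two-sided":
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment, output aligned with input order.

    ``"BH"``: Benjamini-Hochberg step-up with monotonicity enforcement,
    clipped at 1. ``"bonferroni"``: min(1, N*p).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"BH": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"method must be 'BH' or 'bonferroni', got {method!r}")
    return multipletests(p, method=key)[1]


def run_ciscross_main(
    gene_list: Iterable[str],
    promoters: PromoterSet,
    collection: PeakCollection,
    method: str = "BH",
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Rank every peak set of the collection by promoter enrichment in the input genes.

    The foreground is the input list intersected with the universe
    (unmatched ids are dropped with a warning; duplicates collapse); the
    background is the rest of the universe. Results are sorted ascending
    by adjusted p, ties by raw p, then peak set name, and ranked 1..N.

    Raises ``ValueError`` if no input id matches the universe or the
    foreground swallows the whole universe.
    """
    if len(collection) == 0:
        raise ValueError("empty peak collection")
    requested = {normalize_gene_id(g) for g in gene_list if g.strip()}
    universe = promoters.universe
    foreground = requested & universe
    unmatched = sorted(requested - universe)
    if not foreground:
        raise ValueError(
            "no input gene id matches the promoter universe; unmatched ids: "
            + ", ".join(unmatched)
        )
    if foreground == universe:
        raise ValueError("input gene list covers the entire universe; no background remains")
    if unmatched:
        logger.warning("%d input gene id(s) not in universe, dropped: %s%s",
                       len(unmatched), ", ".join(unmatched[:10]),
                       "..." if len(unmatched) > 10 else "")

    prom_index = _PromoterIndex(promoters)
    fg_mask = np.asarray([gid in foreground for gid in prom_index.ids], dtype=bool)
    n_fg = int(fg_mask.sum())
    n_bg = len(prom_index.ids) - n_fg

    names: list[str] = []
    partial: list[tuple[PeakSet, ContingencyTable, set[str], float]] = []
    for ps in collection:
        hit_mask = prom_index.hit_mask(IntervalIndex(ps.peaks))
        a = int((hit_mask & fg_mask).sum())
        c = int(hit_mask.sum()) - a
        table = ContingencyTable(a, n_fg - a, c, n_bg - c)
        hits = {prom_index.ids[i] for i in np.flatnonzero(hit_mask & fg_mask)}
        p_raw = fisher_enrichment_p(table, alternative=alternative)
        partial.append((ps, table, hits, p_raw))
        names.append(ps.name)

    p_adj = adjust_pvalues([t[3] for t in partial], method=method)
    order = sorted(range(len(partial)),
                   key=lambda i: (p_adj[i], partial[i][3], names[i]))
    results: list[EnrichmentResult] = []
    for rank, i in enumerate(order, 1):
        ps, table, hits, p_raw = partial[i]
        results.append(EnrichmentResult(
            peak_set_name=ps.name, tf_id=ps.tf_id, tf_family=ps.tf_family,
            table=table, p_raw=p_raw, p_adj=float(p_adj[i]), rank=rank,
            hit_genes=hits,
        ))
    return results


def ciscross_light(
    gene_id: str,
    promoters: PromoterSet,
    collection: PeakCollection,
) -> pd.DataFrame:
    """All peaks, from every peak set, lying in one gene's promoter.

    Returns a DataFrame with columns (peak_set, tf_id, chrom, start,
    end) giving the genomic coordinates of each overlapping peak; empty
    when the promoter holds no peak. Raises ``KeyError`` for a gene id
    outside the universe.
    """
    gid = normalize_gene_id(gene_id)
    if gid not in promoters.universe:
        raise KeyError(f"gene id {gid!r} not in the promoter universe")
    prom = promoters.promoters[gid]
    rows: list[dict] = []
    for ps in collection:
        for p in ps.peaks:
            if p.chrom == prom.chrom and p.start < prom.end and p.end > prom.start:
                rows.append({"peak_set": ps.name, "tf_id": ps.tf_id,
                             "chrom": p.chrom, "start": p.start, "end": p.end})
    return pd.DataFrame(rows, columns=["peak_set", "tf_id", "chrom", "start", "end"])


def gene_to_tf_table(
    gene_ids: Iterable[str],
    promoters: PromoterSet,
    collection: PeakCollection,
) -> pd.DataFrame:
    """Per (gene, peak set) count of peaks in the gene's promoter (hits only)."""
    ids = sorted({normalize_gene_id(g) for g in gene_ids} & promoters.universe)
    proms = [promoters.promoters[g] for g in ids]
    rows: list[dict] = []
    for ps in collection:
        starts_by: dict[str, list[int]] = {}
        ends_by: dict[str, list[int]] = {}
        for p in ps.peaks:
            starts_by.setdefault(p.chrom, []).append(p.start)
            ends_by.setdefault(p.chrom, []).append(p.end)
        arr = {c: (np.asarray(starts_by[c]), np.asarray(ends_by[c])) for c in starts_by}
        for gid, prom in zip(ids, proms):
            if prom.chrom not in arr:
                continue
            s, e = arr[prom.chrom]
            n = int(((s < prom.end) & (e > prom.start)).sum())
            if n > 0:
                rows.append({"gene": gid, "peak_set": ps.name, "n_peaks_in_promoter": n})
    return pd.DataFrame(rows, columns=["gene", "peak_set", "n_peaks_in_promoter"])


def compare_regulator_lists(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    fdr_cut: float = 0.05,
) -> ListOverlap:
    """Percentage overlap of the significant-regulator lists of two runs.

    Significance is adjusted p < `fdr_cut`; the matching key is the
    peak-set name; overlap % = 100 * |A n B| / |A u B|. Two empty lists
    are reported as 100% with `both_empty` flagged.
    """
    if not results_a or not results_b:
        raise ValueError("both result lists must be non-empty")
    sig_a = {r.peak_set_name for r in results_a if r.p_adj < fdr_cut}
    sig_b = {r.peak_set_name for r in results_b if r.p_adj < fdr_cut}
    union = sig_a | sig_b
    if not union:
        logger.warning("both significant sets empty at FDR < %g; overlap reported as 100%%", fdr_cut)
        return ListOverlap(100.0, set(), set(), set(), 0, 0, both_empty=True)
    shared = sig_a & sig_b
    return ListOverlap(
        percent=100.0 * len(shared) / len(union),
        shared=shared, only_a=sig_a - sig_b, only_b=sig_b - sig_a,
        n_a=len(sig_a), n_b=len(sig_b),
    )


def format_p(p: float) -> str:
    """Stable textual form for p-values: scientific below 1e-4, fixed otherwise."""
    return f"{p:.6e}" if p < 1e-4 else f"{p:.6f}"


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Ranked results as a DataFrame matching the TSV output layout."""
    rows = []
    for r in results:
        rows.append({
            "rank": r.rank, "peak_set": r.peak_set_name, "tf_id": r.tf_id,
            "tf_family": r.tf_family, "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d,
            "p_raw": format_p(r.p_raw), "p_adj": format_p(r.p_adj),
            "hit_genes": ";".join(sorted(r.hit_genes)),
        })
    return pd.DataFrame(rows, columns=["rank", "peak_set", "tf_id", "tf_family",
                                       "a", "b", "c", "d", "p_raw", "p_adj", "hit_genes"])
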