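"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written against the *definitions* (exact
integer enumeration, per-base boolean masks, all-pairs scans) rather
than sharing any code path with the package.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.special import gammaln


def hypergeom_tail_exact(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), exact integers."""
    n_pop = a + b + c + d
    k_succ = a + c
    n_draw = a + b
    num = sum(comb(k_succ, k) * comb(n_pop - k_succ, n_draw - k)
              for k in range(a, min(k_succ, n_draw) + 1))
    return num / comb(n_pop, n_draw)


def hypergeom_tail_lgamma(a: int, b: int, c: int, d: int) -> float:
    """Same tail, summed from the log-gamma pmf formula (for large margins)."""
    n_pop = a + b + c + d
    k_succ = a + c
    n_draw = a + b
    kmax = min(k_succ, n_draw)
    if a > kmax:
        return 0.0
    k = np.arange(a, kmax + 1)

    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    logt = logc(k_succ, k) + logc(n_pop - k_succ, n_draw - k) - logc(n_pop, n_draw)
    m = logt.max()
    return float(min(1.0, np.exp(m) * np.exp(logt - m).sum()))


def bh_stepup(p):
    """Benjamini-Hochberg step-up: p*N/rank, cumulative min from the top, clip at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def bonferroni(p):
    return np.minimum(1.0, np.asarray(p, dtype=float) * len(p))


def naive_overlap_hits(promoters: dict, peaks: list) -> set:
    """All-pairs scan: gene ids whose promoter shares >= 1 base with >= 1 peak."""
    hits = set()
    for gid, prom in promoters.items():
        for pk in peaks:
            if pk[0] == prom[0] and pk[1] < prom[2] and pk[2] > prom[1]:
                hits.add(gid)
                break
    return hits


def base_masks(track, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(l, dtype=bool) for c, l in chrom_sizes.items()}
    for iv in track:
        masks[iv[0]][iv[1]:iv[2]] = True
    return masks


def mask_jaccard(track_a, track_b, chrom_sizes: dict[str, int]):
    """(jaccard, intersection_bp, union_bp) from per-base boolean masks."""
    ma = base_masks(track_a, chrom_sizes)
    mb = base_masks(track_b, chrom_sizes)
    inter = sum(int((ma[c] & mb[c]).sum()) for c in chrom_sizes)
    union = sum(int((ma[c] | mb[c]).sum()) for c in chrom_sizes)
    return (0.0 if union == 0 else inter / union), inter, union


def replica_rule_says_idr(idr_count: int, replica_counts: list[int]) -> bool:
    """Independent restatement: IDR wins iff > 2000 peaks or >= twice the largest replica."""
    return idr_count > 2000 or idr_count >= 2 * max(replica_counts)
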