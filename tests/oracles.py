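"""Independent brute-force oracles for interval arithmetic and statistics.

Everything here is deliberately naive: per-base set membership, O(n*m)
loops, exact fractions, closed-form rank statistics.  The oracles share
no code with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Interval oracles (per-base sets, plain loops)


def brute_intron_set(transcripts: dict) -> list:
    """Unique non-overlapping introns of one gene.

    ``transcripts``: transcript id -> sorted exon [(start, end)].
    Rules: candidate gaps between consecutive exons; drop candidates
    touching any exonic base of the gene; deduplicate identical spans to
    the smallest transcript id; resolve residual overlaps greedily in
    (transcript id, start) order.  Returns sorted (start, end) list.
    """
    exon_bases = set()
    for exons in transcripts.values():
        for s, e in exons:
            exon_bases.update(range(s, e))
    candidates = {}
    for tid in sorted(transcripts):
        exons = transcripts[tid]
        for i in range(len(exons) - 1):
            gap = (exons[i][1], exons[i + 1][0])
            if gap[1] <= gap[0]:
                continue
            if gap not in candidates:
                candidates[gap] = tid
    clean = [
        (iv, tid)
        for iv, tid in candidates.items()
        if not any(b in exon_bases for b in range(iv[0], iv[1]))
    ]
    kept_bases: set = set()
    kept = []
    for iv, tid in sorted(clean, key=lambda c: (c[1], c[0])):
        bases = set(range(iv[0], iv[1]))
        if not bases & kept_bases:
            kept.append(iv)
            kept_bases |= bases
    return sorted(kept)


def brute_cluster_counts(introns: list, peaks: list) -> list:
    """Per-intron count of strand-matched overlapping peaks.

    introns: (chrom, start, end, strand); peaks likewise.
    """
    out = []
    for ic, istart, iend, istrand in introns:
        n = 0
        for pc, pstart, pend, pstrand in peaks:
            if pc == ic and pstrand == istrand and pstart < iend and pend > istart:
                n += 1
        out.append(n)
    return out


def brute_closest(features: list, peaks: list):
    """Nearest peak edge per feature: (distance, peak index) with ties to
    the smaller peak start; (None, None) when no peak shares the contig.

    features: (chrom, start, end); peaks: (chrom, start, end).
    """
    out = []
    for fc, fs, fe in features:
        best = None
        for j, (pc, ps, pe) in enumerate(peaks):
            if pc != fc:
                continue
            gap = max(ps - fe, fs - pe, 0)
            if best is None or gap < best[0] or (gap == best[0] and ps < peaks[best[1]][1]):
                best = (gap, j)
        out.append(best if best is not None else (None, None))
    return out


def brute_annotate(peak, category_bases: dict, priority: list) -> str:
    """First category in priority order sharing a base with the peak.

    category_bases: category -> set of (chrom, strand, position).
    peak: (chrom, start, end, strand).
    """
    chrom, start, end, strand = peak
    for cat in priority:
        bases = category_bases.get(cat, set())
        if any((chrom, strand, pos) in bases for pos in range(start, end)):
            return cat
    return "intergenic"


# ---------------------------------------------------------------------------
# Statistics oracles


def hypergeom_tail_exact(k: int, N: int, n1: int, n2: int) -> float:
    """P(X >= k) by exact pmf summation with rational arithmetic."""
    if k <= max(0, n1 + n2 - N):
        return 1.0
    hi = min(n1, n2)
    if k > hi:
        return 0.0
    total = Fraction(0)
    denom = math.comb(N, n2)
    for i in range(k, hi + 1):
        total += Fraction(math.comb(n1, i) * math.comb(N - n1, n2 - i), denom)
    return float(total)


def bh_brute(p: list) -> list:
    """padj_i = min_{j >= i}(p_(j) * m / j), by definition, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for rank_pos, i in enumerate(order):
        vals = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        out[i] = min(1.0, min(vals))
    return out


def kruskal_hand(groups: list) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook rank formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    h = 0.0
    pos = 0
    for g in groups:
        rsum = sum(ranks[pos : pos + len(g)])
        h += rsum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def dunn_pair_permutation_p(group_a, group_b, rest: list, n_perm: int, seed: int) -> float:
    """Permutation p-value for the Dunn pairwise statistic.

    Conditional on the pooled ranks over ALL groups, permute group labels
    and compare |mean rank difference| of the focal pair with the
    observed one.  Vectorized over permutations.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([group_a, group_b] + [np.asarray(r) for r in rest])
    ranks = rankdata(pooled)
    na, nb = len(group_a), len(group_b)
    obs = abs(ranks[:na].mean() - ranks[na : na + nb].mean())
    rng = np.random.default_rng(seed)
    n = len(pooled)
    # ranks are fixed; shuffle which ranks belong to the focal groups
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    ra = ranks[idx[:, :na]].mean(axis=1)
    rb = ranks[idx[:, na : na + nb]].mean(axis=1)
    return float(np.mean(np.abs(ra - rb) >= obs - 1e-12))
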