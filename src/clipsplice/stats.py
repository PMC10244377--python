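"""Shared nonparametric tests and multiple-testing adjustment.

Three analysis layers (splicing efficiency vs. cluster count, miR category
expression, AFM stiffness) compare groups of skewed, heteroscedastic
observations.  The omnibus test throughout is the tie-corrected
Kruskal-Wallis test; post-hoc comparisons are Dunn's all-pairs z test
(rank-based, shared pooled variance) or the Games-Howell test
(Welch-type, for unequal variances such as modulus distributions).

All functions accept a mapping ``label -> 1-D array-like`` of finite
observations and return plain dataclasses that serialize cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "KruskalResult",
    "PairwiseResult",
    "kruskal_wallis",
    "dunn_all_pairs",
    "games_howell",
    "bh_adjust",
]

GroupedSample = dict  # label -> array-like of observations


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    df: int
    n_total: int
    group_sizes: dict = field(default_factory=dict)
    group_medians: dict = field(default_factory=dict)
    group_quartiles: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)


@dataclass
class PairwiseResult:
    """One row per unordered pair of group labels."""

    pairs: list  # (label_a, label_b)
    statistic: np.ndarray  # z (Dunn) or t (Games-Howell)
    df: np.ndarray | None
    pvalue: np.ndarray
    padj: np.ndarray | None

    def as_records(self) -> list[dict]:
        rows = []
        for i, (a, b) in enumerate(self.pairs):
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "statistic": float(self.statistic[i]),
                    "df": None if self.df is None else float(self.df[i]),
                    "pvalue": float(self.pvalue[i]),
                    "padj": None if self.padj is None else float(self.padj[i]),
                }
            )
        return rows

    def p_for(self, a, b, adjusted: bool = True) -> float:
        for i, (x, y) in enumerate(self.pairs):
            if {x, y} == {a, b}:
                src = self.padj if (adjusted and self.padj is not None) else self.pvalue
                return float(src[i])
        raise KeyError(f"no pair ({a}, {b})")


def _clean_groups(groups: GroupedSample, min_size: int = 2):
    """Drop groups with fewer than ``min_size`` finite observations."""
    kept, excluded = {}, []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= min_size:
            kept[label] = v
        else:
            excluded.append(label)
    return kept, excluded


def kruskal_wallis(groups: GroupedSample) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value.

    Groups with fewer than 2 observations are excluded (recorded in
    ``excluded``); at least two groups and three total observations are
    required.
    """
    kept, excluded = _clean_groups(groups)
    if len(kept) < 2:
        raise ValueError("kruskal_wallis needs >=2 groups with >=2 observations")
    arrays = list(kept.values())
    n_total = int(sum(a.size for a in arrays))
    if n_total < 3:
        raise ValueError("kruskal_wallis needs >=3 total observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0  # scipy raises on all-identical input
    else:
        h, p = sps.kruskal(*arrays)
    qs = {k: tuple(np.percentile(v, [25, 75])) for k, v in kept.items()}
    return KruskalResult(
        statistic=float(h),
        pvalue=float(p),
        df=len(kept) - 1,
        n_total=n_total,
        group_sizes={k: int(v.size) for k, v in kept.items()},
        group_medians={k: float(np.median(v)) for k, v in kept.items()},
        group_quartiles={k: (float(a), float(b)) for k, (a, b) in qs.items()},
        excluded=excluded,
    )


def dunn_all_pairs(groups: GroupedSample, adjust: str = "bh") -> PairwiseResult:
    """Dunn's all-pairs rank comparison after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt( [N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j) )

    with ranks pooled over all groups and the tie term
    T = sum(t^3 - t) over tied values.  Two-sided normal p-values,
    Benjamini-Hochberg adjusted across all pairs by default
    (``adjust=None`` disables adjustment).
    """
    kept, _ = _clean_groups(groups)
    labels = list(kept.keys())
    if len(labels) < 2:
        raise ValueError("dunn_all_pairs needs >=2 groups")
    pooled = np.concatenate([kept[k] for k in labels])
    n = np.array([kept[k].size for k in labels])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(n)
    mean_ranks = np.array(
        [ranks[s:e].mean() for s, e in zip(np.r_[0, bounds[:-1]], bounds)]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    pairs, zs = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(var_base * (1.0 / n[i] + 1.0 / n[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((labels[i], labels[j]))
            zs.append(z)
    zs = np.asarray(zs)
    p = 2.0 * sps.norm.sf(np.abs(zs))
    padj = bh_adjust(p) if adjust == "bh" else None
    return PairwiseResult(pairs=pairs, statistic=zs, df=None, pvalue=p, padj=padj)


def games_howell(groups: GroupedSample) -> PairwiseResult:
    """Games-Howell all-pairs test for unequal variances and sizes.

    Per pair: Welch standard error, Welch-Satterthwaite df, and a p-value
    from the studentized-range distribution with k groups,
    p = P(q_{k,df} > |t| * sqrt(2)).
    """
    kept, _ = _clean_groups(groups)
    labels = list(kept.keys())
    k = len(labels)
    if k < 2:
        raise ValueError("games_howell needs >=2 groups")
    m = np.array([kept[l].mean() for l in labels])
    v = np.array([kept[l].var(ddof=1) for l in labels])
    n = np.array([kept[l].size for l in labels], dtype=float)
    pairs, ts, dfs, ps = [], [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            se = np.sqrt(se2)
            t = 0.0 if se == 0 else (m[i] - m[j]) / se
            if se2 == 0:
                df = n[i] + n[j] - 2
                p = 1.0
            else:
                df = se2**2 / (
                    (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
                )
                p = float(sps.studentized_range.sf(np.abs(t) * np.sqrt(2.0), k, df))
            pairs.append((labels[i], labels[j]))
            ts.append(t)
            dfs.append(df)
            ps.append(min(1.0, p))
    return PairwiseResult(
        pairs=pairs,
        statistic=np.asarray(ts),
        df=np.asarray(dfs),
        pvalue=np.asarray(ps),
        padj=None,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
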