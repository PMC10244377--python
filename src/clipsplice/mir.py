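"""miRNA expression analysis: normalization, manual fold change, DE
filters, CLIP-peak distance categories, and the miR-target
anticorrelation filter.

Count normalization uses median-of-ratios size factors (rescaled to
geometric mean 1).  The fold change is the study's manual formula

    log2FC = log2[(N_x + 1) / (N_y + 1)]

with N the per-condition mean of normalized counts; the pseudocount
makes it defined for silent features.  baseMean is the mean of
normalized counts over all samples.

Distance categories (precedence top to bottom):

* ``lt2kb``                       - mature miR within 2000 nt of a CLIP peak
* ``gt2kb_noncoding_intron``      - farther, inside an intron of a noncoding gene
* ``gt2kb_protein_coding_intron`` - farther, inside an intron of a protein-coding gene
* ``other``                       - everything else
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as _stats
from .peaks import PeakSet, closest_peak_distance

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "normalize_counts",
    "base_mean",
    "manual_log2fc",
    "mannwhitney_de",
    "de_filter",
    "categorize_mirs",
    "compare_mir_expression",
    "mir_target_filter",
    "MIR_CATEGORIES",
]

MIR_CATEGORIES = [
    "lt2kb",
    "gt2kb_noncoding_intron",
    "gt2kb_protein_coding_intron",
    "other",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each feature nonzero in every sample, the ratio of its count to
    its geometric mean across samples is taken; a sample's factor is the
    median of these ratios.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature with nonzero counts in all samples; filter low-count features first"
        )
    logmat = np.log(mat[all_pos])
    log_geo = logmat.mean(axis=1)
    ratios = np.exp(logmat - log_geo[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def base_mean(norm_counts: pd.DataFrame) -> pd.Series:
    """Mean of normalized counts across ALL samples (both conditions)."""
    return norm_counts.mean(axis=1).rename("baseMean")


def manual_log2fc(
    norm_counts: pd.DataFrame, condition_map: dict, x: str, y: str
) -> pd.Series:
    """log2[(N_x+1)/(N_y+1)] with N the per-condition mean of normalized counts."""
    sx = [s for s, c in condition_map.items() if c == x]
    sy = [s for s, c in condition_map.items() if c == y]
    if not sx or not sy:
        raise ValueError(f"conditions {x!r}/{y!r} need >=1 sample each")
    nx = norm_counts[sx].mean(axis=1)
    ny = norm_counts[sy].mean(axis=1)
    return np.log2((nx + 1.0) / (ny + 1.0)).rename("log2FC")


def mannwhitney_de(
    norm_counts: pd.DataFrame, condition_map: dict, x: str, y: str
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney test between conditions, with
    BH-adjusted p-values, the manual log2FC, and baseMean.

    This is the synthetic pipeline's p-value source; externally computed
    DE tables can be passed to :func:`de_filter` unchanged.
    """
    sx = [s for s, c in condition_map.items() if c == x]
    sy = [s for s, c in condition_map.items() if c == y]
    pvals = np.ones(len(norm_counts))
    for i, (_, row) in enumerate(norm_counts.iterrows()):
        a, b = row[sx].to_numpy(), row[sy].to_numpy()
        if np.ptp(np.r_[a, b]) == 0:
            continue
        pvals[i] = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    out = pd.DataFrame(
        {
            "baseMean": base_mean(norm_counts),
            "log2FC": manual_log2fc(norm_counts, condition_map, x, y),
            "pvalue": pvals,
            "padj": _stats.bh_adjust(pvals),
        },
        index=norm_counts.index,
    )
    return out


def de_filter(
    results: pd.DataFrame,
    kind: str = "mir",
    min_abs_log2fc: float = 1.0,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression filter: |log2FC| >= 1, padj <= 0.05, and
    baseMean >= 5 (miRs) or >= 10 (genes); all bounds inclusive.

    Adds a ``direction`` column (up/down by the sign of log2FC).
    """
    cutoffs = {"mir": 5.0, "gene": 10.0}
    if kind not in cutoffs:
        raise ValueError(f"kind must be 'mir' or 'gene', got {kind!r}")
    mask = (
        (results["log2FC"].abs() >= min_abs_log2fc)
        & (results["padj"] <= max_padj)
        & (results["baseMean"] >= cutoffs[kind])
    )
    out = results[mask].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out


def categorize_mirs(
    mirs: pd.DataFrame,
    peaks: PeakSet,
    intron_context: pd.DataFrame,
    max_distance: int = 2000,
) -> pd.DataFrame:
    """Assign each mature miR a CLIP-distance / intron-context category.

    ``mirs`` needs columns mir_id, chrom, start, end; ``intron_context``
    is the output of :func:`clipsplice.annotation.classify_intron_context`.
    Precedence: lt2kb > intron context > other.  The <2 kb bound is
    inclusive at exactly ``max_distance``.  miRs on contigs absent from
    the intron table fall to "other" with a warning.
    """
    dist = closest_peak_distance(mirs, peaks, max_search=None)
    known_contigs = set(intron_context["chrom"])
    cats, hosts = [], []
    for row in dist.itertuples(index=False):
        host = None
        sub = intron_context[
            (intron_context["chrom"] == row.chrom)
            & (intron_context["start"] < row.end)
            & (intron_context["end"] > row.start)
        ]
        # mature miR must lie within the intron
        sub = sub[(sub["start"] <= row.start) & (row.end <= sub["end"])]
        if not sub.empty:
            host = sub.iloc[0]
        if np.isfinite(row.distance) and row.distance <= max_distance:
            cats.append("lt2kb")
        elif host is not None:
            cats.append(
                "gt2kb_noncoding_intron"
                if host["context"] == "noncoding_intron"
                else "gt2kb_protein_coding_intron"
            )
        else:
            if row.chrom not in known_contigs:
                logger.warning("miR on unannotated contig %s: categorized as other", row.chrom)
            cats.append("other")
        hosts.append(None if host is None else f"{host['gene_id']}|{host['intron_index']}")
    out = dist.copy()
    out["category"] = pd.Categorical(cats, categories=MIR_CATEGORIES)
    out["host_intron"] = hosts
    return out


def compare_mir_expression(
    assignment: pd.DataFrame, norm_counts: pd.DataFrame
) -> dict:
    """Kruskal-Wallis plus BH-adjusted Dunn all-pairs over per-miR
    log2(baseMean) grouped by distance category.

    Categories with <2 members are excluded (reported in the result).
    """
    bm = base_mean(norm_counts)
    merged = assignment.set_index("mir_id").join(bm, how="inner")
    merged["log2_base_mean"] = np.log2(merged["baseMean"] + 1e-9)
    groups = {
        str(cat): sub["log2_base_mean"].to_numpy()
        for cat, sub in merged.groupby("category", observed=True)
    }
    occupied = {k: v for k, v in groups.items() if v.size >= 2}
    excluded = sorted(set(groups) - set(occupied))
    if excluded:
        logger.warning("categories excluded (<2 members): %s", excluded)
    kw = _stats.kruskal_wallis(occupied)
    dunn = _stats.dunn_all_pairs(occupied, adjust="bh")
    return {
        "kruskal": kw,
        "dunn": dunn,
        "group_medians": kw.group_medians,
        "excluded_groups": excluded,
    }


def mir_target_filter(
    mir_fc: pd.DataFrame,
    mrna_fc: pd.DataFrame,
    target_scores: pd.DataFrame,
    min_score: float = 60.0,
) -> pd.DataFrame:
    """Keep miR-target pairs with opposing, nonzero log2FC and a target
    prediction score >= ``min_score`` (inclusive: 60 kept, 59 dropped).

    ``target_scores`` needs columns mir_id, gene_id, score; the two FC
    tables are indexed by feature id with a ``log2FC`` column.
    """
    pairs = target_scores.copy()
    pairs["mir_log2fc"] = pairs["mir_id"].map(mir_fc["log2FC"])
    pairs["gene_log2fc"] = pairs["gene_id"].map(mrna_fc["log2FC"])
    pairs = pairs.dropna(subset=["mir_log2fc", "gene_log2fc"])
    keep = (
        (pairs["score"] >= min_score)
        & (pairs["mir_log2fc"] != 0)
        & (pairs["gene_log2fc"] != 0)
        & (np.sign(pairs["mir_log2fc"]) == -np.sign(pairs["gene_log2fc"]))
    )
    return pairs[keep].reset_index(drop=True)
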