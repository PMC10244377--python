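"""Splicing efficiency from junction-spanning reads, and its relation to
CLIP cluster counts.

Splicing efficiency (SE) of an intron in a sample is the fraction of
junction-spanning reads that are exon-exon:

    SE = ee / (ee + ei)

where ``ee`` counts exon-exon junction reads and ``ei`` counts
exon-intron boundary reads (donor-side and acceptor-side combined).
SE = 1 means fully spliced, 0 fully retained.  At the gene level the
counts are pooled over the gene's unique introns before dividing.
Rows with ee + ei < ``min_reads`` are flagged missing, not set to zero:
the ratio is unstable at low coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "splicing_efficiency",
    "delta_splicing_efficiency",
    "count_clusters_per_feature",
    "group_se_by_cluster_count",
    "compare_se_groups",
    "read_junction_counts",
    "DEFAULT_CLUSTER_BINS",
]

JUNCTION_COLUMNS = ["gene_id", "intron_index", "sample", "ee", "ei"]

#: bin edges over cluster counts: {0}, {1-2}, {3-5}, {>=6}
DEFAULT_CLUSTER_BINS = (0, 1, 3, 6)


def read_junction_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    return df


def _validate_counts(counts: pd.DataFrame) -> None:
    for col in ("ee", "ei"):
        if (counts[col] < 0).any():
            raise ValueError(f"negative {col} counts")


def splicing_efficiency(
    counts: pd.DataFrame, level: str = "intron", min_reads: int = 10
) -> pd.DataFrame:
    """Per-intron (or pooled per-gene) SE per sample.

    Returns a table with columns ``gene_id`` [, ``intron_index``],
    ``sample``, ``ee``, ``ei``, ``coverage``, ``se`` (NaN below
    ``min_reads``) and ``missing``.
    """
    if level not in ("intron", "gene"):
        raise ValueError(f"level must be 'intron' or 'gene', got {level!r}")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    _validate_counts(counts)
    keys = ["gene_id", "sample"] if level == "gene" else ["gene_id", "intron_index", "sample"]
    df = counts.groupby(keys, as_index=False)[["ee", "ei"]].sum()
    df["coverage"] = df["ee"] + df["ei"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["se"] = df["ee"] / df["coverage"]
    df["missing"] = df["coverage"] < min_reads
    df.loc[df["missing"], "se"] = np.nan
    return df


def delta_splicing_efficiency(se_a: pd.DataFrame, se_b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature difference of mean SE: mean over a's samples minus
    mean over b's samples (condition minus reference).

    Features missing (all-NaN) on either side are dropped; the number
    dropped is recorded in ``df.attrs['n_dropped']``.
    """
    keys = [c for c in ("gene_id", "intron_index") if c in se_a.columns and c in se_b.columns]
    if not keys:
        raise ValueError("no shared feature keys")
    ma = se_a.groupby(keys)["se"].mean().rename("se_a")
    mb = se_b.groupby(keys)["se"].mean().rename("se_b")
    joined = pd.concat([ma, mb], axis=1, join="inner")
    if joined.empty:
        raise ValueError("no shared introns between the two tables")
    ok = joined.dropna()
    out = ok.reset_index()
    out["delta_se"] = out["se_a"] - out["se_b"]
    out.attrs["n_dropped"] = int(len(joined) - len(ok))
    return out


def count_clusters_per_feature(intron_set, peaks, level: str = "intron") -> pd.DataFrame:
    """Number of CLIP peaks overlapping (>=1 bp, strand-matched) each
    intron, or each gene's intron union.

    At the gene level a peak spanning several introns of one gene is
    counted once.  Raises when the peak contigs are disjoint from the
    intron contigs (namespace mismatch).
    """
    introns = intron_set.to_frame()
    pdf = peaks.df
    if len(pdf) and len(introns):
        shared = set(introns["chrom"]) & set(pdf["chrom"])
        if not shared:
            raise ValueError(
                "no shared contigs between introns and peaks: "
                f"{sorted(set(introns['chrom']))[:3]} vs {sorted(set(pdf['chrom']))[:3]}"
            )
    if level == "intron":
        counts = np.zeros(len(introns), dtype=int)
        for i, row in enumerate(introns.itertuples(index=False)):
            sub = pdf[(pdf["chrom"] == row.chrom) & (pdf["strand"] == row.strand)]
            if sub.empty:
                continue
            counts[i] = int(
                ((sub["start"] < row.end) & (sub["end"] > row.start)).sum()
            )
        out = introns.copy()
        out["cluster_count"] = counts
        return out
    if level == "gene":
        rows = []
        for (gene, chrom, strand), sub_introns in introns.groupby(["gene_id", "chrom", "strand"]):
            sub = pdf[(pdf["chrom"] == chrom) & (pdf["strand"] == strand)]
            if sub.empty:
                rows.append({"gene_id": gene, "cluster_count": 0})
                continue
            hit = np.zeros(len(sub), dtype=bool)
            for irow in sub_introns.itertuples(index=False):
                hit |= (sub["start"] < irow.end).to_numpy() & (sub["end"] > irow.start).to_numpy()
            rows.append({"gene_id": gene, "cluster_count": int(hit.sum())})
        return pd.DataFrame(rows)
    raise ValueError(f"level must be 'intron' or 'gene', got {level!r}")


def bin_label(count: int, edges=DEFAULT_CLUSTER_BINS) -> str:
    """Human-readable label of the bin containing ``count``."""
    edges = list(edges)
    if any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    for lo, hi in zip(edges, edges[1:] + [None]):
        if hi is None or count < hi:
            if count >= lo:
                if hi is None:
                    return f">={lo}"
                return str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}"
    raise ValueError(f"count {count} below smallest bin edge {edges[0]}")


def group_se_by_cluster_count(
    se: pd.DataFrame,
    cluster_counts: pd.DataFrame,
    bins=DEFAULT_CLUSTER_BINS,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Attach a cluster-count bin to each SE row.

    ``cluster_counts`` is the output of :func:`count_clusters_per_feature`.
    Bins occupied by fewer than ``min_group_size`` features are flagged in
    ``df.attrs['small_bins']`` (not removed).
    """
    keys = [c for c in ("gene_id", "intron_index") if c in se.columns and c in cluster_counts.columns]
    merged = se.merge(cluster_counts[keys + ["cluster_count"]], on=keys, how="inner")
    merged["cluster_bin"] = [bin_label(c, bins) for c in merged["cluster_count"]]
    sizes = merged.groupby("cluster_bin")[keys[0]].nunique()
    merged.attrs["small_bins"] = sorted(sizes[sizes < min_group_size].index)
    merged.attrs["bin_order"] = _bin_order(bins)
    return merged


def _bin_order(bins=DEFAULT_CLUSTER_BINS) -> list:
    edges = list(bins)
    labels = []
    for lo, hi in zip(edges, edges[1:] + [None]):
        if hi is None:
            labels.append(f">={lo}")
        else:
            labels.append(str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}")
    return labels


def compare_se_groups(grouping: pd.DataFrame, group_col: str = "cluster_bin") -> dict:
    """Kruskal-Wallis omnibus plus Dunn all-pairs (BH-adjusted) over SE
    values grouped by ``group_col``.

    SE values are pooled per feature per sample within each group.
    Groups with fewer than 2 observations are excluded with a warning
    recorded in the report.
    """
    groups = {
        str(label): sub["se"].dropna().to_numpy()
        for label, sub in grouping.groupby(group_col)
    }
    occupied = {k: v for k, v in groups.items() if v.size >= 2}
    if len(occupied) < 2:
        raise ValueError("need >=2 occupied groups for comparison")
    kw = _stats.kruskal_wallis(occupied)
    dunn = _stats.dunn_all_pairs(occupied, adjust="bh")
    return {
        "kruskal": kw,
        "dunn": dunn,
        "group_medians": kw.group_medians,
        "group_quartiles": kw.group_quartiles,
        "excluded_groups": sorted(set(groups) - set(occupied)),
    }
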