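"""CLIP peak annotation, feature distances, metaprofiles, motif windows.

Peaks are strand-aware clusters enriched over a size-matched input (SMI)
control, carried as a BED6+2 table (log2 fold change over input and
adjusted p-value as the two extra columns).  Coordinates are 0-based
half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakSet",
    "CoverageTrack",
    "Metaprofile",
    "filter_peaks",
    "annotate_peaks",
    "closest_peak_distance",
    "exon_metaprofile",
    "premir_metaprofile",
    "cassette_exon_map",
    "motif_windows",
    "DEFAULT_CATEGORY_PRIORITY",
]

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "log2fc", "padj"]


@dataclass
class PeakSet:
    """Strand-aware CLIP clusters with enrichment scores (BED6+2)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = {"chrom", "start", "end", "strand"} - set(self.df.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("peaks with start >= end")

    def __len__(self):
        return len(self.df)

    @property
    def centers(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    @classmethod
    def read_bed(cls, path) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS)
        return cls(df)

    def write_bed(self, path) -> None:
        cols = [c for c in PEAK_COLUMNS if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CoverageTrack:
    """Per-contig, per-strand read coverage arrays (reads/bp)."""

    label: str  # "IP" or "SMI"
    data: dict = field(default_factory=dict)  # (contig, strand) -> float ndarray

    def get(self, contig: str, strand: str) -> np.ndarray:
        return self.data[(contig, strand)]

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def write_bedgraph(self, prefix) -> None:
        for strand, suffix in (("+", ".plus"), ("-", ".minus")):
            with open(f"{prefix}{suffix}.bedgraph", "w") as out:
                for (contig, s), arr in sorted(self.data.items()):
                    if s != strand:
                        continue
                    # run-length encode
                    change = np.flatnonzero(np.diff(arr)) + 1
                    starts = np.r_[0, change]
                    ends = np.r_[change, arr.size]
                    for a, b in zip(starts, ends):
                        if arr[a] != 0:
                            out.write(f"{contig}\t{a}\t{b}\t{arr[a]:.6g}\n")


@dataclass
class Metaprofile:
    positions: np.ndarray  # feature-relative bin coordinates (nt or bin index)
    values: np.ndarray  # aggregated signal per bin
    spread: np.ndarray  # SEM (mean aggregation) or MAD (median aggregation)
    n: int
    aggregator: str = "mean"


# ---------------------------------------------------------------------------
# Filtering and annotation

DEFAULT_CATEGORY_PRIORITY = [
    "CDS-exon",
    "5'UTR",
    "3'UTR",
    "noncoding exon",
    "protein-coding intron",
    "noncoding intron",
]


def filter_peaks(peaks: PeakSet, min_log2fc: float = 3.0, max_padj: float = 0.001) -> PeakSet:
    """Keep peaks with log2fc >= min_log2fc and padj <= max_padj (inclusive)."""
    df = peaks.df
    kept = df[(df["log2fc"] >= min_log2fc) & (df["padj"] <= max_padj)].reset_index(drop=True)
    return PeakSet(kept)


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _category_intervals(annotation):
    """(category, chrom, strand) -> merged sorted intervals."""
    buckets: dict = {}

    def add(cat, chrom, strand, s, e):
        if e > s:
            buckets.setdefault((cat, chrom, strand), []).append((s, e))

    for g in annotation.genes:
        union = g.exon_union()
        if g.biotype == "protein_coding":
            for t in g.transcripts:
                if t.cds:
                    cds_lo = min(s for s, _ in t.cds)
                    cds_hi = max(e for _, e in t.cds)
                    for s, e in t.cds:
                        add("CDS-exon", g.chrom, g.strand, s, e)
                    for s, e in t.exons:
                        left = (max(s, 0), min(e, cds_lo))
                        right = (max(s, cds_hi), e)
                        five, three = (left, right) if g.strand == "+" else (right, left)
                        add("5'UTR", g.chrom, g.strand, *five)
                        add("3'UTR", g.chrom, g.strand, *three)
                else:
                    for s, e in t.exons:
                        add("CDS-exon", g.chrom, g.strand, s, e)
            intron_cat = "protein-coding intron"
        else:
            for s, e in union:
                add("noncoding exon", g.chrom, g.strand, s, e)
            intron_cat = "noncoding intron"
        prev = g.start
        for s, e in union:
            add(intron_cat, g.chrom, g.strand, prev, s)
            prev = e
        add(intron_cat, g.chrom, g.strand, prev, g.end)
    return {k: _merge_intervals(v) for k, v in buckets.items()}


def _any_overlap(merged, start, end) -> bool:
    """Any-overlap query against merged, sorted, non-overlapping intervals."""
    if not merged:
        return False
    starts = [iv[0] for iv in merged]
    i = np.searchsorted(starts, end, side="left")
    return i > 0 and merged[i - 1][1] > start


def annotate_peaks(peaks: PeakSet, annotation, priority=None) -> pd.DataFrame:
    """Assign one functional category per peak via a fixed priority order.

    Categories: CDS-exon > 5'UTR > 3'UTR > noncoding exon >
    protein-coding intron > noncoding intron > intergenic (configurable
    via ``priority``).  Overlap is strand-matched, any-overlap (>=1 bp).
    Category fractions are attached as ``df.attrs['fractions']``.
    """
    priority = list(priority or DEFAULT_CATEGORY_PRIORITY)
    cat_ivs = _category_intervals(annotation)
    cats = []
    for row in peaks.df.itertuples(index=False):
        label = "intergenic"
        for cat in priority:
            merged = cat_ivs.get((cat, row.chrom, row.strand))
            if merged and _any_overlap(merged, row.start, row.end):
                label = cat
                break
        cats.append(label)
    out = peaks.df.copy()
    out["category"] = cats
    frac = out["category"].value_counts(normalize=True).to_dict()
    out.attrs["fractions"] = frac
    return out


# ---------------------------------------------------------------------------
# Distances


def closest_peak_distance(
    features: pd.DataFrame,
    peaks: PeakSet,
    max_search: int | None = None,
    strand_matched: bool = False,
) -> pd.DataFrame:
    """Distance (nt) from each feature interval to its nearest peak edge.

    Distance 0 for any overlap; ties broken toward the peak with the
    smaller genomic start.  Features with no peak within ``max_search``
    (when given) get distance NaN and ``within_search=False``.

    ``features`` needs columns chrom, start, end (strand too when
    ``strand_matched``).
    """
    pdf = peaks.df
    dist = np.full(len(features), np.nan)
    nearest = np.full(len(features), None, dtype=object)
    for i, row in enumerate(features.itertuples(index=False)):
        sub = pdf[pdf["chrom"] == row.chrom]
        if strand_matched:
            sub = sub[sub["strand"] == row.strand]
        if sub.empty:
            continue
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        gaps = np.maximum(0, np.maximum(ps - row.end, row.start - pe))
        best = gaps.min()
        tie = np.flatnonzero(gaps == best)
        winner = tie[np.argmin(ps[tie])]
        dist[i] = best
        names = sub["name"].to_numpy() if "name" in sub.columns else sub.index.to_numpy()
        nearest[i] = names[winner]
    out = features.copy()
    out["distance"] = dist
    out["peak"] = nearest
    if max_search is not None:
        within = out["distance"] <= max_search
        out.loc[~within.fillna(False), ["distance", "peak"]] = [np.nan, None]
        out["within_search"] = within.fillna(False)
    return out


# ---------------------------------------------------------------------------
# Metaprofiles


def _oriented(arr: np.ndarray, strand: str) -> np.ndarray:
    return arr if strand == "+" else arr[::-1]


def _resample(values: np.ndarray, n_out: int) -> np.ndarray:
    if values.size == n_out:
        return values.astype(float)
    x_out = np.linspace(0, values.size - 1, n_out)
    return np.interp(x_out, np.arange(values.size), values.astype(float))


def exon_metaprofile(
    coverage_ip: CoverageTrack,
    coverage_smi: CoverageTrack,
    annotation,
    flank: int = 300,
    body_bins: int = 100,
):
    """Exon-anchored coverage profile: 5' intronic flank, rescaled exon
    body, 3' intronic flank, strand-oriented; mean +/- SEM across exons.

    Returns (ip_profile, smi_profile).  Only internal exons are used, so
    both flanks are intronic; terminal exons would mix intergenic
    background into the flanks.
    """
    rows_ip, rows_smi = [], []
    for g in annotation.genes:
        clen = annotation.contigs[g.chrom]
        union = g.exon_union()
        for s, e in union[1:-1]:
            if s - flank < 0 or e + flank > clen:
                continue
            for track, rows in ((coverage_ip, rows_ip), (coverage_smi, rows_smi)):
                arr = track.get(g.chrom, g.strand)
                left = arr[s - flank : s]
                body = _resample(arr[s:e], body_bins)
                right = arr[e : e + flank]
                prof = np.concatenate([left, body, right])
                rows.append(_oriented(prof, g.strand))
    positions = np.r_[np.arange(-flank, 0), np.arange(body_bins), np.arange(body_bins, body_bins + flank)]
    out = []
    for rows in (rows_ip, rows_smi):
        mat = np.asarray(rows, dtype=float)
        n = mat.shape[0]
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
        out.append(Metaprofile(positions=positions, values=mean, spread=sem, n=n))
    return tuple(out)


def premir_metaprofile(
    coverage: CoverageTrack,
    pre_mirs: pd.DataFrame,
    extend: int = 2000,
    scaled_length: int = 5000,
    bin_size: int = 50,
) -> Metaprofile:
    """Coverage around pre-miRNAs: each +/-``extend`` region rescaled to a
    common ``scaled_length`` axis, binned by the within-bin median, and
    averaged across pre-miRs.

    ``pre_mirs`` needs columns chrom, start, end, strand.
    """
    n_bins = scaled_length // bin_size
    rows = []
    for row in pre_mirs.itertuples(index=False):
        clen = coverage.data[(row.chrom, row.strand)].size
        s, e = row.start - extend, row.end + extend
        if s < 0 or e > clen:
            continue
        arr = coverage.get(row.chrom, row.strand)[s:e]
        scaled = _resample(np.asarray(arr, dtype=float), scaled_length)
        scaled = _oriented(scaled, row.strand)
        binned = scaled[: n_bins * bin_size].reshape(n_bins, bin_size)
        rows.append(np.median(binned, axis=1))
    mat = np.asarray(rows, dtype=float)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(n_bins)
    return Metaprofile(
        positions=np.arange(n_bins) * bin_size,
        values=mean,
        spread=sem,
        n=n,
        aggregator="median-binned mean",
    )


def _ratio_window(ip_arr, smi_arr, ip_total, smi_total, start, end):
    """Per-position RPKM(IP)/RPKM(SMI) with a 1-read pseudocount.

    Library-size factors cancel up to the totals ratio, so the ratio is
    (ip+1)/ip_total * smi_total/(smi+1); identical tracks give exactly 1.
    """
    ip = ip_arr[start:end].astype(float)
    smi = smi_arr[start:end].astype(float)
    return ((ip + 1.0) / ip_total) / ((smi + 1.0) / smi_total)


def cassette_exon_map(
    coverage_ip: CoverageTrack,
    coverage_smi: CoverageTrack,
    events: pd.DataFrame,
    min_abs_dpsi: float = 0.2,
    acceptor_intron: int = 250,
    acceptor_exon: int = 50,
    donor_exon: int = 50,
    donor_intron: int = 250,
    bin_size: int = 50,
) -> dict:
    """CLIP signal map around differentially spliced cassette exons.

    Events (columns chrom, strand, exon_start, exon_end, delta_psi,
    direction in {higher_in_OE, lower_in_OE}) are selected at
    |delta_psi| >= ``min_abs_dpsi`` and partitioned by direction.  Two
    windows per event, in transcript orientation: acceptor side (250 nt
    intron + 50 nt exon) and donor side (50 nt exon + 250 nt intron).
    Signal is per-position RPKM(IP)/RPKM(SMI), averaged in 50-bp bins,
    then averaged across events.  Returns
    {direction: (acceptor_profile, donor_profile)}.
    """
    ip_total, smi_total = coverage_ip.total(), coverage_smi.total()
    sel = events[np.abs(events["delta_psi"]) >= min_abs_dpsi]
    out = {}
    for direction, sub in sel.groupby("direction"):
        acc_rows, don_rows = [], []
        for row in sub.itertuples(index=False):
            ip = coverage_ip.get(row.chrom, row.strand)
            smi = coverage_smi.get(row.chrom, row.strand)
            if row.strand == "+":
                acc = (row.exon_start - acceptor_intron, row.exon_start + acceptor_exon)
                don = (row.exon_end - donor_exon, row.exon_end + donor_intron)
            else:
                acc = (row.exon_end - acceptor_exon, row.exon_end + acceptor_intron)
                don = (row.exon_start - donor_intron, row.exon_start + donor_exon)
            clipped = False
            for win, rows_list in ((acc, acc_rows), (don, don_rows)):
                s, e = max(0, win[0]), min(ip.size, win[1])
                if (s, e) != win:
                    clipped = True
                r = _ratio_window(ip, smi, ip_total, smi_total, s, e)
                r = _oriented(r, row.strand)
                n_bins = max(1, r.size // bin_size)
                binned = r[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
                rows_list.append(binned)
            if clipped:
                warnings.warn(f"event at {row.chrom}:{row.exon_start} window clipped to contig")
        profiles = []
        for rows_list in (acc_rows, don_rows):
            width = max(r.size for r in rows_list)
            mat = np.full((len(rows_list), width), np.nan)
            for i, r in enumerate(rows_list):
                mat[i, : r.size] = r
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(mat, axis=0)
                n_per = np.sum(~np.isnan(mat), axis=0)
                sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n_per, 1))
            profiles.append(
                Metaprofile(
                    positions=np.arange(width) * bin_size,
                    values=mean,
                    spread=sem,
                    n=len(rows_list),
                )
            )
        out[direction] = tuple(profiles)
    return out


# ---------------------------------------------------------------------------
# Motif windows

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def motif_windows(peaks: PeakSet, fasta_path, flank: int = 50) -> list:
    """Sequence windows of ``flank`` nt on both sides of each peak center
    (2*flank+1 nt total), reverse-complemented for minus-strand peaks.

    Returns records (name, sequence, clipped: bool); windows at contig
    edges are clipped and flagged.  Write with :func:`write_fasta`.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    records = []
    for idx, row in enumerate(peaks.df.itertuples(index=False)):
        contig = fa[row.chrom]
        center = (row.start + row.end) // 2
        lo, hi = center - flank, center + flank + 1
        clo, chi = max(0, lo), min(len(contig), hi)
        seq = contig[clo:chi].seq.upper()
        if row.strand == "-":
            seq = _revcomp(seq)
        name = getattr(row, "name", None) or f"peak_{idx}"
        records.append((name, seq, (clo, chi) != (lo, hi)))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as out:
        for name, seq, clipped in records:
            flag = " clipped" if clipped else ""
            out.write(f">{name}{flag}\n{seq}\n")
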