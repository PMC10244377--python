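"""Synthetic-data generator for every input the pipeline consumes.

One :class:`SimConfig` (a seed plus the effect sizes below) fully
determines a toy cohort with the qualitative structure the analyses are
designed to detect:

* a one-contig genome annotation with multi-exon protein-coding and
  noncoding genes, some hosting intronic miRs;
* CLIP peak sets biased toward the donor splice site, with extra peaks
  planted within 2 kb of a flagged miR subset;
* junction-spanning read counts whose true splicing efficiency falls
  with the intronic peak count (beta1 < 0) and rises with the
  LIS1-dose scalar of the genotype (beta2 > 0);
* negative-binomial miR counts elevated for peak-proximal miRs;
* IP/SMI coverage tracks with peak-shaped enrichment, and cassette-exon
  event tables with direction-specific planted signal;
* interactome gene lists with an exact planted overlap; and
* grids of Hertzian force curves with group-specific moduli.

Every generator emits a machine-readable truth table, and every output
is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import ForceCurve, ForceCurveSet, hertz_prefactor
from .annotation import Gene, GenomeAnnotation, Transcript, build_unique_intron_set, write_gtf
from .peaks import CoverageTrack, PeakSet

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "make_toy_annotation",
    "simulate_genome_sequence",
    "simulate_peaks",
    "simulate_junction_counts",
    "simulate_mir_counts",
    "simulate_coverage",
    "simulate_lsv_events",
    "simulate_force_curves",
    "simulate_curve_batch",
    "simulate_interactomes",
    "generate_all",
]

# rng stream ids, one per generator, so adding a generator never shifts
# the draws of another
_S_ANNOT, _S_PEAKS, _S_JUNC, _S_MIR, _S_COV, _S_LSV, _S_AFM, _S_OVL, _S_SEQ = range(9)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SimConfig:
    seed: int = 0
    # --- toy genome ---
    n_genes: int = 80
    exons_per_gene: tuple = (2, 8)
    exon_length: tuple = (100, 300)
    intron_length: tuple = (500, 3000)
    intergenic_gap: tuple = (6000, 12000)
    frac_noncoding: float = 0.3
    extra_isoform_frac: float = 0.25
    utr_length: int = 50
    contig: str = "chrS"
    contig_length: int | None = None  # computed when None
    # --- miRs ---
    n_mirs: int = 120
    frac_mirs_near_peaks: float = 0.25
    frac_mirs_pc_intron: float = 0.35
    frac_mirs_nc_intron: float = 0.15
    mature_mir_length: int = 22
    premir_pad: int = 30
    # --- CLIP peaks ---
    peak_rate_per_intron: float = 1.2
    donor_bias_scale: float = 300.0  # nt, truncated-exponential scale
    peak_width: tuple = (30, 80)
    frac_exonic_peaks: float = 0.05  # of significant peaks
    frac_intergenic_peaks: float = 0.08
    subthreshold_frac: float = 0.15  # extra peaks failing the log2fc/padj filter
    mir_guard_nt: int = 2500  # keep random peaks this far from non-flagged miRs
    mir_peak_on_mir_prob: float = 0.5  # flagged-miR peaks placed directly on the miR
    # --- junction counts / SE model ---
    genotypes: dict = field(default_factory=lambda: {"F/-": 0.5, "WT": 1.0, "OE": 2.0})
    n_replicates: int = 4
    reads_per_intron: int = 200
    se_beta0: float = 0.8
    se_beta1: float = -0.05  # per peak-count bin code, negative
    se_beta2: float = 0.05  # per log2(1 + dose), positive
    # --- miR counts ---
    n_mir_samples: int = 6
    mir_base_log_mean: float = 4.0  # natural log of expected count (~55)
    mir_near_peak_effect: float = 1.5  # log-scale shift for the lt2kb class
    mir_noncoding_effect: float = 0.5  # log-scale shift for >2kb noncoding introns
    mir_dispersion: float = 0.3  # NB: var = mu + alpha * mu^2
    # --- coverage ---
    coverage_base: float = 5.0  # mean background reads/bp over gene bodies
    peak_bump_height: float = 3.0  # reads/bp per unit log2fc
    event_bump_height: float = 30.0
    # --- LSV events ---
    n_lsv_events: int = 40
    lsv_dpsi: tuple = (0.25, 0.45)
    lsv_subthreshold_frac: float = 0.2
    # --- interactomes ---
    interactome_n1: int = 100
    interactome_n2: int = 100
    interactome_universe: int = 1000
    interactome_overlap: int = 28
    # --- AFM ---
    afm_groups: dict = field(
        default_factory=lambda: {
            "AGO1-4_KO": 1.0,
            "Dox_AGO2": 3.0,
            "AGO1-4_KO_LIS1_OE": 5.0,
            "Dox_AGO2_LIS1_OE": 6.0,
        }
    )  # label -> true modulus, kPa
    afm_grid: tuple = (12, 12)
    afm_noise_frac: float = 0.05  # multiplicative force noise
    afm_force_floor: float = 10e-12  # additive noise SD, N
    afm_contact_jitter: float = 20e-9  # m
    afm_max_indentation: float = 500e-9  # m
    afm_points_per_curve: int = 400
    afm_precontact: float = 200e-9  # m of baseline before contact
    afm_baseline_offset: float = 5e-11  # N
    nu: float = 0.5
    theta_deg: float = 22.0

    def __post_init__(self):
        for name in (
            "frac_noncoding",
            "frac_mirs_near_peaks",
            "frac_mirs_pc_intron",
            "frac_mirs_nc_intron",
            "frac_exonic_peaks",
            "frac_intergenic_peaks",
            "subthreshold_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_mirs_near_peaks + self.frac_mirs_pc_intron + self.frac_mirs_nc_intron > 1.0:
            raise ValueError("miR category fractions exceed 1")


# ---------------------------------------------------------------------------
# Annotation + miRs


def make_toy_annotation(config: SimConfig):
    """Lay out genes end to end on one toy contig and place miRs.

    Returns (GenomeAnnotation, miR table).  The miR table records the
    planted truth category of each mature miR
    (lt2kb / gt2kb_protein_coding_intron / gt2kb_noncoding_intron /
    other) plus its pre-miR span.
    """
    rng = _rng(config.seed, _S_ANNOT)
    genes = []
    gaps = []  # intergenic (start, end) intervals
    cursor = 5000
    n_noncoding = int(round(config.n_genes * config.frac_noncoding))
    biotypes = ["noncoding"] * n_noncoding + ["protein_coding"] * (config.n_genes - n_noncoding)
    rng.shuffle(biotypes)
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for ei in range(n_ex):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if ei < n_ex - 1:
                pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        gid = f"G{gi:04d}"
        gene = Gene(
            id=gid,
            chrom=config.contig,
            strand=strand,
            start=exons[0][0],
            end=exons[-1][1],
            biotype=biotypes[gi],
        )
        t1 = Transcript(id=f"{gid}.t1", gene_id=gid, exons=list(exons))
        if gene.biotype == "protein_coding":
            u = config.utr_length
            if strand == "+":
                cds_lo, cds_hi = exons[0][0] + u, exons[-1][1] - u
            else:
                cds_lo, cds_hi = exons[0][0] + u, exons[-1][1] - u
            t1.cds = [
                (max(s, cds_lo), min(e, cds_hi))
                for s, e in exons
                if min(e, cds_hi) > max(s, cds_lo)
            ]
        gene.transcripts.append(t1)
        if n_ex >= 3 and rng.random() < config.extra_isoform_frac:
            skip = int(rng.integers(1, n_ex - 1))
            t2_exons = [iv for i, iv in enumerate(exons) if i != skip]
            gene.transcripts.append(Transcript(id=f"{gid}.t2", gene_id=gid, exons=t2_exons))
        genes.append(gene)
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        gaps.append((gene.end, gene.end + gap))
        cursor = gene.end + gap
    contig_length = cursor + 5000
    if config.contig_length is not None:
        if contig_length > config.contig_length:
            raise ValueError(
                f"genes need {contig_length} bp but contig_length is "
                f"{config.contig_length}; increase contig_length"
            )
        contig_length = config.contig_length
    ann = GenomeAnnotation(genes=genes, contigs={config.contig: contig_length})
    ann.validate()
    mirs = _place_mirs(ann, gaps, config, rng)
    return ann, mirs


def _gene_introns(gene: Gene):
    """Exon-union gaps of a gene (where intronic miRs can live)."""
    union = gene.exon_union()
    return [(union[i][1], union[i + 1][0]) for i in range(len(union) - 1)]


def _place_mirs(ann: GenomeAnnotation, gaps, config: SimConfig, rng) -> pd.DataFrame:
    n = config.n_mirs
    n_near = int(round(n * config.frac_mirs_near_peaks))
    n_pc = int(round(n * config.frac_mirs_pc_intron))
    n_nc = int(round(n * config.frac_mirs_nc_intron))
    n_other = n - n_near - n_pc - n_nc

    pc_genes = [g for g in ann.genes if g.biotype == "protein_coding" and _gene_introns(g)]
    nc_genes = [g for g in ann.genes if g.biotype == "noncoding" and _gene_introns(g)]
    rng.shuffle(pc_genes)
    # disjoint host genes for near-peak vs far miRs so guard distances hold
    split = max(1, len(pc_genes) // 2)
    near_hosts, far_hosts = pc_genes[:split], pc_genes[split:]

    def intron_slots(genes_list):
        slots = []
        for g in genes_list:
            for iv in _gene_introns(g):
                if iv[1] - iv[0] >= config.mature_mir_length + 2 * config.premir_pad + 40:
                    slots.append((g, iv))
        rng.shuffle(slots)
        return slots

    rows = []

    def add_intronic(count, slots, category, flag):
        if count > len(slots):
            raise ValueError(
                f"not enough intron slots for {count} {category} miRs; "
                "increase n_genes or intron_length"
            )
        for _ in range(count):
            g, (s, e) = slots.pop()
            lo = s + config.premir_pad + 10
            hi = e - config.premir_pad - 10 - config.mature_mir_length
            start = int(rng.integers(lo, hi + 1))
            rows.append((g.chrom, start, g.strand, g.id, g.biotype, category, flag))

    add_intronic(n_near, intron_slots(near_hosts), "lt2kb", True)
    add_intronic(n_pc, intron_slots(far_hosts), "gt2kb_protein_coding_intron", False)
    add_intronic(n_nc, intron_slots(nc_genes), "gt2kb_noncoding_intron", False)

    wide_gaps = [g for g in gaps if g[1] - g[0] >= 2 * config.mir_guard_nt + 200]
    rng.shuffle(wide_gaps)
    if n_other > len(wide_gaps):
        raise ValueError("not enough intergenic gaps for 'other' miRs; increase n_genes")
    for i in range(n_other):
        s, e = wide_gaps[i]
        lo = s + config.mir_guard_nt
        hi = e - config.mir_guard_nt - config.mature_mir_length
        start = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((config.contig, start, strand, None, None, "other", False))

    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "strand", "host_gene", "host_biotype", "truth_category", "near_peak_flag"],
    )
    df["end"] = df["start"] + config.mature_mir_length
    df["premir_start"] = df["start"] - config.premir_pad
    df["premir_end"] = df["end"] + config.premir_pad
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(0, "mir_id", [f"miR-{i:04d}" for i in range(len(df))])
    return df[
        [
            "mir_id", "chrom", "start", "end", "strand", "host_gene", "host_biotype",
            "truth_category", "near_peak_flag", "premir_start", "premir_end",
        ]
    ]


def simulate_genome_sequence(annotation: GenomeAnnotation, config: SimConfig) -> dict:
    """Random nucleotide sequence per contig (for motif-window extraction)."""
    rng = _rng(config.seed, _S_SEQ)
    seqs = {}
    for contig, length in annotation.contigs.items():
        seqs[contig] = "".join(rng.choice(list("ACGT"), size=length))
    return seqs


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Peaks


def _too_close_to_guarded_mir(start, end, guarded, guard):
    for ms, me in guarded:
        if start < me + guard and ms - guard < end:
            return True
    return False


def simulate_peaks(
    annotation: GenomeAnnotation,
    config: SimConfig,
    mirs: pd.DataFrame | None = None,
    intron_set=None,
) -> PeakSet:
    """CLIP peaks: per-intron Poisson counts with donor-biased positions,
    guaranteed peaks near flagged miRs, plus exonic / intergenic /
    sub-threshold peaks.

    Peak-to-donor distance is a truncated exponential
    (scale ``donor_bias_scale``), so the median donor distance is well
    below the median acceptor distance.  Random peaks are kept
    ``mir_guard_nt`` away from non-flagged miRs so the planted distance
    categories stay true.
    """
    rng = _rng(config.seed, _S_PEAKS)
    if intron_set is None:
        intron_set = build_unique_intron_set(annotation)
    guarded = []
    if mirs is not None:
        guarded = [
            (r.start, r.end)
            for r in mirs.itertuples(index=False)
            if not r.near_peak_flag
        ]
    rows = []  # chrom, start, end, strand, significant, kind

    def draw_width():
        return int(rng.integers(config.peak_width[0], config.peak_width[1] + 1))

    # intronic peaks, donor-biased
    for intron in intron_set:
        c = rng.poisson(config.peak_rate_per_intron)
        for _ in range(c):
            w = draw_width()
            ilen = intron.end - intron.start
            if ilen <= w + 2:
                continue
            for _attempt in range(6):
                d = rng.exponential(config.donor_bias_scale)
                d = min(d, ilen - w - 1)
                if intron.strand == "+":
                    s = intron.start + int(d)
                else:
                    s = intron.end - int(d) - w
                if not _too_close_to_guarded_mir(s, s + w, guarded, config.mir_guard_nt):
                    rows.append((intron.chrom, s, s + w, intron.strand, True, "intronic"))
                    break

    # peaks next to flagged miRs (within 2 kb; half directly on the miR)
    if mirs is not None:
        for r in mirs[mirs["near_peak_flag"]].itertuples(index=False):
            w = draw_width()
            if rng.random() < config.mir_peak_on_mir_prob:
                s = r.start - int(rng.integers(0, max(1, w // 2)))
            else:
                offset = int(rng.integers(100, 1500))
                s = r.end + offset if rng.random() < 0.5 else r.start - offset - w
            rows.append((r.chrom, s, s + w, r.strand, True, "mir_proximal"))

    n_intronic = sum(1 for r in rows if r[5] == "intronic")
    frac_int = 1.0 - config.frac_exonic_peaks - config.frac_intergenic_peaks
    n_exonic = int(round(n_intronic * config.frac_exonic_peaks / frac_int))
    n_intergenic = int(round(n_intronic * config.frac_intergenic_peaks / frac_int))

    all_exons = [
        (g.chrom, s, e, g.strand) for g in annotation.genes for s, e in g.exon_union()
    ]
    for _ in range(n_exonic):
        for _attempt in range(20):
            chrom, s, e, strand = all_exons[int(rng.integers(len(all_exons)))]
            w = min(draw_width(), e - s - 2)
            start = int(rng.integers(s, e - w))
            if not _too_close_to_guarded_mir(start, start + w, guarded, config.mir_guard_nt):
                rows.append((chrom, start, start + w, strand, True, "exonic"))
                break

    spans = sorted((g.start, g.end) for g in annotation.genes)
    clen = annotation.contigs[config.contig]
    for _ in range(n_intergenic):
        for _attempt in range(20):
            w = draw_width()
            s = int(rng.integers(0, clen - w))
            in_gene = any(a - 500 < s + w and s < b + 500 for a, b in spans)
            if not in_gene and not _too_close_to_guarded_mir(s, s + w, guarded, config.mir_guard_nt):
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((config.contig, s, s + w, strand, True, "intergenic"))
                break

    n_sig = len(rows)
    n_sub = int(round(n_sig * config.subthreshold_frac))
    for _ in range(n_sub):
        w = draw_width()
        s = int(rng.integers(0, clen - w))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((config.contig, s, s + w, strand, False, "subthreshold"))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "planted_significant", "planted_kind"])
    df["start"] = df["start"].clip(lower=0)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    df.insert(3, "name", [f"peak_{i:05d}" for i in range(len(df))])
    df.insert(4, "score", 0)
    sig = df["planted_significant"].to_numpy()
    log2fc = np.where(sig, 3.0 + rng.exponential(1.0, len(df)), rng.uniform(0.5, 2.9, len(df)))
    padj = np.where(sig, 10.0 ** -rng.uniform(4, 8, len(df)), 10.0 ** -rng.uniform(0.0, 2.5, len(df)))
    df["log2fc"] = np.round(log2fc, 4)
    df["padj"] = padj
    return PeakSet(df)


# ---------------------------------------------------------------------------
# Junction counts

_BIN_EDGES = (0, 1, 3, 6)


def _bin_code(count: int) -> int:
    """Monotone bin code g(c): {0} -> 0, {1-2} -> 1, {3-5} -> 2, {>=6} -> 3."""
    for code, (lo, hi) in enumerate(((0, 1), (1, 3), (3, 6))):
        if lo <= count < hi:
            return code
    return 3


def simulate_junction_counts(
    annotation: GenomeAnnotation,
    peaks: PeakSet,
    config: SimConfig,
    intron_set=None,
):
    """Binomial junction-spanning read counts per intron, sample.

    True SE of intron i in a sample with dose d is
    clip(beta0 + beta1 * g(c_i) + beta2 * log2(1 + d), 0.01, 0.99)
    with c_i the planted count of significant peaks overlapping the
    intron.  Returns (counts, sample_map, truth).
    """
    rng = _rng(config.seed, _S_JUNC)
    if intron_set is None:
        intron_set = build_unique_intron_set(annotation)
    pdf = peaks.df[peaks.df["planted_significant"]] if "planted_significant" in peaks.df.columns else peaks.df
    sample_map = {}
    counts_rows = []
    truth_rows = []
    for intron in intron_set:
        c = 0
        for p in pdf.itertuples(index=False):
            if p.chrom == intron.chrom and p.strand == intron.strand and p.start < intron.end and p.end > intron.start:
                c += 1
        code = _bin_code(c)
        for genotype, dose in config.genotypes.items():
            true_se = float(
                np.clip(
                    config.se_beta0 + config.se_beta1 * code + config.se_beta2 * np.log2(1.0 + dose),
                    0.01,
                    0.99,
                )
            )
            truth_rows.append(
                {
                    "gene_id": intron.gene_id,
                    "intron_index": intron.ordinal,
                    "genotype": genotype,
                    "cluster_count": c,
                    "bin_code": code,
                    "true_se": true_se,
                }
            )
            for rep in range(1, config.n_replicates + 1):
                sample = f"{genotype}_rep{rep}"
                sample_map[sample] = genotype
                ee = int(rng.binomial(config.reads_per_intron, true_se))
                counts_rows.append(
                    {
                        "gene_id": intron.gene_id,
                        "intron_index": intron.ordinal,
                        "sample": sample,
                        "ee": ee,
                        "ei": config.reads_per_intron - ee,
                    }
                )
    counts = pd.DataFrame(counts_rows)
    truth = pd.DataFrame(truth_rows)
    return counts, sample_map, truth


# ---------------------------------------------------------------------------
# miR counts


def _negbin(rng, mean, alpha, size):
    """NB draws with variance mu + alpha*mu^2 (alpha -> 0 is Poisson)."""
    if alpha <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_mir_counts(mirs: pd.DataFrame, config: SimConfig):
    """Negative-binomial miR count matrix with category-dependent means.

    mu = exp(base + near_peak_effect * 1[lt2kb]
                  + noncoding_effect * 1[gt2kb_noncoding_intron]).
    Returns (counts DataFrame indexed by mir_id, truth Series of
    categories).
    """
    rng = _rng(config.seed, _S_MIR)
    effect = {
        "lt2kb": config.mir_near_peak_effect,
        "gt2kb_noncoding_intron": config.mir_noncoding_effect,
        "gt2kb_protein_coding_intron": 0.0,
        "other": 0.0,
    }
    samples = [f"smallRNA_s{i + 1}" for i in range(config.n_mir_samples)]
    mat = np.zeros((len(mirs), len(samples)), dtype=int)
    for i, cat in enumerate(mirs["truth_category"]):
        mu = float(np.exp(config.mir_base_log_mean + effect[cat]))
        mat[i] = _negbin(rng, mu, config.mir_dispersion, len(samples))
    counts = pd.DataFrame(mat, index=mirs["mir_id"], columns=samples)
    truth = pd.Series(mirs["truth_category"].to_numpy(), index=mirs["mir_id"], name="truth_category")
    return counts, truth


# ---------------------------------------------------------------------------
# Coverage and LSV events


def simulate_lsv_events(annotation: GenomeAnnotation, config: SimConfig) -> pd.DataFrame:
    """Cassette-exon event table with planted directions.

    Internal exons of distinct protein-coding genes; half higher_in_OE,
    half lower_in_OE, plus a sub-threshold fraction with |dPSI| = 0.1.
    """
    rng = _rng(config.seed, _S_LSV)
    candidates = []
    for g in annotation.genes:
        if g.biotype != "protein_coding":
            continue
        union = g.exon_union()
        if len(union) < 3:
            continue
        k = int(rng.integers(1, len(union) - 1))
        candidates.append((g, union[k]))
    rng.shuffle(candidates)
    candidates = candidates[: config.n_lsv_events]
    rows = []
    for i, (g, (s, e)) in enumerate(candidates):
        direction = "higher_in_OE" if i % 2 == 0 else "lower_in_OE"
        if rng.random() < config.lsv_subthreshold_frac:
            mag = 0.1
        else:
            mag = float(rng.uniform(*config.lsv_dpsi))
        dpsi = mag if direction == "higher_in_OE" else -mag
        rows.append(
            {
                "chrom": g.chrom,
                "strand": g.strand,
                "exon_start": s,
                "exon_end": e,
                "gene_id": g.id,
                "delta_psi": round(dpsi, 3),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def simulate_coverage(
    annotation: GenomeAnnotation,
    peaks: PeakSet,
    config: SimConfig,
    events: pd.DataFrame | None = None,
):
    """IP and SMI coverage tracks.

    SMI is flat Poisson background over gene bodies; IP adds a Gaussian
    bump per significant peak (height proportional to its log2fc) and,
    when ``events`` is given, direction-specific bumps: exon-body
    enrichment for higher_in_OE events, intron-acceptor enrichment for
    lower_in_OE events.
    """
    rng = _rng(config.seed, _S_COV)
    tracks = {}
    for label in ("IP", "SMI"):
        data = {}
        for contig, length in annotation.contigs.items():
            for strand in "+-":
                data[(contig, strand)] = np.zeros(length)
        tracks[label] = CoverageTrack(label=label, data=data)
    for g in annotation.genes:
        lam = config.coverage_base
        for label in ("IP", "SMI"):
            arr = tracks[label].data[(g.chrom, g.strand)]
            arr[g.start : g.end] += rng.poisson(lam, g.end - g.start)
    pdf = peaks.df
    if "planted_significant" in pdf.columns:
        pdf = pdf[pdf["planted_significant"]]
    for p in pdf.itertuples(index=False):
        arr = tracks["IP"].data[(p.chrom, p.strand)]
        center = (p.start + p.end) // 2
        sigma = max(10.0, (p.end - p.start) / 2.0)
        lo = max(0, int(center - 4 * sigma))
        hi = min(arr.size, int(center + 4 * sigma))
        x = np.arange(lo, hi)
        arr[lo:hi] += config.peak_bump_height * p.log2fc * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if events is not None:
        for ev in events.itertuples(index=False):
            if abs(ev.delta_psi) < 0.2:
                continue
            arr = tracks["IP"].data[(ev.chrom, ev.strand)]
            if ev.direction == "higher_in_OE":
                lo, hi = ev.exon_start, ev.exon_end
            else:  # intronic, acceptor side
                if ev.strand == "+":
                    lo, hi = ev.exon_start - 250, ev.exon_start - 50
                else:
                    lo, hi = ev.exon_end + 50, ev.exon_end + 250
            lo, hi = max(0, lo), min(arr.size, hi)
            arr[lo:hi] += config.event_bump_height
    return tracks["IP"], tracks["SMI"]


# ---------------------------------------------------------------------------
# AFM


def _make_curve(
    rng, config: SimConfig, e_kpa: float, pixel, height_m: float = 0.0, dome_max_m: float = 0.0
) -> ForceCurve:
    # one shared ramp length per scan: taller pixels contact later along
    # the ramp is wrong physics -- the tip travels *less* before contact,
    # so contact z is (dome_max - height) into the ramp
    pref = hertz_prefactor(config.nu, config.theta_deg)
    jitter = rng.uniform(-config.afm_contact_jitter, config.afm_contact_jitter)
    z_contact = config.afm_precontact + (dome_max_m - height_m) + jitter
    z_max = config.afm_precontact + dome_max_m + config.afm_contact_jitter + config.afm_max_indentation
    z = np.linspace(0.0, z_max, config.afm_points_per_curve)
    delta = np.clip(z - z_contact, 0.0, None)
    f_true = pref * (e_kpa * 1e3) * delta**2
    mult = 1.0 + config.afm_noise_frac * rng.standard_normal(z.size)
    f = config.afm_baseline_offset + f_true * mult + config.afm_force_floor * rng.standard_normal(z.size)
    return ForceCurve(z=z, force=f, pixel=pixel)


def simulate_force_curves(config: SimConfig) -> dict:
    """Per-group grids of force curves over a dome-shaped colony.

    The colony height profile is a Gaussian dome (max 400 nm) centered
    on the grid; the true modulus is uniform within a group.  Returns
    {group: ForceCurveSet} with the truth (modulus, dome height) stored
    on each set.
    """
    rng = _rng(config.seed, _S_AFM)
    nrow, ncol = config.afm_grid
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    r2 = (rr - (nrow - 1) / 2.0) ** 2 + (cc - (ncol - 1) / 2.0) ** 2
    dome = 400e-9 * np.exp(-r2 / (2.0 * (max(nrow, ncol) / 4.0) ** 2))
    out = {}
    for group, e_kpa in config.afm_groups.items():
        curves = [
            _make_curve(rng, config, e_kpa, (r, c), height_m=float(dome[r, c]), dome_max_m=400e-9)
            for r in range(nrow)
            for c in range(ncol)
        ]
        out[group] = ForceCurveSet(
            curves=curves,
            group=group,
            grid_shape=(nrow, ncol),
            truth={"modulus_kpa": e_kpa, "dome_max_m": 400e-9},
        )
    return out


def simulate_curve_batch(
    e_kpa: float, n_curves: int, config: SimConfig | None = None, seed: int | None = None
) -> list:
    """Flat batch of curves at one modulus (for recovery experiments)."""
    config = config or SimConfig()
    rng = _rng(config.seed if seed is None else seed, _S_AFM)
    return [_make_curve(rng, config, e_kpa, (0, i)) for i in range(n_curves)]


# ---------------------------------------------------------------------------
# Interactomes


def simulate_interactomes(config: SimConfig):
    """Two gene lists with an exact planted overlap k inside a universe."""
    rng = _rng(config.seed, _S_OVL)
    N = config.interactome_universe
    n1, n2, k = config.interactome_n1, config.interactome_n2, config.interactome_overlap
    if k > min(n1, n2) or n1 + n2 - k > N:
        raise ValueError("infeasible overlap configuration")
    universe = [f"P{i:05d}" for i in range(N)]
    perm = rng.permutation(N)
    shared = perm[:k]
    a_only = perm[k : k + n1 - k]
    b_only = perm[k + n1 - k : k + n1 - k + n2 - k]
    list_a = sorted(universe[i] for i in np.r_[shared, a_only])
    list_b = sorted(universe[i] for i in np.r_[shared, b_only])
    return list_a, list_b, universe, k


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SyntheticDataset:
    config: SimConfig
    annotation: GenomeAnnotation
    mirs: pd.DataFrame
    intron_set: object
    peaks: PeakSet
    junction_counts: pd.DataFrame
    sample_map: dict
    junction_truth: pd.DataFrame
    mir_counts: pd.DataFrame
    mir_truth: pd.Series
    coverage_ip: CoverageTrack
    coverage_smi: CoverageTrack
    lsv_events: pd.DataFrame
    force_curves: dict
    interactome: tuple  # (list_a, list_b, universe, k)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.annotation, outdir / "annotation.gtf")
        self.mirs.to_csv(outdir / "mirs.tsv", sep="\t", index=False)
        self.intron_set.write_bed(outdir / "introns.bed")
        self.intron_set.write_tsv(outdir / "introns.tsv")
        self.peaks.write_bed(outdir / "peaks.bed")
        self.junction_counts.to_csv(outdir / "junction_counts.tsv", sep="\t", index=False)
        pd.Series(self.sample_map, name="genotype").rename_axis("sample").to_csv(
            outdir / "sample_map.tsv", sep="\t"
        )
        self.junction_truth.to_csv(outdir / "junction_truth.tsv", sep="\t", index=False)
        self.mir_counts.to_csv(outdir / "mir_counts.tsv", sep="\t")
        self.lsv_events.to_csv(outdir / "lsv_events.tsv", sep="\t", index=False)
        self.coverage_ip.write_bedgraph(outdir / "coverage_ip")
        self.coverage_smi.write_bedgraph(outdir / "coverage_smi")
        for group, fcs in self.force_curves.items():
            fcs.write_tsv(outdir / f"afm_{group}.tsv")
        a, b, universe, k = self.interactome
        for name, lst in (("interactome_a", a), ("interactome_b", b), ("universe", universe)):
            (outdir / f"{name}.txt").write_text("\n".join(lst) + "\n")
        truth = {
            "seed": self.config.seed,
            "interactome_overlap": k,
            "afm_moduli_kpa": dict(self.config.afm_groups),
            "mir_categories": self.mirs["truth_category"].value_counts().to_dict(),
            "se_model": {
                "beta0": self.config.se_beta0,
                "beta1": self.config.se_beta1,
                "beta2": self.config.se_beta2,
            },
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def generate_all(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic cohort in memory."""
    config = config or SimConfig()
    annotation, mirs = make_toy_annotation(config)
    intron_set = build_unique_intron_set(annotation)
    peaks = simulate_peaks(annotation, config, mirs=mirs, intron_set=intron_set)
    counts, sample_map, truth = simulate_junction_counts(annotation, peaks, config, intron_set)
    mir_counts, mir_truth = simulate_mir_counts(mirs, config)
    events = simulate_lsv_events(annotation, config)
    cov_ip, cov_smi = simulate_coverage(annotation, peaks, config, events=events)
    force = simulate_force_curves(config)
    interactome = simulate_interactomes(config)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        mirs=mirs,
        intron_set=intron_set,
        peaks=peaks,
        junction_counts=counts,
        sample_map=sample_map,
        junction_truth=truth,
        mir_counts=mir_counts,
        mir_truth=mir_truth,
        coverage_ip=cov_ip,
        coverage_smi=cov_smi,
        lsv_events=events,
        force_curves=force,
        interactome=interactome,
    )
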