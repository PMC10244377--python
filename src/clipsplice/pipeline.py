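"""End-to-end orchestration: simulate -> intron set -> splicing
efficiency -> peak landscape -> miR categories -> overlap -> AFM.

A :class:`RunConfig` (YAML-loadable) fixes the seed and all analysis
thresholds; :func:`run_pipeline` executes the stages, writes per-stage
TSV/JSON outputs plus a ``summary.json``, and is deterministic: the same
config and seed produce a byte-identical summary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import afm as _afm
from . import mir as _mir
from . import overlap as _overlap
from . import peaks as _peaks
from . import simulate as _sim
from . import splicing as _splicing
from .annotation import classify_intron_context

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "splicing", "peaks", "mir", "overlap", "afm")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple = DEFAULT_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # thresholds (defaults mirror the study's printed cutoffs)
    peak_min_log2fc: float = 3.0
    peak_max_padj: float = 0.001
    min_reads: int = 10
    cluster_bins: tuple = _splicing.DEFAULT_CLUSTER_BINS
    mir_max_distance: int = 2000
    min_abs_dpsi: float = 0.2
    delta_range_nm: tuple = (150.0, 500.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        for key in ("stages", "cluster_bins", "delta_range_nm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the summary dict.

    Stage outputs land under ``outdir``; failures raise
    :class:`PipelineStageError` naming the stage (partial outputs are
    retained).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("clipsplice")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "thresholds": _round_floats(_threshold_dict(config))}
    logger.info("run config: %s", asdict(config))
    logger.info("python %s, numpy %s, pandas %s", sys.version.split()[0], np.__version__, pd.__version__)

    unknown = [s for s in config.stages if s not in DEFAULT_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    state: dict = {}
    try:
        for stage in config.stages:
            logger.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](config, state, summary, outdir)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(stage, exc) from exc
            logger.info("stage %s: done", stage)
        (outdir / "summary.json").write_text(
            json.dumps(_round_floats(summary), indent=2, sort_keys=True) + "\n"
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


def _threshold_dict(config: RunConfig) -> dict:
    return {
        "peak_min_log2fc": config.peak_min_log2fc,
        "peak_max_padj": config.peak_max_padj,
        "min_reads": config.min_reads,
        "cluster_bins": list(config.cluster_bins),
        "mir_max_distance": config.mir_max_distance,
        "min_abs_dpsi": config.min_abs_dpsi,
        "delta_range_nm": list(config.delta_range_nm),
    }


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config, state, summary, outdir):
    sim_config = _sim.SimConfig(seed=config.seed, **config.sim)
    ds = _sim.generate_all(sim_config)
    ds.write(outdir / "data")
    state["ds"] = ds
    state["filtered_peaks"] = _peaks.filter_peaks(
        ds.peaks, config.peak_min_log2fc, config.peak_max_padj
    )
    summary["simulate"] = {
        "n_genes": len(ds.annotation.genes),
        "n_introns": len(ds.intron_set),
        "n_peaks_total": len(ds.peaks),
        "n_peaks_significant": len(state["filtered_peaks"]),
        "n_mirs": len(ds.mirs),
    }


def _require(state, key, producer):
    if key not in state:
        raise RuntimeError(f"stage requires {producer!r} output; enable that stage first")
    return state[key]


def _stage_splicing(config, state, summary, outdir):
    ds = _require(state, "ds", "simulate")
    fpeaks = state["filtered_peaks"]
    se = _splicing.splicing_efficiency(ds.junction_counts, level="intron", min_reads=config.min_reads)
    se.to_csv(outdir / "splicing_efficiency.tsv", sep="\t", index=False)
    cc = _splicing.count_clusters_per_feature(ds.intron_set, fpeaks, level="intron")
    grouping = _splicing.group_se_by_cluster_count(se, cc, bins=config.cluster_bins)
    grouping["genotype"] = grouping["sample"].map(ds.sample_map)

    bin_order = grouping.attrs["bin_order"]
    occupied = [b for b in bin_order if b in set(grouping["cluster_bin"])]
    med_by_bin = {
        b: float(grouping.loc[grouping["cluster_bin"] == b, "se"].median()) for b in occupied
    }
    rho = sps.spearmanr(
        [bin_order.index(b) for b in occupied], [med_by_bin[b] for b in occupied]
    ).statistic
    report = _splicing.compare_se_groups(grouping)
    genotype_medians = {
        b: {
            g: float(sub.loc[sub["cluster_bin"] == b, "se"].median())
            for g, sub in grouping.groupby("genotype")
        }
        for b in occupied
    }
    genotypes = list(ds.config.genotypes)
    hi, lo = genotypes[-1], genotypes[0]  # highest vs lowest dose by config order
    se_by_geno = {
        g: se[se["sample"].isin([s for s, gg in ds.sample_map.items() if gg == g])]
        for g in (hi, lo)
    }
    dse = _splicing.delta_splicing_efficiency(se_by_geno[hi], se_by_geno[lo])
    dse.to_csv(outdir / "delta_se.tsv", sep="\t", index=False)
    summary["splicing"] = {
        "n_se_rows": int(len(se)),
        "median_se_by_bin": med_by_bin,
        "median_se_by_bin_genotype": genotype_medians,
        "spearman_bin_vs_median_se": float(rho),
        "kruskal_p_bins": report["kruskal"].pvalue,
        "dunn_pairs": report["dunn"].as_records(),
        "delta_se_contrast": f"{hi} - {lo}",
        "median_delta_se": float(dse["delta_se"].median()),
    }


def _stage_peaks(config, state, summary, outdir):
    ds = _require(state, "ds", "simulate")
    fpeaks = state["filtered_peaks"]
    annotated = _peaks.annotate_peaks(fpeaks, ds.annotation)
    annotated.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
    fractions = annotated.attrs["fractions"]
    intronic = fractions.get("protein-coding intron", 0.0) + fractions.get("noncoding intron", 0.0)

    ip_prof, smi_prof = _peaks.exon_metaprofile(ds.coverage_ip, ds.coverage_smi, ds.annotation)
    premir_cols = ds.mirs.rename(columns={"premir_start": "start", "premir_end": "end"})
    pre = _peaks.premir_metaprofile(
        ds.coverage_ip, premir_cols[["chrom", "start", "end", "strand"]]
    )
    flagged = premir_cols[premir_cols["near_peak_flag"]]
    pre_flagged = _peaks.premir_metaprofile(
        ds.coverage_ip, flagged[["chrom", "start", "end", "strand"]]
    )
    def central_ratio(prof):
        n5 = len(prof.values) // 5
        flanks = np.r_[prof.values[:n5], prof.values[-n5:]]
        return float(np.mean(prof.values[2 * n5 : 3 * n5]) / max(np.mean(flanks), 1e-9))
    cmap = _peaks.cassette_exon_map(
        ds.coverage_ip, ds.coverage_smi, ds.lsv_events, min_abs_dpsi=config.min_abs_dpsi
    )
    seqs = _sim.simulate_genome_sequence(ds.annotation, ds.config)
    fasta = outdir / "data" / "genome.fa"
    _sim.write_fasta(seqs, fasta)
    windows = _peaks.motif_windows(fpeaks, fasta)
    _peaks.write_fasta(windows, outdir / "motif_windows.fa")

    profile_rows = []
    for label, prof in (("exon_IP", ip_prof), ("exon_SMI", smi_prof), ("premir_IP", pre)):
        for pos, val, spread in zip(prof.positions, prof.values, prof.spread):
            profile_rows.append((label, int(pos), float(val), float(spread)))
    for direction, (acc, don) in cmap.items():
        for side, prof in (("acceptor", acc), ("donor", don)):
            for pos, val, spread in zip(prof.positions, prof.values, prof.spread):
                profile_rows.append((f"cassette_{direction}_{side}", int(pos), float(val), float(spread)))
    pd.DataFrame(profile_rows, columns=["profile", "position", "value", "spread"]).to_csv(
        outdir / "metaprofiles.tsv", sep="\t", index=False
    )
    summary["peaks"] = {
        "category_fractions": {k: float(v) for k, v in sorted(fractions.items())},
        "intronic_fraction": float(intronic),
        "exon_profile_argmax_position": int(ip_prof.positions[int(np.argmax(ip_prof.values))]),
        "premir_central_enrichment_all": central_ratio(pre),
        "premir_central_enrichment_flagged": central_ratio(pre_flagged),
        "n_motif_windows": len(windows),
        "n_cassette_events_used": {k: int(v[0].n) for k, v in cmap.items()},
    }


def _stage_mir(config, state, summary, outdir):
    ds = _require(state, "ds", "simulate")
    fpeaks = state["filtered_peaks"]
    factors = _mir.size_factors(ds.mir_counts)
    norm = _mir.normalize_counts(ds.mir_counts, factors)
    context = classify_intron_context(ds.intron_set, ds.annotation)
    assignment = _mir.categorize_mirs(
        ds.mirs, fpeaks, context, max_distance=config.mir_max_distance
    )
    assignment.to_csv(outdir / "mir_categories.tsv", sep="\t", index=False)
    report = _mir.compare_mir_expression(assignment, norm)
    truth_match = float(
        (assignment.set_index("mir_id")["category"].astype(str)
         == ds.mirs.set_index("mir_id")["truth_category"]).mean()
    )
    summary["mir"] = {
        "size_factors": {k: float(v) for k, v in factors.items()},
        "category_counts": assignment["category"].value_counts().to_dict(),
        "truth_agreement": truth_match,
        "kruskal_p": report["kruskal"].pvalue,
        "category_median_log2_base_mean": report["group_medians"],
        "dunn_pairs": report["dunn"].as_records(),
    }


def _stage_overlap(config, state, summary, outdir):
    ds = _require(state, "ds", "simulate")
    a, b, universe, k = ds.interactome
    res = _overlap.hypergeometric_overlap(a, b, universe)
    (outdir / "overlap.json").write_text(json.dumps(_round_floats(res.as_dict()), indent=2, sort_keys=True))
    summary["overlap"] = res.as_dict()


def _stage_afm(config, state, summary, outdir):
    ds = _require(state, "ds", "simulate")
    lo_nm, hi_nm = config.delta_range_nm
    delta_range = (lo_nm * 1e-9, hi_nm * 1e-9)
    group_values = {}
    maps = {}
    for group, fcs in ds.force_curves.items():
        mm = _afm.build_modulus_map(fcs, delta_range=delta_range)
        maps[group] = mm
        # erosion can empty the center mask on small scan grids; back off
        for margin in (2, 1, 0):
            vals = _afm.colony_center_values(mm, erode_margin=margin)
            if len(vals) >= 3:
                break
            logger.warning("group %s: center mask too small at margin %d", group, margin)
        group_values[group] = vals
        pd.DataFrame(mm.modulus_kpa).to_csv(outdir / f"modulus_map_{group}.tsv", sep="\t", index=False)
    report = _afm.compare_stiffness(group_values)
    truth = {g: ds.force_curves[g].truth["modulus_kpa"] for g in group_values}
    rel_err = {
        g: abs(float(np.median(v)) - truth[g]) / truth[g] for g, v in group_values.items() if len(v)
    }
    summary["afm"] = {
        "group_median_kpa": report["group_medians"],
        "planted_kpa": truth,
        "median_relative_error": rel_err,
        "kruskal_p": report["kruskal"].pvalue,
        "games_howell_pairs": report["games_howell"].as_records(),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "splicing": _stage_splicing,
    "peaks": _stage_peaks,
    "mir": _stage_mir,
    "overlap": _stage_overlap,
    "afm": _stage_afm,
}
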