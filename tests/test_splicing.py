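"""Splicing efficiency statistic and its cluster-count relation."""

import numpy as np
import pandas as pd
import pytest

from clipsplice.peaks import PeakSet
from clipsplice.simulate import SimConfig, generate_all, simulate_junction_counts
from clipsplice.splicing import (
    bin_label,
    compare_se_groups,
    count_clusters_per_feature,
    delta_splicing_efficiency,
    group_se_by_cluster_count,
    splicing_efficiency,
)

from oracles import brute_cluster_counts


def _counts(rows):
    return pd.DataFrame(rows, columns=["gene_id", "intron_index", "sample", "ee", "ei"])


class TestSplicingEfficiency:
    def test_forced_arithmetic(self):
        se = splicing_efficiency(_counts([("G1", 1, "s1", 30, 10)]), min_reads=1)
        assert se["se"].iloc[0] == pytest.approx(0.75)

    @pytest.mark.parametrize("ee,ei,expected", [(10, 0, 1.0), (0, 5, 0.0)])
    def test_boundary_cases(self, ee, ei, expected):
        se = splicing_efficiency(_counts([("G1", 1, "s1", ee, ei)]), min_reads=1)
        assert se["se"].iloc[0] == expected

    def test_low_coverage_flagged_missing_not_zero(self):
        se = splicing_efficiency(_counts([("G1", 1, "s1", 3, 2)]), min_reads=10)
        assert se["missing"].iloc[0]
        assert np.isnan(se["se"].iloc[0])

    def test_gene_level_pools_counts_before_dividing(self):
        rows = [("G1", 1, "s1", 10, 30), ("G1", 2, "s1", 90, 10)]
        se = splicing_efficiency(_counts(rows), level="gene", min_reads=1)
        assert se["se"].iloc[0] == pytest.approx(100 / 140)

    def test_scale_invariance(self):
        a = splicing_efficiency(_counts([("G1", 1, "s1", 12, 4)]), min_reads=1)
        b = splicing_efficiency(_counts([("G1", 1, "s1", 36, 12)]), min_reads=1)
        assert a["se"].iloc[0] == b["se"].iloc[0]

    def test_gene_se_between_intron_extremes(self):
        rows = [("G1", 1, "s1", 50, 50), ("G1", 2, "s1", 90, 10)]
        intron = splicing_efficiency(_counts(rows), level="intron", min_reads=1)
        gene = splicing_efficiency(_counts(rows), level="gene", min_reads=1)
        g = gene["se"].iloc[0]
        assert intron["se"].min() <= g <= intron["se"].max()

    def test_binomial_concentration_on_planted_se(self):
        """500 introns at 200 reads, true SE 0.8: mean estimate near 0.8."""
        rng = np.random.default_rng(42)
        rows = [
            (f"G{i}", 1, "s1", int(ee), 200 - int(ee))
            for i, ee in enumerate(rng.binomial(200, 0.8, size=500))
        ]
        se = splicing_efficiency(_counts(rows), min_reads=10)
        assert 0.78 <= se["se"].mean() <= 0.82

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            splicing_efficiency(_counts([("G1", 1, "s1", 1, 1)]), level="exon")


class TestDeltaSE:
    def test_identical_tables_give_zero(self):
        rows = [("G1", 1, "s1", 30, 10), ("G2", 1, "s1", 5, 15)]
        se = splicing_efficiency(_counts(rows), min_reads=1)
        d = delta_splicing_efficiency(se, se)
        assert (d["delta_se"] == 0).all()

    def test_antisymmetry(self):
        se_a = splicing_efficiency(_counts([("G1", 1, "s1", 30, 10)]), min_reads=1)
        se_b = splicing_efficiency(_counts([("G1", 1, "s2", 10, 30)]), min_reads=1)
        d1 = delta_splicing_efficiency(se_a, se_b)["delta_se"].iloc[0]
        d2 = delta_splicing_efficiency(se_b, se_a)["delta_se"].iloc[0]
        assert d1 == pytest.approx(-d2)

    def test_no_shared_introns_rejected(self):
        se_a = splicing_efficiency(_counts([("G1", 1, "s1", 3, 1)]), min_reads=1)
        se_b = splicing_efficiency(_counts([("G2", 1, "s1", 3, 1)]), min_reads=1)
        with pytest.raises(ValueError, match="shared"):
            delta_splicing_efficiency(se_a, se_b)

    def test_planted_dose_effect_positive_delta(self, default_dataset):
        """Higher LIS1 dose (OE) vs lower (F/-): median delta SE > 0."""
        ds = default_dataset
        se = splicing_efficiency(ds.junction_counts, min_reads=10)
        by_geno = {
            g: se[se["sample"].isin([s for s, gg in ds.sample_map.items() if gg == g])]
            for g in ("OE", "F/-")
        }
        d = delta_splicing_efficiency(by_geno["OE"], by_geno["F/-"])
        assert d["delta_se"].median() > 0


class TestClusterCounts:
    def test_strand_matched_overlap(self, default_dataset):
        iset = default_dataset.intron_set
        intron = iset.introns[0]
        peaks = PeakSet(pd.DataFrame({
            "chrom": [intron.chrom] * 2,
            "start": [intron.start + 10, intron.start + 10],
            "end": [intron.start + 20, intron.start + 20],
            "strand": [intron.strand, "-" if intron.strand == "+" else "+"],
        }))
        sub = type(iset)(introns=[intron])
        counts = count_clusters_per_feature(sub, peaks)
        assert counts["cluster_count"].iloc[0] == 1  # only the same-strand peak

    def test_gene_level_peak_counted_once(self):
        from clipsplice.annotation import IntronSet, Intron

        introns = [
            Intron("G1", "chrT", "+", 100, 200, 1, "protein_coding"),
            Intron("G1", "chrT", "+", 300, 400, 2, "protein_coding"),
        ]
        peaks = PeakSet(pd.DataFrame({
            "chrom": ["chrT"], "start": [150], "end": [350], "strand": ["+"],
        }))
        counts = count_clusters_per_feature(IntronSet(introns), peaks, level="gene")
        assert counts["cluster_count"].iloc[0] == 1

    def test_contig_mismatch_rejected(self, default_dataset):
        peaks = PeakSet(pd.DataFrame({
            "chrom": ["chrZ"], "start": [0], "end": [10], "strand": ["+"],
        }))
        with pytest.raises(ValueError, match="contig"):
            count_clusters_per_feature(default_dataset.intron_set, peaks)

    def test_matches_brute_force_oracle(self, default_dataset):
        ds = default_dataset
        counts = count_clusters_per_feature(ds.intron_set, ds.peaks)
        introns = [
            (i.chrom, i.start, i.end, i.strand) for i in ds.intron_set
        ]
        peaks = list(
            ds.peaks.df[["chrom", "start", "end", "strand"]].itertuples(index=False, name=None)
        )
        assert counts["cluster_count"].tolist() == brute_cluster_counts(introns, peaks)


class TestGrouping:
    def test_bin_labels(self):
        assert bin_label(0) == "0"
        assert bin_label(2) == "1-2"
        assert bin_label(4) == "3-5"
        assert bin_label(9) == ">=6"

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            bin_label(1, edges=(0, 3, 2))

    def test_all_zero_counts_single_bin(self):
        se = splicing_efficiency(
            _counts([("G1", 1, "s1", 10, 2), ("G2", 1, "s1", 9, 3)]), min_reads=1
        )
        cc = pd.DataFrame({"gene_id": ["G1", "G2"], "intron_index": [1, 1], "cluster_count": [0, 0]})
        grouping = group_se_by_cluster_count(se, cc)
        assert set(grouping["cluster_bin"]) == {"0"}

    def test_planted_negative_slope_monotone_medians(self, default_dataset):
        """With beta1 < 0, median SE strictly decreases across occupied bins
        within each genotype."""
        ds = default_dataset
        se = splicing_efficiency(ds.junction_counts, min_reads=10)
        cc = count_clusters_per_feature(ds.intron_set, ds.peaks)
        grouping = group_se_by_cluster_count(se, cc)
        grouping["genotype"] = grouping["sample"].map(ds.sample_map)
        order = grouping.attrs["bin_order"]
        for genotype, sub in grouping.groupby("genotype"):
            meds = [
                sub.loc[sub["cluster_bin"] == b, "se"].median()
                for b in order
                if (sub["cluster_bin"] == b).any()
            ]
            assert all(a > b for a, b in zip(meds, meds[1:])), genotype


class TestCompare:
    def test_two_identical_groups_null(self):
        g = pd.DataFrame({
            "cluster_bin": ["a"] * 30 + ["b"] * 30,
            "se": list(np.linspace(0, 1, 30)) * 2,
        })
        report = compare_se_groups(g)
        assert report["kruskal"].pvalue > 0.99

    def test_single_member_group_excluded(self):
        g = pd.DataFrame({
            "cluster_bin": ["a"] * 10 + ["b"] * 10 + ["c"],
            "se": list(np.linspace(0, 1, 10)) * 2 + [0.5],
        })
        report = compare_se_groups(g)
        assert report["excluded_groups"] == ["c"]

    def test_planted_effect_detected(self, default_dataset):
        ds = default_dataset
        se = splicing_efficiency(ds.junction_counts, min_reads=10)
        cc = count_clusters_per_feature(ds.intron_set, ds.peaks)
        grouping = group_se_by_cluster_count(se, cc)
        report = compare_se_groups(grouping)
        assert report["kruskal"].pvalue < 1e-10


def test_null_beta1_kw_type_i_error():
    """With no planted cluster effect, KW across bins rejects ~5%."""
    rejections = 0
    n_reps = 120
    base = SimConfig(
        seed=0, n_genes=24, n_mirs=8, n_replicates=1,
        genotypes={"WT": 1.0}, se_beta1=0.0, se_beta2=0.0,
    )
    from dataclasses import replace

    from clipsplice.annotation import build_unique_intron_set
    from clipsplice.simulate import make_toy_annotation, simulate_peaks

    for rep in range(n_reps):
        cfg = replace(base, seed=50_000 + rep)
        ann, mirs = make_toy_annotation(cfg)
        iset = build_unique_intron_set(ann)
        peaks = simulate_peaks(ann, cfg, mirs=mirs, intron_set=iset)
        counts, sample_map, _ = simulate_junction_counts(ann, peaks, cfg, iset)
        se = splicing_efficiency(counts, min_reads=10)
        cc = count_clusters_per_feature(iset, peaks)
        grouping = group_se_by_cluster_count(se, cc)
        try:
            report = compare_se_groups(grouping)
        except ValueError:
            continue
        rejections += report["kruskal"].pvalue < 0.05
    assert 0.02 <= rejections / n_reps <= 0.09
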