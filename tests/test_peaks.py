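"""Peak filtering, annotation, distances, metaprofiles, motif windows."""

import numpy as np
import pandas as pd
import pytest

from clipsplice.annotation import GenomeAnnotation, Gene, Transcript
from clipsplice.peaks import (
    CoverageTrack,
    DEFAULT_CATEGORY_PRIORITY,
    PeakSet,
    annotate_peaks,
    cassette_exon_map,
    closest_peak_distance,
    exon_metaprofile,
    filter_peaks,
    motif_windows,
    premir_metaprofile,
)
from clipsplice.simulate import (
    SimConfig,
    simulate_coverage,
    simulate_genome_sequence,
    write_fasta,
)

from oracles import brute_annotate, brute_closest


def _peakset(rows, extra=()):
    cols = ["chrom", "start", "end", "strand"] + list(extra)
    return PeakSet(pd.DataFrame(rows, columns=cols))


class TestFilter:
    def test_inclusive_boundary_retained(self):
        ps = _peakset([("c", 0, 10, "+", 3.0, 0.001)], extra=("log2fc", "padj"))
        assert len(filter_peaks(ps)) == 1

    def test_high_padj_dropped(self):
        ps = _peakset([("c", 0, 10, "+", 5.0, 0.01)], extra=("log2fc", "padj"))
        assert len(filter_peaks(ps)) == 0

    def test_matches_brute_force_on_random_set(self):
        rng = np.random.default_rng(0)
        n = 500
        df = pd.DataFrame({
            "chrom": "c",
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "strand": "+",
            "log2fc": rng.uniform(0, 6, n),
            "padj": 10.0 ** -rng.uniform(0, 6, n),
        })
        kept = filter_peaks(PeakSet(df))
        expected = {
            i for i in range(n) if df["log2fc"][i] >= 3.0 and df["padj"][i] <= 0.001
        }
        assert set(kept.df["start"] // 100) == expected


def _toy_annotation():
    """One pc gene with CDS/UTRs, one noncoding gene, shared contig."""
    pc = Gene(id="G1", chrom="c", strand="+", start=0, end=1000, biotype="protein_coding")
    t = Transcript(id="T1", gene_id="G1", exons=[(0, 200), (500, 1000)])
    t.cds = [(50, 200), (500, 900)]  # 5'UTR [0,50), 3'UTR [900,1000)
    pc.transcripts.append(t)
    nc = Gene(id="G2", chrom="c", strand="+", start=2000, end=3000, biotype="noncoding")
    nc.transcripts.append(Transcript(id="T2", gene_id="G2", exons=[(2000, 2200), (2800, 3000)]))
    return GenomeAnnotation(genes=[pc, nc], contigs={"c": 5000})


class TestAnnotate:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (60, 80, "CDS-exon"),
            (0, 30, "5'UTR"),
            (920, 960, "3'UTR"),
            (300, 350, "protein-coding intron"),
            (2100, 2150, "noncoding exon"),
            (2400, 2500, "noncoding intron"),
            (4000, 4100, "intergenic"),
            (180, 260, "CDS-exon"),  # spans exon/intron boundary: exon wins
        ],
    )
    def test_category_priority(self, start, end, expected):
        ps = _peakset([("c", start, end, "+")])
        out = annotate_peaks(ps, _toy_annotation())
        assert out["category"].iloc[0] == expected

    def test_strand_mismatch_is_intergenic(self):
        ps = _peakset([("c", 60, 80, "-")])
        assert annotate_peaks(ps, _toy_annotation())["category"].iloc[0] == "intergenic"

    def test_fractions_sum_to_one(self, default_dataset):
        out = annotate_peaks(default_dataset.peaks, default_dataset.annotation)
        assert sum(out.attrs["fractions"].values()) == pytest.approx(1.0)

    def test_planted_intronic_majority_recovered(self, default_dataset):
        """~87% of significant peaks are planted intronic; the annotation
        recovers that fraction."""
        sig = filter_peaks(default_dataset.peaks)
        out = annotate_peaks(sig, default_dataset.annotation)
        frac = out.attrs["fractions"]
        intronic = frac.get("protein-coding intron", 0) + frac.get("noncoding intron", 0)
        assert abs(intronic - 0.87) < 0.03

    def test_matches_per_base_oracle_on_random_peaks(self):
        ann = _toy_annotation()
        from clipsplice.peaks import _category_intervals

        cat_ivs = _category_intervals(ann)
        category_bases = {}
        for (cat, chrom, strand), ivs in cat_ivs.items():
            bases = category_bases.setdefault(cat, set())
            for s, e in ivs:
                bases.update((chrom, strand, p) for p in range(s, e))
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(300):
            s = int(rng.integers(0, 4900))
            rows.append(("c", s, s + int(rng.integers(1, 120)), "+" if rng.random() < 0.7 else "-"))
        out = annotate_peaks(_peakset(rows), ann)
        for row, got in zip(rows, out["category"]):
            assert got == brute_annotate(row, category_bases, DEFAULT_CATEGORY_PRIORITY)


class TestClosest:
    def test_gap_arithmetic(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [500], "end": [520]})
        ps = _peakset([("c", 600, 650, "+")])
        out = closest_peak_distance(feats, ps)
        assert out["distance"].iloc[0] == 80

    def test_overlap_is_zero(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [500], "end": [520]})
        ps = _peakset([("c", 510, 530, "+")])
        assert closest_peak_distance(feats, ps)["distance"].iloc[0] == 0

    def test_max_search_flags_far_features(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        ps = _peakset([("c", 5000, 5010, "+")])
        out = closest_peak_distance(feats, ps, max_search=2000)
        assert not out["within_search"].iloc[0]
        assert np.isnan(out["distance"].iloc[0])

    def test_matches_brute_force_with_tie_rule(self):
        rng = np.random.default_rng(8)
        n = 400
        feats = pd.DataFrame({
            "chrom": rng.choice(["c1", "c2"], n),
            "start": rng.integers(0, 20000, n),
        })
        feats["end"] = feats["start"] + rng.integers(1, 50, n)
        prows = []
        for _ in range(n):
            s = int(rng.integers(0, 20000))
            prows.append((rng.choice(["c1", "c2"]), s, s + int(rng.integers(1, 80)), "+"))
        ps = _peakset(prows)
        ps.df["name"] = [f"p{i}" for i in range(n)]
        out = closest_peak_distance(feats, ps)
        oracle = brute_closest(
            list(feats[["chrom", "start", "end"]].itertuples(index=False, name=None)),
            [(c, s, e) for c, s, e, _ in prows],
        )
        for (dist, j), got_d, got_p in zip(oracle, out["distance"], out["peak"]):
            if dist is None:
                assert got_p is None
            else:
                assert got_d == dist
                assert got_p == f"p{j}"


class TestMetaprofiles:
    def test_flat_coverage_gives_flat_profile(self):
        ann = _toy_annotation()
        # add a middle exon so internal exons exist
        g = ann.genes[0]
        g.transcripts[0].exons = [(0, 200), (300, 400), (500, 1000)]
        flat = {("c", "+"): np.full(5000, 3.0), ("c", "-"): np.full(5000, 3.0)}
        ip = CoverageTrack("IP", {k: v.copy() for k, v in flat.items()})
        smi = CoverageTrack("SMI", {k: v.copy() for k, v in flat.items()})
        prof_ip, prof_smi = exon_metaprofile(ip, smi, ann, flank=100, body_bins=20)
        assert np.allclose(prof_ip.values, 3.0)
        assert np.allclose(prof_ip.spread, 0.0)

    def test_donor_biased_peaks_put_maximum_past_donor(self, default_dataset):
        """Planted donor-proximal peaks: the IP profile maximum falls in the
        donor-adjacent intronic flank; the SMI control does not."""
        ds = default_dataset
        ip, smi = simulate_coverage(ds.annotation, ds.peaks, ds.config, events=None)
        prof_ip, prof_smi = exon_metaprofile(ip, smi, ds.annotation)
        body_bins = 100
        argmax_pos = prof_ip.positions[int(np.argmax(prof_ip.values))]
        assert body_bins <= argmax_pos < body_bins + 300
        donor = prof_ip.values[prof_ip.positions >= body_bins]
        acceptor = prof_ip.values[prof_ip.positions < 0]
        assert donor.mean() > acceptor.mean() + 0.5
        smi_donor = prof_smi.values[prof_smi.positions >= body_bins]
        smi_acc = prof_smi.values[prof_smi.positions < 0]
        assert abs(smi_donor.mean() - smi_acc.mean()) < 0.2

    def test_premir_all_zero_coverage(self):
        cov = CoverageTrack("IP", {("c", "+"): np.zeros(10000)})
        mirs = pd.DataFrame({"chrom": ["c"], "start": [5000], "end": [5080], "strand": ["+"]})
        prof = premir_metaprofile(cov, mirs)
        assert np.allclose(prof.values, 0.0)

    def test_premir_delta_coverage_centered_after_scaling(self):
        arr = np.zeros(10000)
        arr[5000:5080] = 50.0  # over the pre-miR span (median binning
        # suppresses anything narrower than half a bin)
        cov = CoverageTrack("IP", {("c", "+"): arr})
        mirs = pd.DataFrame({"chrom": ["c"], "start": [5000], "end": [5080], "strand": ["+"]})
        prof = premir_metaprofile(cov, mirs)
        peak_bin = int(np.argmax(prof.values))
        assert abs(peak_bin - len(prof.values) // 2) <= 1

    def test_premir_planted_on_mir_peaks_enriched_center(self):
        """All flagged miRs carry on-miR peaks over sparse background:
        central enrichment over the flanks exceeds 2x."""
        cfg = SimConfig(seed=11, coverage_base=0.5, mir_peak_on_mir_prob=1.0)
        from clipsplice.simulate import make_toy_annotation, simulate_peaks

        ann, mirs = make_toy_annotation(cfg)
        peaks = simulate_peaks(ann, cfg, mirs=mirs)
        ip, _ = simulate_coverage(ann, peaks, cfg, events=None)
        flagged = mirs[mirs["near_peak_flag"]].rename(
            columns={"premir_start": "start", "premir_end": "end"}
        )
        prof = premir_metaprofile(ip, flagged[["chrom", "start", "end", "strand"]])
        n5 = len(prof.values) // 5
        center = prof.values[2 * n5 : 3 * n5].mean()
        flanks = np.r_[prof.values[:n5], prof.values[-n5:]].mean()
        assert center / max(flanks, 1e-9) > 2

    def test_profile_invariant_to_feature_order(self):
        cov = CoverageTrack("IP", {("c", "+"): np.arange(10000, dtype=float)})
        mirs = pd.DataFrame({
            "chrom": ["c", "c"], "start": [3000, 6000], "end": [3080, 6080], "strand": ["+", "+"],
        })
        p1 = premir_metaprofile(cov, mirs)
        p2 = premir_metaprofile(cov, mirs.iloc[::-1])
        assert np.allclose(p1.values, p2.values)


class TestCassetteMap:
    def _events(self):
        return pd.DataFrame({
            "chrom": ["c", "c"],
            "strand": ["+", "+"],
            "exon_start": [2000, 6000],
            "exon_end": [2200, 6150],
            "delta_psi": [0.3, -0.3],
            "direction": ["higher_in_OE", "lower_in_OE"],
        })

    def test_identical_tracks_give_unit_profile(self):
        arr = np.random.default_rng(0).poisson(5, 10000).astype(float)
        ip = CoverageTrack("IP", {("c", "+"): arr.copy()})
        smi = CoverageTrack("SMI", {("c", "+"): arr.copy()})
        out = cassette_exon_map(ip, smi, self._events())
        for direction, (acc, don) in out.items():
            assert np.allclose(acc.values, 1.0)
            assert np.allclose(don.values, 1.0)

    def test_window_binning_geometry(self):
        arr = np.ones(10000)
        ip = CoverageTrack("IP", {("c", "+"): arr})
        smi = CoverageTrack("SMI", {("c", "+"): arr.copy()})
        out = cassette_exon_map(ip, smi, self._events())
        acc, don = out["higher_in_OE"]
        assert len(acc.values) == (250 + 50) // 50
        assert len(don.values) == (50 + 250) // 50

    def test_subthreshold_events_excluded(self):
        ev = self._events()
        ev.loc[0, "delta_psi"] = 0.1
        arr = np.ones(10000)
        ip = CoverageTrack("IP", {("c", "+"): arr})
        smi = CoverageTrack("SMI", {("c", "+"): arr.copy()})
        out = cassette_exon_map(ip, smi, ev)
        assert "higher_in_OE" not in out

    def test_planted_direction_specific_enrichment(self, default_dataset):
        """higher_in_OE events carry exonic signal; lower_in_OE events carry
        intronic acceptor-side signal (profile maxima land accordingly)."""
        ds = default_dataset
        out = cassette_exon_map(ds.coverage_ip, ds.coverage_smi, ds.lsv_events)
        acc_hi, don_hi = out["higher_in_OE"]
        acc_lo, don_lo = out["lower_in_OE"]
        # acceptor window layout: 5 intronic bins then 1 exonic bin
        assert int(np.argmax(acc_lo.values)) < 5  # intron, acceptor side
        assert int(np.argmax(acc_hi.values)) == 5  # exonic bin
        # donor window layout: 1 exonic bin then 5 intronic bins
        assert int(np.argmax(don_hi.values)) == 0


class TestMotifWindows:
    def test_window_arithmetic_and_strand(self, tmp_path, default_dataset):
        ds = default_dataset
        seqs = simulate_genome_sequence(ds.annotation, ds.config)
        fasta = tmp_path / "genome.fa"
        write_fasta(seqs, fasta)
        ps = _peakset([("chrS", 100, 110, "+"), ("chrS", 100, 110, "-")])
        recs = motif_windows(ps, fasta)
        seq = seqs["chrS"]
        expected = seq[55:156]
        assert recs[0][1] == expected
        comp = str.maketrans("ACGT", "TGCA")
        assert recs[1][1] == expected.translate(comp)[::-1]
        assert len(recs[0][1]) == 101

    def test_contig_edge_clipped_and_flagged(self, tmp_path, default_dataset):
        ds = default_dataset
        seqs = simulate_genome_sequence(ds.annotation, ds.config)
        fasta = tmp_path / "genome.fa"
        write_fasta(seqs, fasta)
        ps = _peakset([("chrS", 0, 10, "+")])
        recs = motif_windows(ps, fasta)
        assert recs[0][2]  # clipped flag
        assert len(recs[0][1]) < 101
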