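#!/usr/bin/env python
"""CLIP peak landscape: filtering, functional categories, metaprofiles.

Applies the significance filter (log2FC >= 3, padj <= 0.001), assigns
each peak one functional category by priority, and builds the
exon-anchored and pre-miR metaprofiles plus the cassette-exon signal
map.  Finding on the default cohort: ~87% of significant peaks are
intronic, the exon-profile maximum sits in the donor-proximal intronic
flank, and higher_in_OE cassette events carry exonic signal while
lower_in_OE events carry acceptor-side intronic signal.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from clipsplice.peaks import (
    annotate_peaks,
    cassette_exon_map,
    exon_metaprofile,
    filter_peaks,
    motif_windows,
    premir_metaprofile,
    write_fasta as write_window_fasta,
)
from clipsplice.simulate import (
    SimConfig,
    generate_all,
    simulate_coverage,
    simulate_genome_sequence,
    write_fasta,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    ds = generate_all(SimConfig(seed=args.seed))
    sig = filter_peaks(ds.peaks)
    print(f"peaks: {len(ds.peaks)} total, {len(sig)} pass log2FC>=3, padj<=0.001")

    annotated = annotate_peaks(sig, ds.annotation)
    frac = pd.Series(annotated.attrs["fractions"]).sort_values(ascending=False)
    frac.rename("fraction").to_csv(out / "peak_category_fractions.tsv", sep="\t")
    print("category fractions:")
    print((100 * frac).round(1).to_string())
    intronic = frac.get("protein-coding intron", 0) + frac.get("noncoding intron", 0)
    print(f"intronic total: {100 * intronic:.1f}%")

    # donor bias is assessed on peak-only coverage (no cassette-event signal)
    ip, smi = simulate_coverage(ds.annotation, ds.peaks, ds.config, events=None)
    prof_ip, prof_smi = exon_metaprofile(ip, smi, ds.annotation)
    pd.DataFrame({
        "position": prof_ip.positions, "ip": prof_ip.values, "smi": prof_smi.values,
    }).to_csv(out / "exon_metaprofile.tsv", sep="\t", index=False)
    argmax = prof_ip.positions[int(np.argmax(prof_ip.values))]
    print(f"exon metaprofile IP maximum at position {argmax} "
          "(donor-proximal intron = positions 100-399)")

    premir = ds.mirs.rename(columns={"premir_start": "start", "premir_end": "end"})
    pre = premir_metaprofile(ds.coverage_ip, premir[["chrom", "start", "end", "strand"]])
    pd.DataFrame({"position": pre.positions, "signal": pre.values}).to_csv(
        out / "premir_metaprofile.tsv", sep="\t", index=False
    )

    cmap = cassette_exon_map(ds.coverage_ip, ds.coverage_smi, ds.lsv_events)
    for direction, (acc, don) in cmap.items():
        print(f"cassette {direction}: acceptor-window argmax bin {int(np.argmax(acc.values))} "
              f"(0-4 intronic, 5 exonic), donor-window argmax bin {int(np.argmax(don.values))} "
              "(0 exonic, 1-5 intronic)")

    seqs = simulate_genome_sequence(ds.annotation, ds.config)
    fasta = out / "genome.fa"
    write_fasta(seqs, fasta)
    windows = motif_windows(sig, fasta)
    write_window_fasta(windows, out / "motif_windows.fa")
    print(f"{len(windows)} motif windows (101 nt) written for external motif search")


if __name__ == "__main__":
    main()
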