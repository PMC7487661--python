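#!/usr/bin/env python
"""Identify the TF's lncRNA and PCG targets from promoter binding.

Maps each ChIP sample's peaks onto strand-aware promoter windows
(-2000..+200 bp of TSS), keeps genes bound in >= 2 of 5 samples,
intersects with the consensus DE calls, refines lncRNA targets by
co-expression support, summarises peak length/signal per biotype and
exports bound-region sequences with their GC content.  Writes
results/targets.tsv, results/peak_summary.json, results/regions.fa.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from tfnetminer import io, targets


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--de-table", type=Path, default=Path("results/de_table.tsv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    annotation = io.read_annotation(args.datadir / "annotation.tsv")
    peak_files = sorted(args.datadir.glob("peaks_*.bed"))
    peaks = {p.stem.removeprefix("peaks_"): io.read_peaks_bed(p) for p in peak_files}
    windows = targets.promoter_windows(annotation)
    binding = targets.assign_binding(peaks, windows)

    de = pd.read_csv(args.de_table, sep="\t")
    cons = de[de["consensus"]]
    up = cons.loc[cons.direction == "up", "gene_id"].tolist()
    down = cons.loc[cons.direction == "down", "gene_id"].tolist()
    coexpr = [io.read_edges(args.datadir / f"coexpr_ds{i}.tsv") for i in (1, 2, 3)]
    ts = targets.select_targets(binding, up, down, annotation, coexpr, tf_gene="KLF5")

    rows = [(g, "lncRNA", d, g in ts.lncrna_highconf) for g, d in ts.lncrna_targets]
    rows += [(g, "PCG", d, False) for g, d in ts.pcg_targets]
    pd.DataFrame(rows, columns=["gene_id", "biotype", "direction", "highconf"]) \
        .to_csv(args.outdir / "targets.tsv", sep="\t", index=False)

    stats = targets.peak_region_stats(peaks, ts, annotation)
    summary = {
        bt: {"n_peaks": s.n_peaks, "mean_length": s.mean_length, "mean_signal": s.mean_signal}
        for bt, s in stats["summaries"].items()
    }
    summary["length_ttest_p"] = stats["length_ttest_p"]
    summary["signal_ttest_p"] = stats["signal_ttest_p"]
    (args.outdir / "peak_summary.json").write_text(json.dumps(summary, indent=1))

    genome = io.read_genome(args.datadir / "genome.fa")
    target_windows = {w.gene_id: w for w in windows if w.gene_id in ts.all_ids}
    bound_peaks = [
        p for plist in peaks.values() for p in plist
        if any(min(p.end, w.end) - max(p.start, w.start) >= 1
               for w in target_windows.values())
    ]
    regions = targets.export_regions(bound_peaks, genome)
    io.write_fasta_records([(name, seq) for name, seq, _ in regions],
                           args.outdir / "regions.fa")

    print(f"{len(ts.lncrna_targets)} lncRNA targets ({len(ts.lncrna_highconf)} "
          f"high-confidence) and {len(ts.pcg_targets)} PCG targets")
    for bt, s in stats["summaries"].items():
        if s.n_peaks:
            print(f"  {bt}: {s.n_peaks} peaks, mean length {s.mean_length:.0f} bp, "
                  f"mean signal {s.mean_signal:.1f}")
    if regions:
        print(f"  bound regions mean GC: {np.mean([gc for *_, gc in regions]):.2f} "
              f"-> {args.outdir / 'regions.fa'}")


if __name__ == "__main__":
    main()
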