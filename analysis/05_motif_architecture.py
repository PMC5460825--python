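"""Motif architecture of the pooled GR peaks.

Scans summit windows with the consensus library (full GRE, GRE
half-site, NF-1 half-site, bHLH, nGRE), classifies per-peak
architecture, partitions by full-GRE presence, builds positional
histograms, stratifies motif and composite-class frequencies by peak
strength (top vs bottom third of tag density), summarizes the nGRE
centrality question, and runs the k-mer enrichment stand-in for de novo
discovery.

Reads results/simdata/ and results/peaks/, writes results/motifs/.
"""

import json
import logging
from pathlib import Path

import pandas as pd

from grchip import io, motifarch

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

SIM = Path("results/simdata")
OUT = Path("results/motifs")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    genome = io.parse_fasta(SIM / "genome.fa")["chr1"]
    pooled = pd.read_csv("results/peaks/peaks_pooled.tsv", sep="\t")

    hits = motifarch.scan_peaks(pooled, genome)
    hits_wide = motifarch.scan_peaks(pooled, genome, halfwidth=1000)
    arch = motifarch.classify_architecture(pooled, hits)
    io.write_tsv(hits, OUT / "motif_hits.tsv")
    io.write_tsv(arch, OUT / "architecture.tsv")

    freq = motifarch.class_frequencies(arch)
    io.write_tsv(freq.rename("fraction").rename_axis("motif_class")
                 .reset_index(), OUT / "motif_frequencies.tsv")
    print("motif frequencies over pooled peaks:")
    for cls, f in freq.items():
        print(f"  {cls}: {100 * f:.1f}%")
    neither = int((~arch["has_full_gre"] & ~arch["has_gre_half"]).sum())
    print(f"peaks with neither GRE form: {neither}")

    _, _, part = motifarch.partition_by_full_gre(arch)
    io.write_tsv(part, OUT / "partition_frequencies.tsv", index=True)

    hist, med = motifarch.positional_histogram(
        motifarch.drop_nested_half_hits(hits_wide))
    io.write_tsv(hist, OUT / "positional_histograms.tsv", index=True)
    io.write_tsv(med.rename_axis("motif").reset_index(),
                 OUT / "median_abs_offsets.tsv")

    strat = motifarch.stratify_by_strength(pooled, arch)
    io.write_tsv(strat, OUT / "strength_stratification.tsv", index=True)
    comp = motifarch.composite_by_strength(pooled, arch)
    io.write_tsv(comp, OUT / "composite_by_strength.tsv", index=True)
    print("top vs bottom third frequencies (full GRE, NF-1, bHLH):")
    for cls in ("has_full_gre", "has_nf1_half", "has_bhlh"):
        print(f"  {cls}: {strat.loc[cls, 'top_third']:.3f} vs "
              f"{strat.loc[cls, 'bottom_third']:.3f}")
    print(f"GRE/H alone composite: top {comp.loc['GRE/H alone', 'top_third']:.3f} "
          f"vs bottom {comp.loc['GRE/H alone', 'bottom_third']:.3f}")

    report, summary = motifarch.ngre_analysis(hits_wide)
    io.write_tsv(report, OUT / "ngre_report.tsv")
    (OUT / "ngre_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"nGRE-containing peaks: {summary['n_with_ngre']}; "
          f"lacking any GRE form: {summary['n_without_gre_form']}")

    fg = [motifarch.peak_window(genome, int(r["summit"]), 100)[0]
          for _, r in pooled.iterrows()]
    kmers = motifarch.kmer_enrichment(fg, widths=(6, 8, 10, 12, 14, 16),
                                      seed=1)
    io.write_tsv(kmers.groupby("width").head(25),
                 OUT / "kmer_enrichment_top.tsv")
    best12 = kmers[kmers["width"] == 12].iloc[0]
    print(f"top 12-mer: {best12['kmer']} (q = {best12['q_value']:.2e})")
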