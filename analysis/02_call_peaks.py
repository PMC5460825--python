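"""Call replicate-concordant GR peaks and pool the two groups.

Per sample: deduplicate, extend tags to 150 bp, bin, and run the
hotspot-style windowed binomial test against the input-normalized local
background.  Peaks called in both replicates of a group are intersected;
because the planted site set already emulates the paper-style
post-selection peak list, every concordant peak is kept for the pooled
analysis set (the top-20% ranking is reported for reference).

Reads results/simdata/, writes results/peaks/ and prints recovery
against the planted truth.
"""

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from grchip import io, peakcall
from grchip.pipeline import preprocess_sample

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

SIM = Path("results/simdata")
OUT = Path("results/peaks")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    genome = io.parse_fasta(SIM / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}
    peaks_by_sample, tracks = {}, {}
    for c in (1, 2):
        for r in (1, 2):
            name = f"chip_c{c}_r{r}"
            _, chip_track = preprocess_sample(SIM / f"{name}.bed", sizes)
            _, input_track = preprocess_sample(
                SIM / f"input_c{c}_r{r}.bed", sizes)
            peaks_by_sample[name] = peakcall.call_hotspots(chip_track,
                                                           input_track)
            print(f"{name}: {len(peaks_by_sample[name])} hotspot peaks")
    group_peaks = {}
    for g, c in (("A", 1), ("B", 2)):
        conc = peakcall.concordant_peaks(peaks_by_sample[f"chip_c{c}_r1"],
                                         peaks_by_sample[f"chip_c{c}_r2"])
        group_peaks[g] = peakcall.rank_top_fraction(conc, 1.0)
        top20 = peakcall.rank_top_fraction(conc, 0.2)
        io.write_tsv(group_peaks[g], OUT / f"peaks_group_{g}.tsv")
        io.write_tsv(top20, OUT / f"peaks_group_{g}_top20.tsv")
        print(f"group {g}: {len(conc)} concordant "
              f"({len(top20)} in the top 20%)")
    pooled = peakcall.pool_nonduplicated(group_peaks["A"], group_peaks["B"])
    io.write_tsv(pooled, OUT / "peaks_pooled.tsv")

    truth = pd.read_csv(SIM / "truth_sites.tsv", sep="\t")
    centers = truth["center"].to_numpy()
    starts = pooled["start"].to_numpy()
    ends = pooled["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], np.maximum.accumulate(ends[order])
    j = np.searchsorted(starts, centers, side="right") - 1
    hit = (j >= 0) & (ends[np.clip(j, 0, None)] > centers)
    w = truth["enrichment_weight"].to_numpy()
    print(f"pooled: {len(pooled)} peaks; recovery of sites with weight >= "
          f"median: {hit[w >= np.median(w)].mean():.3f}; overall "
          f"{hit.mean():.3f}")
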