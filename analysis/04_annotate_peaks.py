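"""Annotate pooled peaks to their nearest TSS and classify locations.

Each summit gets a signed distance to the nearest transcription start
site and one exclusive category (promoter -5 kb/+100 bp > 5'UTR > exon >
intron > 3'UTR > intergenic); the gene-proximal subset (gene body or
within 5 kb upstream of a TSS) is exported for downstream gene-level
work.

Reads results/simdata/ and results/peaks/, writes results/annotation/.
"""

import logging
from pathlib import Path

import pandas as pd

from grchip import annotate, io

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

SIM = Path("results/simdata")
OUT = Path("results/annotation")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    pooled = pd.read_csv("results/peaks/peaks_pooled.tsv", sep="\t")
    genes = annotate.gene_models_from_table(
        annotate.read_gene_models(SIM / "gene_models.tsv"))
    ann = annotate.nearest_tss(pooled, genes)
    io.write_tsv(ann, OUT / "annotations.tsv")
    frac = annotate.category_fractions(ann)
    io.write_tsv(frac.rename("fraction").rename_axis("category")
                 .reset_index(), OUT / "category_fractions.tsv")
    proximal = annotate.select_gene_proximal(pooled, ann, genes)
    io.write_tsv(proximal, OUT / "peaks_gene_proximal.tsv")
    print("genomic distribution:")
    for cat, f in frac.items():
        print(f"  {cat}: {100 * f:.1f}%")
    print(f"gene-proximal subset: {len(proximal)} of {len(pooled)} peaks")
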