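"""Peak annotation relative to gene models.

Each peak is assigned its nearest transcription start site (TSS; txStart
for + genes, txEnd for - genes) with a signed distance (negative =
upstream of the gene), and one exclusive genomic category evaluated at the
summit with precedence promoter > 5'UTR > exon > intron > 3'UTR >
intergenic.  The promoter is defined as -5 kb to +100 bp around the TSS.
The gene-proximal subset keeps peaks whose summit lies inside a gene body
or within 5 kb upstream of a TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene", "chrom", "strand", "txStart", "txEnd",
                "exonStarts", "exonEnds"]

CATEGORIES = ["promoter", "5utr", "exon", "intron", "3utr", "intergenic"]

PROMOTER_UPSTREAM = 5000   # bp upstream of TSS
PROMOTER_DOWNSTREAM = 100  # bp downstream of TSS


@dataclass
class GeneModel:
    """One transcript model; exons sorted, within [txStart, txEnd)."""

    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene}")
        ex = list(zip(self.exon_starts, self.exon_ends))
        if ex != sorted(ex) or any(s >= e for s, e in ex):
            raise ValueError(f"malformed exons for {self.gene}")
        for s, e in ex:
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"exon outside transcript for {self.gene}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    def utr_exons(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(5'UTR exon, 3'UTR exon) — the strand-aware first/last exon.

        Synthetic gene models carry no CDS, so the terminal exon segments
        stand in for UTRs.
        """
        first = (self.exon_starts[0], self.exon_ends[0])
        last = (self.exon_starts[-1], self.exon_ends[-1])
        return (first, last) if self.strand == "+" else (last, first)


def gene_models_from_table(table: pd.DataFrame) -> list[GeneModel]:
    models = []
    for _, r in table.iterrows():
        models.append(GeneModel(
            gene=str(r["gene"]), chrom=str(r["chrom"]),
            strand=str(r["strand"]),
            tx_start=int(r["txStart"]), tx_end=int(r["txEnd"]),
            exon_starts=tuple(int(x) for x in
                              str(r["exonStarts"]).rstrip(",").split(",")),
            exon_ends=tuple(int(x) for x in
                            str(r["exonEnds"]).rstrip(",").split(","))))
    return models


def read_gene_models(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene-model table missing columns {sorted(missing)}")
    gene_models_from_table(table)  # validates
    return table


def write_gene_models_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def signed_tss_distance(summit: int, gene: GeneModel) -> int:
    """Summit-to-TSS distance; negative means upstream of the gene."""
    d = summit - gene.tss
    return d if gene.strand == "+" else -d


def nearest_tss(peaks: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Nearest-TSS assignment; ties go to the lexicographically first gene."""
    if not genes:
        raise ValueError("at least one gene model required")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for _, r in peaks.iterrows():
        summit = int(r["summit"])
        candidates = by_chrom.get(r["chrom"], [])
        pool = candidates if candidates else genes
        best = min(pool, key=lambda g: (abs(summit - g.tss)
                                        if g.chrom == r["chrom"] else np.inf,
                                        g.gene))
        dist = signed_tss_distance(summit, best)
        rows.append(dict(peak_id=r["peak_id"], nearest_gene=best.gene,
                         tss_distance=int(dist)))
    ann = pd.DataFrame(rows)
    ann["category"] = [
        classify_genomic_region(int(p["summit"]), str(p["chrom"]),
                                int(a["tss_distance"]), genes)
        for (_, p), (_, a) in zip(peaks.iterrows(), ann.iterrows())]
    return ann


def classify_genomic_region(summit: int, chrom: str, nearest_distance: int,
                            genes: list[GeneModel]) -> str:
    """One exclusive category for a summit, by the stated precedence.

    Promoter status uses the nearest-TSS signed distance
    (-5000 <= d <= +100); the transcript-body categories test the summit
    against every gene containing it.
    """
    if -PROMOTER_UPSTREAM <= nearest_distance <= PROMOTER_DOWNSTREAM:
        return "promoter"
    found = set()
    for g in genes:
        if g.chrom != chrom or not (g.tx_start <= summit < g.tx_end):
            continue
        utr5, utr3 = g.utr_exons()
        if utr5[0] <= summit < utr5[1]:
            found.add("5utr")
        elif utr3[0] <= summit < utr3[1]:
            found.add("3utr")
        elif any(s <= summit < e for s, e in zip(g.exon_starts, g.exon_ends)):
            found.add("exon")
        else:
            found.add("intron")
    for cat in ("5utr", "exon", "intron", "3utr"):
        if cat in found:
            return cat
    return "intergenic"


def category_fractions(annotations: pd.DataFrame) -> pd.Series:
    """Fraction of peaks per category (sums to 1)."""
    frac = annotations["category"].value_counts(normalize=True)
    return frac.reindex(CATEGORIES, fill_value=0.0)


def select_gene_proximal(peaks: pd.DataFrame, annotations: pd.DataFrame,
                         genes: list[GeneModel],
                         upstream: int = 5000) -> pd.DataFrame:
    """Peaks whose summit is inside a gene body or within ``upstream`` bp
    upstream (strand-aware) of a TSS."""
    keep = []
    for (_, p), (_, a) in zip(peaks.iterrows(), annotations.iterrows()):
        summit = int(p["summit"])
        inside = any(g.chrom == p["chrom"] and g.tx_start <= summit < g.tx_end
                     for g in genes)
        upstream_ok = any(
            g.chrom == p["chrom"]
            and -upstream <= signed_tss_distance(summit, g) < 0
            for g in genes)
        keep.append(inside or upstream_ok)
    return peaks[np.asarray(keep, dtype=bool)].reset_index(drop=True)
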