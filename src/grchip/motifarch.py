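"""Motif architecture of GR binding sites.

Peak windows are scanned with the consensus library (full GRE, GRE
half-site, NF-1 half-site, bHLH element, nGRE with variable spacer) on
both strands.  Per-peak boolean class flags (a full-GRE hit implies the
half-site flag, since the palindrome's 3' half is itself a half-site) are
combined into composite architecture labels; frequencies are stratified by
the presence of a full palindrome and by peak strength (top vs bottom
third of tag density).  The nGRE report asks, for every nGRE-containing
peak, whether a conventional GRE form sits closer to the summit — the
paper-level question of whether apparent nGRE peaks are better explained
by ordinary GRE binding.  A reverse-complement-collapsed k-mer
hypergeometric enrichment serves as a simplified de novo discovery
stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffbind import bh_adjust
from .motifs import MotifModel, MotifHit, default_motif_library, \
    reverse_complement, scan_library

COUNT_HALFWIDTH = 100      # bp, frequency-counting window around the summit
HISTOGRAM_HALFWIDTH = 1000  # bp, positional-histogram window

COMPOSITE_LABELS = ["GRE/H alone", "GRE/H+NF1", "GRE/H+bHLH",
                    "GRE/H+NF1+bHLH", "non-GRE motifs only", "none"]

FLAG_COLUMNS = ["has_full_gre", "has_gre_half", "has_nf1_half",
                "has_bhlh", "has_ngre"]


def peak_window(genome: str, summit: int, halfwidth: int) -> tuple[str, int]:
    """Sequence window around a summit and the summit's window-local index.

    Clipped at chromosome bounds; the local index shifts accordingly.
    """
    lo = max(0, summit - halfwidth)
    hi = min(len(genome), summit + halfwidth + 1)
    return genome[lo:hi], summit - lo


def scan_peaks(peaks: pd.DataFrame, genome: str,
               library: list[MotifModel] | None = None,
               halfwidth: int = COUNT_HALFWIDTH) -> pd.DataFrame:
    """Scan every peak window with the library; hits as a long table.

    Offsets are hit midpoints relative to the summit.
    """
    if library is None:
        library = default_motif_library()
    class_of = {m.name: m.motif_class for m in library}
    rows = []
    for _, r in peaks.iterrows():
        window, local = peak_window(genome, int(r["summit"]), halfwidth)
        for name, hits in scan_library(window, library, summit=local).items():
            for h in hits:
                rows.append(dict(peak_id=r["peak_id"], motif=name,
                                 motif_class=class_of[name],
                                 offset=h.offset, strand=h.strand,
                                 matched=h.matched))
    return pd.DataFrame(rows, columns=["peak_id", "motif", "motif_class",
                                       "offset", "strand", "matched"])


def positional_histogram(hits: pd.DataFrame, bin_size: int = 10,
                         halfwidth: int = HISTOGRAM_HALFWIDTH
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-motif histogram of hit offsets and per-motif median |offset|.

    The median absolute offset quantifies how tightly a motif clusters at
    the binding-site center (GREs tight, NF-1/bHLH broader).
    """
    edges = np.arange(-halfwidth, halfwidth + bin_size, bin_size)
    centers = (edges[:-1] + edges[1:]) // 2
    motifs = sorted(hits["motif"].unique()) if len(hits) else []
    mat = pd.DataFrame(0, index=centers, columns=motifs, dtype=int)
    medians = {}
    for motif in motifs:
        off = hits.loc[hits["motif"] == motif, "offset"].to_numpy()
        off = off[(off >= -halfwidth) & (off < halfwidth)]
        h, _ = np.histogram(off, bins=edges)
        mat[motif] = h
        medians[motif] = float(np.median(np.abs(off))) if len(off) else np.nan
    mat.index.name = "offset_bin"
    return mat, pd.Series(medians, name="median_abs_offset")


def drop_nested_half_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Remove GRE half-site hits nested inside a full-GRE hit of the same
    peak (used for histograms/frequency counting; the architecture flag
    still records the implication)."""
    if not len(hits):
        return hits
    keep = np.ones(len(hits), dtype=bool)
    full = hits[hits["motif_class"] == "full_gre"]
    spans = {pid: [(int(r["offset"]) - 6, int(r["offset"]) + 6)
                   for _, r in g.iterrows()]
             for pid, g in full.groupby("peak_id")}
    for i, (_, r) in enumerate(hits.iterrows()):
        if r["motif_class"] != "gre_half":
            continue
        for lo, hi in spans.get(r["peak_id"], []):
            if lo <= int(r["offset"]) <= hi:
                keep[i] = False
                break
    return hits[keep].reset_index(drop=True)


def classify_architecture(peaks: pd.DataFrame, hits: pd.DataFrame
                          ) -> pd.DataFrame:
    """Per-peak class flags and composite label from counting-window hits."""
    flags = pd.DataFrame(False, index=peaks["peak_id"], columns=FLAG_COLUMNS)
    if len(hits):
        present = (hits.groupby(["peak_id", "motif_class"]).size()
                   .unstack(fill_value=0) > 0)
        for cls in present.columns:
            col = f"has_{cls}"
            if col in flags.columns:
                flags.loc[present.index[present[cls]], col] = True
    flags.loc[flags["has_full_gre"], "has_gre_half"] = True
    flags["composite"] = [_composite_label(r) for _, r in flags.iterrows()]
    return flags.reset_index()


def _composite_label(f: pd.Series) -> str:
    gre = f["has_full_gre"] or f["has_gre_half"]
    nf1 = f["has_nf1_half"]
    bh = f["has_bhlh"]
    if gre:
        if nf1 and bh:
            return "GRE/H+NF1+bHLH"
        if nf1:
            return "GRE/H+NF1"
        if bh:
            return "GRE/H+bHLH"
        return "GRE/H alone"
    if nf1 or bh or f["has_ngre"]:
        return "non-GRE motifs only"
    return "none"


def class_frequencies(arch: pd.DataFrame) -> pd.Series:
    """Fraction of peaks carrying each motif class."""
    return arch[FLAG_COLUMNS].mean()


def partition_by_full_gre(arch: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split peaks by full-GRE presence with per-partition class frequencies."""
    with_full = arch[arch["has_full_gre"]]
    without = arch[~arch["has_full_gre"]]
    freq = pd.DataFrame({
        "with_full_gre": class_frequencies(with_full) if len(with_full)
        else pd.Series(0.0, index=FLAG_COLUMNS),
        "without_full_gre": class_frequencies(without) if len(without)
        else pd.Series(0.0, index=FLAG_COLUMNS),
    })
    return with_full, without, freq


def strength_strata(peaks: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Peak ids of the top and bottom third by descending tag density."""
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks to stratify by thirds")
    ordered = peaks.sort_values(
        by=["density", "chrom", "start"] if "start" in peaks.columns
        else ["density"],
        ascending=[False, True, True] if "start" in peaks.columns
        else [False], kind="mergesort")
    k = len(ordered) // 3
    return (pd.Index(ordered["peak_id"].head(k)),
            pd.Index(ordered["peak_id"].tail(k)))


def stratify_by_strength(peaks: pd.DataFrame, arch: pd.DataFrame
                         ) -> pd.DataFrame:
    """Per-class frequency among top-third vs bottom-third peaks."""
    top, bottom = strength_strata(peaks)
    a = arch.set_index("peak_id")
    return pd.DataFrame({
        "top_third": a.loc[top, FLAG_COLUMNS].mean(),
        "bottom_third": a.loc[bottom, FLAG_COLUMNS].mean(),
    })


def composite_by_strength(peaks: pd.DataFrame, arch: pd.DataFrame
                          ) -> pd.DataFrame:
    """Composite-label distribution per strength stratum (columns sum to 1)."""
    top, bottom = strength_strata(peaks)
    a = arch.set_index("peak_id")
    out = {}
    for name, idx in (("top_third", top), ("bottom_third", bottom)):
        counts = a.loc[idx, "composite"].value_counts(normalize=True)
        out[name] = counts.reindex(COMPOSITE_LABELS, fill_value=0.0)
    return pd.DataFrame(out)


GRE_CLASSES = ("full_gre", "gre_half")


def ngre_analysis(hits: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Centrality report for nGRE-containing peaks.

    Per peak with >=1 nGRE hit: the innermost nGRE offset, the innermost
    conventional GRE-form offset (if any), and whether a GRE form sits
    closer to the summit.  The summary counts nGRE peaks, those lacking
    any GRE-form hit, mean |offset| per class, and peaks where the nGRE is
    not the most central motif.
    """
    ngre_peaks = hits.loc[hits["motif_class"] == "ngre", "peak_id"].unique()
    rows = []
    for pid in ngre_peaks:
        ph = hits[hits["peak_id"] == pid]
        ngre_min = int(np.abs(
            ph.loc[ph["motif_class"] == "ngre", "offset"]).min())
        gre = ph[ph["motif_class"].isin(GRE_CLASSES)]
        gre_min = int(np.abs(gre["offset"]).min()) if len(gre) else None
        other = ph[ph["motif_class"] != "ngre"]
        other_min = int(np.abs(other["offset"]).min()) if len(other) else None
        rows.append(dict(
            peak_id=pid,
            ngre_min_abs_offset=ngre_min,
            gre_min_abs_offset=gre_min,
            has_gre_form=gre_min is not None,
            gre_closer=(gre_min is not None and gre_min < ngre_min),
            ngre_not_most_central=(other_min is not None
                                   and other_min < ngre_min)))
    report = pd.DataFrame(rows, columns=[
        "peak_id", "ngre_min_abs_offset", "gre_min_abs_offset",
        "has_gre_form", "gre_closer", "ngre_not_most_central"])
    mean_abs = (hits.assign(absoff=hits["offset"].abs())
                .groupby("motif_class")["absoff"].mean().to_dict()
                if len(hits) else {})
    summary = dict(
        n_with_ngre=int(len(report)),
        n_without_gre_form=int((~report["has_gre_form"]).sum())
        if len(report) else 0,
        n_gre_closer=int(report["gre_closer"].sum()) if len(report) else 0,
        n_ngre_not_most_central=int(report["ngre_not_most_central"].sum())
        if len(report) else 0,
        mean_abs_offset_by_class=mean_abs)
    return report, summary


# ---------------------------------------------------------------------------
# k-mer enrichment (simplified de novo discovery stand-in)

def canonical_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (random Eulerian walk)."""
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s[:-1], s[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        tail = edges[a]
        # keep the last edge of the terminal vertex aside to stay Eulerian
        rng.shuffle(tail)
    # walk; thanks to the Eulerian property of the original sequence a
    # simple retry on dead ends suffices for these short windows
    for _ in range(20):
        pools = {a: list(v) for a, v in edges.items()}
        out = [s[0]]
        cur = s[0]
        ok = True
        for _i in range(len(s) - 1):
            pool = pools.get(cur)
            if not pool:
                ok = False
                break
            j = int(rng.integers(len(pool)))
            cur = pool.pop(j)
            out.append(cur)
        if ok:
            return "".join(out)
    return s  # degenerate composition; give up and keep the original


def kmer_enrichment(foreground: list[str],
                    background: list[str] | None = None,
                    widths: tuple[int, ...] = (6, 8, 10, 12, 14, 16),
                    seed: int = 0) -> pd.DataFrame:
    """Ranked reverse-complement-collapsed k-mer enrichment table.

    Counts, per k-mer, the number of foreground vs background sequences
    containing it; the p-value is the hypergeometric upper tail of drawing
    that many carriers among the foreground from the combined pool; BH
    q-values are per width.  Background defaults to one dinucleotide
    shuffle of each foreground sequence.
    """
    if background is None:
        rng = np.random.default_rng(seed)
        background = [dinucleotide_shuffle(s, rng) for s in foreground]
    frames = []
    for k in widths:
        if k > max((len(s) for s in foreground), default=0):
            raise ValueError(f"k={k} exceeds window length")
        fg_counts: dict[str, int] = {}
        bg_counts: dict[str, int] = {}
        for seqs, counts in ((foreground, fg_counts),
                             (background, bg_counts)):
            for s in seqs:
                s = s.upper()
                seen = {canonical_kmer(s[i:i + k])
                        for i in range(len(s) - k + 1)}
                seen = {km for km in seen
                        if set(km) <= set("ACGT")}
                for km in seen:
                    counts[km] = counts.get(km, 0) + 1
        rows = []
        nf, nb = len(foreground), len(background)
        for km, cf in fg_counts.items():
            cb = bg_counts.get(km, 0)
            p = stats.hypergeom.sf(cf - 1, nf + nb, cf + cb, nf)
            rows.append(dict(width=k, kmer=km, fg_peaks=cf, bg_peaks=cb,
                             p_value=float(p)))
        tab = pd.DataFrame(rows)
        if len(tab):
            tab["q_value"] = bh_adjust(tab["p_value"].to_numpy())
            frames.append(tab.sort_values(["p_value", "kmer"]))
    out = (pd.concat(frames, ignore_index=True) if frames else
           pd.DataFrame(columns=["width", "kmer", "fg_peaks", "bg_peaks",
                                 "p_value", "q_value"]))
    return out
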