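"""Hotspot-style replicate-concordant peak calling.

Enrichment is assessed in sliding windows (default 200 bp, step 50 bp)
against an input-normalized local background: the expected window count is
the larger of the local input count scaled by the ChIP/input depth ratio
(local window 25 kb), the genome-average ChIP expectation, and a
pseudocount.  The window p-value is the upper tail of a binomial with the
ChIP library size as the number of trials; Benjamini-Hochberg-significant
windows are merged into peaks.  Peaks called independently in both
replicates are intersected (replicate concordance), ranked by tag density
(maximum 200-bp-window count scaled to tags per 10 million) and the top
20% per group carried forward; the two groups' lists are then pooled with
overlapping positions de-duplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffbind import bh_adjust
from .tagops import DensityTrack, apply_repeat_mask

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "summit",
                "density", "p_value", "q_value"]


@dataclass
class HotspotParams:
    """Window-test parameters; defaults are the pipeline's standard run."""

    window: int = 200          # bp, enrichment test window
    step: int = 50             # bp, window step == density bin size
    local_background: int = 25_000  # bp, input window for local expectation
    q_threshold: float = 0.01
    merge_gap: int = 150       # bp, max gap between significant windows
    pseudocount: float = 1.0


def _window_sums(bins: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of ``w`` consecutive bins (length n - w + 1)."""
    c = np.concatenate([[0], np.cumsum(bins)])
    return c[w:] - c[:-w]


def _centered_sums(bins: np.ndarray, half: int) -> np.ndarray:
    """For each bin i, the sum over bins [i-half, i+half] clipped to bounds."""
    c = np.concatenate([[0], np.cumsum(bins)])
    n = len(bins)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return c[hi] - c[lo]


def call_hotspots(chip: DensityTrack, input_track: DensityTrack,
                  params: HotspotParams | None = None,
                  mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Call enriched windows against the input-normalized local background."""
    if params is None:
        params = HotspotParams()
    if chip.total == 0:
        raise ValueError("empty ChIP track")
    if chip.bin_size != input_track.bin_size:
        raise ValueError("ChIP and input tracks must share binning")
    bs = chip.bin_size
    wbins = max(1, params.window // bs)
    lhalf = max(1, params.local_background // (2 * bs))

    n_genome_bins = sum(len(v) for v in chip.counts.values())
    genome_avg = chip.total * wbins / n_genome_bins

    depth_ratio = (chip.total / input_track.total
                   if input_track.total else None)
    if depth_ratio is None:
        log.warning("input track empty; using genome-average background only")

    frames = []
    for chrom, cbins in chip.counts.items():
        k = _window_sums(cbins, wbins)
        nwin = len(k)
        if nwin <= 0:
            continue
        if depth_ratio is not None:
            ibins = input_track.counts[chrom]
            local_in = _centered_sums(ibins, lhalf)
            nlocal = np.minimum(np.arange(len(ibins)) + lhalf + 1,
                                len(ibins)) - np.clip(
                np.arange(len(ibins)) - lhalf, 0, None)
            # expected ChIP count in a w-bin window from the local input rate
            expect_bins = local_in * depth_ratio * wbins / nlocal
            expect = expect_bins[:nwin]
        else:
            expect = np.zeros(nwin)
        expect = np.maximum.reduce([expect,
                                    np.full(nwin, genome_avg),
                                    np.full(nwin, params.pseudocount)])
        pvals = stats.binom.sf(k - 1, chip.total,
                               np.minimum(expect / chip.total, 1.0))
        pvals = np.where(k > 0, pvals, 1.0)
        starts = np.arange(nwin) * bs
        frames.append(pd.DataFrame({
            "chrom": chrom, "wstart": starts,
            "wend": starts + wbins * bs, "count": k, "p_value": pvals}))
    windows = pd.concat(frames, ignore_index=True)
    if mask is not None and len(mask):
        keep = apply_repeat_mask(
            windows.rename(columns={"wstart": "start", "wend": "end"}), mask)
        windows = keep.rename(columns={"start": "wstart", "end": "wend"})
    windows["q_value"] = bh_adjust(windows["p_value"].to_numpy())
    sig = windows[windows["q_value"] < params.q_threshold]
    return _merge_windows(sig, chip, params)


def _merge_windows(sig: pd.DataFrame, chip: DensityTrack,
                   params: HotspotParams) -> pd.DataFrame:
    """Merge significant windows within ``merge_gap`` into peak records."""
    rows = []
    bs = chip.bin_size
    norm = chip.norm_factor
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("wstart")
        ws = grp["wstart"].to_numpy()
        we = grp["wend"].to_numpy()
        kk = grp["count"].to_numpy()
        pp = grp["p_value"].to_numpy()
        qq = grp["q_value"].to_numpy()
        new_block = np.concatenate([[True], ws[1:] > we[:-1] + params.merge_gap])
        block = np.cumsum(new_block) - 1
        for b in range(block[-1] + 1):
            m = block == b
            start = int(ws[m][0])
            end = int(we[m][-1])
            cbins = chip.counts[chrom]
            b0, b1 = start // bs, min(end // bs, len(cbins))
            local = cbins[b0:b1]
            summit_bin = b0 + int(np.argmax(local))  # leftmost max bin
            rows.append(dict(
                chrom=chrom, start=start, end=end,
                summit=summit_bin * bs + bs // 2,
                density=float(kk[m].max()) * norm,
                p_value=float(pp[m].min()), q_value=float(qq[m].min())))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS[1:])
    peaks.insert(0, "peak_id",
                 [f"peak{i:05d}" for i in range(len(peaks))])
    return peaks


def concordant_peaks(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Regions where both replicates called a peak (>=1 bp overlap).

    Overlapping pairs are unioned; chained overlaps collapse into one
    record.  Density is the mean of the two replicates' best-window
    densities; the summit comes from the denser replicate's peak.
    """
    rows = []
    for chrom in sorted(set(rep1["chrom"]) & set(rep2["chrom"])):
        a = rep1[rep1["chrom"] == chrom].sort_values("start")
        b = rep2[rep2["chrom"] == chrom].sort_values("start")
        events = []
        for df, tag in ((a, 1), (b, 2)):
            for _, r in df.iterrows():
                events.append((int(r["start"]), int(r["end"]), tag, r))
        events.sort(key=lambda t: t[0])
        # sweep: cluster intervals whose union is contiguous, then require
        # that a cluster contain members of both replicates
        cluster: list = []
        cend = -1
        for ev in events + [(np.inf, np.inf, 0, None)]:
            if cluster and ev[0] >= cend:
                rows.extend(_emit_concordant(chrom, cluster))
                cluster = []
                cend = -1
            if ev[3] is not None:
                cluster.append(ev)
                cend = max(cend, ev[1])
    out = pd.DataFrame(rows, columns=PEAK_COLUMNS[1:])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "peak_id", [f"cpeak{i:05d}" for i in range(len(out))])
    return out


def _emit_concordant(chrom: str, cluster: list) -> list[dict]:
    """Emit union records for clusters containing both replicates, built
    from the actually-overlapping pairs within the cluster."""
    pairs = []
    for s1, e1, t1, r1 in cluster:
        if t1 != 1:
            continue
        for s2, e2, t2, r2 in cluster:
            if t2 != 2 or s2 >= e1 or s1 >= e2:
                continue
            pairs.append((min(s1, s2), max(e1, e2), r1, r2))
    if not pairs:
        return []
    # merge overlapping union intervals
    pairs.sort(key=lambda t: t[0])
    merged: list[list] = []
    for s, e, r1, r2 in pairs:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].append(r1)
            merged[-1][3].append(r2)
        else:
            merged.append([s, e, [r1], [r2]])
    out = []
    for s, e, rs1, rs2 in merged:
        d1 = max(float(r["density"]) for r in rs1)
        d2 = max(float(r["density"]) for r in rs2)
        best = max(rs1 + rs2, key=lambda r: float(r["density"]))
        out.append(dict(chrom=chrom, start=int(s), end=int(e),
                        summit=int(best["summit"]),
                        density=(d1 + d2) / 2.0,
                        p_value=min(float(r["p_value"]) for r in rs1 + rs2),
                        q_value=min(float(r["q_value"]) for r in rs1 + rs2)))
    return out


def rank_top_fraction(peaks: pd.DataFrame, fraction: float = 0.2
                      ) -> pd.DataFrame:
    """Top fraction of peaks by descending density, with rank assigned.

    Ties at the cut are broken by ascending p-value, then coordinate.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if len(peaks) == 0:
        out = peaks.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    ordered = peaks.sort_values(
        by=["density", "p_value", "chrom", "start"],
        ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    n_keep = int(np.ceil(fraction * len(ordered)))
    out = ordered.head(n_keep).copy()
    out["rank"] = np.arange(1, n_keep + 1)
    return out


def pool_nonduplicated(group_a: pd.DataFrame, group_b: pd.DataFrame
                       ) -> pd.DataFrame:
    """Pool two groups' peak lists, merging overlapping positions.

    Overlaps merge to union coordinates with the max density and a
    provenance flag (A/B/both); non-overlapping records pass through.
    """
    a = group_a.copy()
    a["source"] = "A"
    b = group_b.copy()
    b["source"] = "B"
    allp = pd.concat([a, b], ignore_index=True)
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            if cur is None or int(r["start"]) >= cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = dict(chrom=chrom, start=int(r["start"]),
                           end=int(r["end"]), summit=int(r["summit"]),
                           density=float(r["density"]),
                           p_value=float(r["p_value"]),
                           q_value=float(r["q_value"]),
                           sources={r["source"]})
            else:
                cur["end"] = max(cur["end"], int(r["end"]))
                if float(r["density"]) > cur["density"]:
                    cur["density"] = float(r["density"])
                    cur["summit"] = int(r["summit"])
                cur["p_value"] = min(cur["p_value"], float(r["p_value"]))
                cur["q_value"] = min(cur["q_value"], float(r["q_value"]))
                cur["sources"].add(r["source"])
        if cur is not None:
            rows.append(cur)
    for r in rows:
        src = r.pop("sources")
        r["provenance"] = "both" if len(src) == 2 else src.pop()
    out = pd.DataFrame(rows, columns=PEAK_COLUMNS[1:] + ["provenance"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "peak_id", [f"pool{i:05d}" for i in range(len(out))])
    return out


def density_heat_matrix(peaks: pd.DataFrame, tags: pd.DataFrame,
                        chrom_sizes: dict[str, int], flank: int = 3000,
                        bin_size: int = 50) -> tuple[pd.DataFrame, np.ndarray]:
    """Depth-normalized tag density around each summit, rows ranked by density.

    Columns are ``bin_size`` bins over [summit - flank, summit + flank);
    rows follow descending peak density (heat-map row order).  Summits too
    close to a chromosome edge are zero-padded.
    """
    ordered = peaks.sort_values(
        by=["density", "p_value", "chrom", "start"],
        ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    nbins = 2 * flank // bin_size
    mat = np.zeros((len(ordered), nbins))
    norm = 1e7 / len(tags) if len(tags) else 0.0
    mids_by_chrom = {
        c: np.sort((g["start"].to_numpy() + g["end"].to_numpy()) // 2)
        for c, g in tags.groupby("chrom", sort=False)}
    for i, r in ordered.iterrows():
        mids = mids_by_chrom.get(r["chrom"])
        if mids is None:
            continue
        lo = int(r["summit"]) - flank
        hi = int(r["summit"]) + flank
        if lo < 0 or hi > chrom_sizes[r["chrom"]]:
            log.info("summit %s:%d within flank of edge; zero-padded",
                     r["chrom"], int(r["summit"]))
        sel = mids[np.searchsorted(mids, lo):np.searchsorted(mids, hi)]
        if len(sel):
            idx = (sel - lo) // bin_size
            np.add.at(mat[i], idx, 1)
    return ordered, mat * norm
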