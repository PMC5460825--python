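"""Tag loading and preprocessing.

Sequenced tags are extended 150 bp in their 3' direction to approximate
the sonicated fragment, duplicates (same 5' position and strand) are
removed to eliminate PCR bias, and densities are expressed per 10 million
total tags.  All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TAG_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def five_prime_positions(tags: pd.DataFrame) -> np.ndarray:
    """Per-tag 5' coordinate: start on +, end - 1 on -."""
    minus = tags["strand"].to_numpy() == "-"
    return np.where(minus, tags["end"].to_numpy() - 1,
                    tags["start"].to_numpy())


def extend_tags(reads: pd.DataFrame, chrom_sizes: dict[str, int],
                length: int = 150) -> pd.DataFrame:
    """Extend reads to ``length`` bp in their 3' direction.

    Plus-strand reads become [start, start+length); minus-strand reads
    [end-length, end); both clipped to chromosome bounds.  Records without
    a +/- strand are dropped with a warning.
    """
    strand = reads["strand"].astype(str)
    valid = strand.isin(["+", "-"])
    if not valid.all():
        log.warning("dropping %d strand-less records", int((~valid).sum()))
        reads = reads[valid]
        strand = strand[valid]
    minus = (strand == "-").to_numpy()
    start = reads["start"].to_numpy().copy()
    end = reads["end"].to_numpy().copy()
    new_start = np.where(minus, end - length, start)
    new_end = np.where(minus, end, start + length)
    sizes = reads["chrom"].map(chrom_sizes).to_numpy()
    new_start = np.clip(new_start, 0, None)
    new_end = np.minimum(new_end, sizes)
    out = reads.copy()
    out["start"] = new_start
    out["end"] = new_end
    return out.reset_index(drop=True)


def deduplicate_tags(tags: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one tag per (chrom, 5' position, strand).

    Applied before extension so the key is the original mapped position;
    the first occurrence is kept and the removed count logged.
    """
    key = pd.DataFrame({
        "chrom": tags["chrom"].to_numpy(),
        "p5": five_prime_positions(tags),
        "strand": tags["strand"].to_numpy(),
    })
    keep = ~key.duplicated(keep="first").to_numpy()
    removed = int((~keep).sum())
    if removed:
        log.info("deduplication removed %d of %d tags", removed, len(tags))
    return tags[keep].reset_index(drop=True)


def depth_normalization_factor(total_tags: int) -> float:
    """Tags-per-10-million scale factor: 1e7 / total."""
    if total_tags <= 0:
        raise ValueError("total tag count must be positive")
    return 1e7 / total_tags


@dataclass
class DensityTrack:
    """Binned midpoint-count track with a tags-per-10M normalization factor."""

    bin_size: int
    counts: dict[str, np.ndarray]
    total: int
    norm_factor: float

    def chrom_bins(self, chrom: str) -> int:
        return len(self.counts[chrom])


def density_track(tags: pd.DataFrame, chrom_sizes: dict[str, int],
                  bin_size: int = 50) -> DensityTrack:
    """Bin extended tags by midpoint: each tag increments exactly one bin.

    Tags reaching past a chromosome end are clipped with a log note.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    counts = {c: np.zeros(int(np.ceil(size / bin_size)), dtype=np.int64)
              for c, size in chrom_sizes.items()}
    total = 0
    for chrom, grp in tags.groupby("chrom", sort=False):
        size = chrom_sizes[chrom]
        mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
        over = int((mid >= size).sum())
        if over:
            log.info("%d tag midpoints beyond %s end; clipped", over, chrom)
        mid = np.clip(mid, 0, size - 1)
        np.add.at(counts[chrom], mid // bin_size, 1)
        total += len(grp)
    return DensityTrack(bin_size=bin_size, counts=counts, total=total,
                        norm_factor=depth_normalization_factor(total)
                        if total else 0.0)


def _overlaps_any(chrom: np.ndarray, start: np.ndarray, end: np.ndarray,
                  mask: pd.DataFrame) -> np.ndarray:
    """Boolean: does each half-open interval overlap any mask interval by >=1 bp."""
    out = np.zeros(len(start), dtype=bool)
    for c, mgrp in mask.groupby("chrom", sort=False):
        sel = chrom == c
        if not sel.any():
            continue
        ms = mgrp["start"].to_numpy()
        me = mgrp["end"].to_numpy()
        order = np.argsort(ms)
        ms, me = ms[order], me[order]
        # merge mask intervals so a binary search suffices
        merged_s, merged_e = [], []
        for s, e in zip(ms, me):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        s_q = start[sel]
        e_q = end[sel]
        j = np.searchsorted(ms, e_q, side="left") - 1
        hit = (j >= 0) & (me[np.clip(j, 0, None)] > s_q)
        # also catch a mask starting inside the query
        k = np.searchsorted(ms, s_q, side="left")
        hit |= (k < len(ms)) & (ms[np.clip(k, 0, len(ms) - 1)] < e_q)
        out[sel] = hit
    return out


def apply_repeat_mask(intervals: pd.DataFrame,
                      mask: pd.DataFrame | None) -> pd.DataFrame:
    """Drop intervals overlapping a masked region by at least 1 bp."""
    if mask is None or len(mask) == 0:
        return intervals.reset_index(drop=True)
    bad = _overlaps_any(intervals["chrom"].to_numpy(),
                        intervals["start"].to_numpy(),
                        intervals["end"].to_numpy(), mask)
    if bad.any():
        log.info("repeat mask removed %d of %d intervals",
                 int(bad.sum()), len(intervals))
    return intervals[~bad].reset_index(drop=True)


def mask_sequence(seq: str, mask: pd.DataFrame, chrom: str) -> str:
    """Lowercase masked spans so the scanner treats them as non-matching."""
    buf = bytearray(seq.encode("ascii"))
    for _, row in mask[mask["chrom"] == chrom].iterrows():
        s, e = int(row["start"]), int(row["end"])
        buf[s:e] = seq[s:e].lower().encode("ascii")
    return buf.decode("ascii")


def find_simple_repeats(seq: str, chrom: str = "chr1", max_unit: int = 6,
                        min_length: int = 24) -> pd.DataFrame:
    """Tandem-repeat detector for synthetic genomes lacking a mask BED.

    Reports maximal runs where the sequence equals itself shifted by a unit
    of 1..max_unit bp, spanning at least ``min_length`` bp in total.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    spans: list[tuple[int, int]] = []
    for u in range(1, max_unit + 1):
        eq = arr[u:] == arr[:-u]
        if not eq.any():
            continue
        d = np.diff(np.concatenate([[0], eq.view(np.int8), [0]]))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            if (e - s) + u >= min_length:
                spans.append((int(s), int(e) + u))
    if not spans:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    spans.sort()
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return pd.DataFrame([(chrom, s, e) for s, e in merged],
                        columns=["chrom", "start", "end"])
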