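"""File formats: FASTA, BED6 tags/intervals, TSV tables, run metadata.

All interval formats are 0-based half-open.  FASTA round-trips preserve
case (lowercase marks masked bases).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .tagops import TAG_COLUMNS


def parse_fasta(path) -> dict[str, str]:
    """Named sequences from a FASTA file; case preserved."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise ValueError(f"empty FASTA file: {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def parse_bed(path, require_strand: bool = False) -> pd.DataFrame:
    """BED3/BED6 intervals; 0-based half-open; validated per line."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{ln}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise ValueError(f"{path}:{ln}: invalid interval "
                                 f"[{start}, {end})")
            strand = f[5] if len(f) >= 6 else "."
            if require_strand and strand not in "+-":
                raise ValueError(f"{path}:{ln}: strand required (+/-)")
            rows.append((f[0], start, end,
                         f[3] if len(f) >= 4 else f"iv{ln}",
                         f[4] if len(f) >= 5 else 0, strand))
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    """Sorted BED6 output."""
    cols = [c for c in TAG_COLUMNS if c in df.columns]
    out = df[cols].sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tags(path) -> pd.DataFrame:
    """Tag BED6 (strand mandatory)."""
    return parse_bed(path, require_strand=True)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping for provenance metadata."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_metadata(outdir, config: dict, seed: int) -> None:
    from . import __version__
    meta = dict(config_hash=config_hash(config), seed=seed,
                version=__version__, config=config)
    Path(outdir, "run_metadata.json").write_text(
        json.dumps(meta, indent=2, default=str) + "\n")
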