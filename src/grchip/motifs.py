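"""Consensus motif models and a both-strand IUPAC scanner.

The glucocorticoid receptor (GR) binds DNA directly at variants of the
near-palindromic glucocorticoid response element (GRE), ``ACAnnnTGTYCT``,
at single GRE half-sites (``TGTYCT``-like), and — reportedly — at negative
GREs (nGREs), an inverted repeat ``CTCC(N)0-2GGAGA`` with a variable spacer.
Candidate collaborating factors in hippocampus carry an NF-1 half-site
(``TTGGCA``) or a bHLH/E-box element (``CANATGG``, NeuroD1/Olig2-like).

Motifs are represented as IUPAC consensus strings; a gapped consensus
(left half, spacer range, right half) expands to one concrete pattern per
spacer length.  Matching is exact against the consensus: every window whose
bases all fall in the allowed set of the corresponding consensus position is
a hit.  Scanning is implemented over a 4-bit base encoding (A=1, C=2, G=4,
T=8; anything else, including lowercase masked bases, encodes to 0 and can
never match), so degenerate consensus positions become bitmasks and a window
matches iff the AND of sequence code and pattern mask is nonzero at every
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
# complement swaps A<->T (1<->8) and C<->G (2<->4) bit-wise
_COMP_BIT = np.array(
    [((i & 1) * 8) | ((i & 2) * 2) | ((i & 4) >> 1) | ((i & 8) >> 3)
     for i in range(16)],
    dtype=np.uint8,
)

_ENCODE = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BIT.items():
    _ENCODE[ord(_b)] = _v  # uppercase only: lowercase (masked) stays 0

_COMP_CHAR = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case and IUPAC degeneracy."""
    return seq.translate(_COMP_CHAR)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """4-bit encode a sequence; masked/unknown bases encode to 0."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pattern_mask(pattern: str) -> np.ndarray:
    """Per-position allowed-base bitmasks for an IUPAC consensus."""
    masks = np.empty(len(pattern), dtype=np.uint8)
    for i, ch in enumerate(pattern.upper()):
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in pattern {pattern!r}")
        masks[i] = sum(_BASE_BIT[b] for b in IUPAC[ch])
    return masks


@dataclass(frozen=True)
class MotifModel:
    """A compiled consensus motif.

    ``patterns`` holds one concrete IUPAC string per spacer length for
    gapped consensi, a single string otherwise.  ``motif_class`` groups
    motifs into the architecture classes used downstream.
    """

    name: str
    patterns: tuple[str, ...]
    motif_class: str = "custom"
    _masks: tuple = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        masks = tuple(pattern_mask(p) for p in self.patterns)
        object.__setattr__(self, "_masks", masks)

    @property
    def max_length(self) -> int:
        return max(len(p) for p in self.patterns)


MOTIF_CLASSES = ("full_gre", "gre_half", "nf1_half", "bhlh", "ngre")


def compile_motif(name, spec, motif_class="custom") -> MotifModel:
    """Compile an IUPAC consensus or gapped (left, (lo, hi), right) spec.

    A gapped spec expands to one pattern per spacer length, e.g. the nGRE
    consensus CTCC(N)0-2GGAGA becomes CTCCGGAGA, CTCCNGGAGA, CTCCNNGGAGA.
    """
    if isinstance(spec, str):
        patterns = (spec.upper(),)
    else:
        left, (lo, hi), right = spec
        if lo < 0 or lo > hi:
            raise ValueError(f"invalid spacer bounds {lo}..{hi}")
        patterns = tuple(f"{left.upper()}{'N' * k}{right.upper()}"
                         for k in range(lo, hi + 1))
    return MotifModel(name=name, patterns=patterns, motif_class=motif_class)


def default_motif_library() -> list[MotifModel]:
    """The standard five-motif library used throughout the analysis.

    Full GRE and nGRE are the published consensus strings.  The GRE
    half-site is the 3' half of the palindrome; the NF-1 half-site is the
    TTGGC-containing half of the canonical full site TTGGC(N5)GCCAA; the
    bHLH element is the NeuroD1/Olig2-like E-box variant.
    """
    return [
        compile_motif("full_gre", "ACANNNTGTYCT", "full_gre"),
        compile_motif("gre_half", "TGTYCT", "gre_half"),
        compile_motif("nf1_half", "TTGGCA", "nf1_half"),
        compile_motif("bhlh", "CANATGG", "bhlh"),
        compile_motif("ngre", ("CTCC", (0, 2), "GGAGA"), "ngre"),
    ]


def _match_positions(codes: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Start positions where every window base is allowed by the masks."""
    L = len(masks)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ok = (codes[:n] & masks[0]) > 0
    for j in range(1, L):
        ok &= (codes[j:j + n] & masks[j]) > 0
    return np.nonzero(ok)[0].astype(np.int64)


@dataclass(frozen=True)
class MotifHit:
    """One scanner hit, located relative to the scanned window's summit."""

    motif: str
    start: int          # window-local start of the matched interval
    end: int            # half-open
    strand: str
    offset: int         # hit midpoint minus summit position
    matched: str


def scan_sequence(seq: str, model: MotifModel, summit: int = 0) -> list[MotifHit]:
    """Scan one sequence window on both strands for a motif model.

    Coordinates are window-local; ``summit`` is the window-local position of
    the peak summit and offsets are reported relative to it.  A hit whose
    exact reverse complement matches the same interval (palindromic site) is
    reported once, on the + strand.  Lowercase (masked) bases never match.
    """
    codes = encode_sequence(seq)
    hits: list[MotifHit] = []
    for pat, masks in zip(model.patterns, model._masks):
        L = len(masks)
        fwd = _match_positions(codes, masks)
        rev = _match_positions(codes, _COMP_BIT[masks][::-1])
        rev = np.setdiff1d(rev, fwd)  # palindrome dedup: keep + strand
        for strand, positions in (("+", fwd), ("-", rev)):
            for s in positions:
                s = int(s)
                hits.append(MotifHit(
                    motif=model.name,
                    start=s, end=s + L, strand=strand,
                    offset=s + L // 2 - summit,
                    matched=seq[s:s + L],
                ))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def scan_library(seq: str, library: list[MotifModel], summit: int = 0
                 ) -> dict[str, list[MotifHit]]:
    """Scan one window with every motif in a library."""
    return {m.name: scan_sequence(seq, m, summit) for m in library}


def count_matches(seq: str, model: MotifModel) -> int:
    """Number of hits (after palindrome dedup) in a sequence."""
    return len(scan_sequence(seq, model))


def realize_motif(model: MotifModel, rng: np.random.Generator) -> str:
    """Draw one concrete DNA realization of a consensus uniformly.

    For gapped models the spacer length is drawn uniformly first; each
    degenerate position is then realized uniformly over its allowed bases.
    """
    pat = model.patterns[rng.integers(len(model.patterns))]
    return "".join(IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in pat)
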