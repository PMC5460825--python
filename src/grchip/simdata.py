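"""Synthetic GR ChIP-seq data with planted ground truth.

Every downstream stage (peak calling, differential binding, annotation,
motif architecture) is exercised on data from this module: a motif-free
background genome, binding sites planted with known motif composition,
and simulated ChIP/input tags for two conditions x two replicates with no
true between-condition difference by default (the experiment's null).

Three guarantees make the planted composition exactly recoverable:

* the background contains zero matches to any library motif on either
  strand (rejection sampling), so every scanner hit at a site is planted;
* per-class planting uses exact counts, so class fractions over sites are
  configuration values, not random variables;
* each planted site is verified by scanning and replanted if embedding
  created an unintended motif at a junction, or destroyed an intended one.

Site enrichment is composition-weighted: a site's expected ChIP tag count
is proportional to 1 + the summed weights of its planted motif instances,
so composite sites (GRE plus NF-1/bHLH) are systematically stronger than
isolated GRE or half-site peaks — the generative assumption behind the
strength-stratification analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .motifs import (MotifModel, default_motif_library, realize_motif,
                     reverse_complement, scan_library, encode_sequence,
                     _match_positions, _COMP_BIT)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BIT_OF_IDX = np.array([1, 2, 4, 8], dtype=np.uint8)  # A,C,G,T


@dataclass
class ClassConfig:
    """Planting parameters for one motif class."""

    count: int | None = None      # exact number of sites carrying the class
    rate: float | None = None     # alternative: fraction of sites
    offset_sd: float = 30.0       # bp spread of instance midpoints around center
    weight: float = 0.5           # contribution to site enrichment weight

    def resolve_count(self, n_sites: int) -> int:
        if self.count is not None:
            if not 0 <= self.count <= n_sites:
                raise ValueError(f"class count {self.count} exceeds n_sites")
            return int(self.count)
        if self.rate is None:
            return 0
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"class rate {self.rate} outside [0, 1]")
        return int(round(self.rate * n_sites))

    def validate(self):
        if self.offset_sd <= 0:
            raise ValueError("offset_sd must be > 0")
        if self.weight < 0:
            raise ValueError("class weight must be >= 0")


@dataclass
class CompositionConfig:
    """How many sites to plant and what motif classes they carry.

    ``ngre_with_gre`` fixes how many nGRE-carrying sites also carry a GRE
    form (full palindrome or half-site); the remainder are planted into
    sites with no GRE form at all.
    """

    n_sites: int
    peak_halfwidth: int = 100
    classes: dict[str, ClassConfig] = field(default_factory=dict)
    ngre_with_gre: int | None = None

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.peak_halfwidth < 20:
            raise ValueError("peak_halfwidth must be >= 20")
        for cc in self.classes.values():
            cc.validate()

    def resolved_counts(self) -> dict[str, int]:
        return {name: cc.resolve_count(self.n_sites)
                for name, cc in self.classes.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "CompositionConfig":
        classes = {name: ClassConfig(**spec)
                   for name, spec in d.get("classes", {}).items()}
        return cls(n_sites=int(d["n_sites"]),
                   peak_halfwidth=int(d.get("peak_halfwidth", 100)),
                   classes=classes,
                   ngre_with_gre=d.get("ngre_with_gre"))


def default_composition() -> CompositionConfig:
    """The repository's default composition (shipped as package data)."""
    text = resources.files("grchip.data").joinpath(
        "default_composition.yaml").read_text()
    return CompositionConfig.from_dict(yaml.safe_load(text))


@dataclass
class ReadSimParams:
    """Tag-simulation parameters.

    ``depth_per_unit`` is the expected number of ChIP fragments a site of
    enrichment weight 1 contributes per sample; fragment centers scatter
    around the site center with ``frag_dispersion`` (bp, normal); tag 5'
    ends sit ``strand_shift`` bp outside the fragment center on the strand
    facing it.  ``condition_effect`` multiplies site depth in the second
    condition; 1.0 is the null design (no true between-group difference).
    """

    depth_per_unit: float = 50.0
    frag_dispersion: float = 40.0
    strand_shift: int = 75
    read_length: int = 36
    background_rate: float = 0.035   # tags per bp, ChIP background
    input_rate: float = 0.105        # tags per bp, input samples
    condition_effect: float = 1.0

    def validate(self):
        for name in ("depth_per_unit", "frag_dispersion", "strand_shift",
                     "read_length", "background_rate", "input_rate",
                     "condition_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# background genome

def _find_any_motif_spans(codes_bits: np.ndarray,
                          library: list[MotifModel]) -> list[tuple[int, int, str]]:
    """(start, end, motif name) spans matching any library pattern, both strands."""
    spans = []
    for model in library:
        for masks in model._masks:
            L = len(masks)
            for m in (masks, _COMP_BIT[masks][::-1]):
                for s in _match_positions(codes_bits, m):
                    spans.append((int(s), int(s) + L, model.name))
    return spans


def generate_background_genome(length: int, gc: float,
                               motif_library: list[MotifModel] | None = None,
                               seed: int = 0, max_iter: int = 500) -> str:
    """Random sequence of given GC content with zero library-motif matches.

    Rejection sampling: draw the whole sequence, locate every motif match
    on either strand, redraw exactly the matched spans, and iterate until
    no window matches.  Deterministic for a fixed seed.
    """
    if length < 10_000:
        raise ValueError("length must be >= 10 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if motif_library is None:
        motif_library = default_motif_library()
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p).astype(np.int8)
    for _ in range(max_iter):
        spans = _find_any_motif_spans(_BIT_OF_IDX[idx], motif_library)
        if not spans:
            return _BASES[idx].tobytes().decode("ascii")
        redraw = np.zeros(length, dtype=bool)
        for s, e, _ in spans:
            redraw[s:e] = True
        k = int(redraw.sum())
        idx[redraw] = rng.choice(4, size=k, p=p).astype(np.int8)
    offender = spans[0][2]
    raise RuntimeError(
        f"rejection sampling failed after {max_iter} iterations; "
        f"motif {offender!r} could not be excluded")


# ---------------------------------------------------------------------------
# site planting

def _place_centers(length: int, n: int, margin: int, spacing: int,
                   rng: np.random.Generator) -> np.ndarray:
    usable = length - 2 * margin - (n - 1) * spacing
    if usable < 0:
        raise ValueError(
            f"genome of {length} bp too small for {n} sites at "
            f"spacing {spacing} (margin {margin})")
    jitter = np.sort(rng.random(n)) * usable
    return (margin + jitter + np.arange(n) * spacing).astype(np.int64)


def _choose(rng, pool: np.ndarray, k: int, what: str) -> np.ndarray:
    if k > len(pool):
        raise ValueError(f"cannot place {k} {what} sites in pool of {len(pool)}")
    return rng.choice(pool, size=k, replace=False)


def _assign_classes(cfg: CompositionConfig, rng) -> dict[str, np.ndarray]:
    """Site indices carrying each class, honoring exact counts and the
    full-GRE/half-site partition plus the nGRE co-occurrence constraint."""
    n = cfg.n_sites
    counts = cfg.resolved_counts()
    allidx = np.arange(n)
    assign: dict[str, np.ndarray] = {}

    full = _choose(rng, allidx, counts.get("full_gre", 0), "full_gre")
    assign["full_gre"] = full
    not_full = np.setdiff1d(allidx, full)
    half = _choose(rng, not_full, counts.get("gre_half", 0), "gre_half")
    assign["gre_half"] = half
    gre_any = np.concatenate([full, half])
    no_gre = np.setdiff1d(allidx, gre_any)

    for name in ("nf1_half", "bhlh"):
        assign[name] = _choose(rng, allidx, counts.get(name, 0), name)

    n_ngre = counts.get("ngre", 0)
    if n_ngre:
        with_gre = cfg.ngre_with_gre
        if with_gre is None:
            with_gre = n_ngre
        if with_gre > n_ngre:
            raise ValueError("ngre_with_gre exceeds ngre count")
        a = _choose(rng, gre_any, with_gre, "ngre-with-GRE")
        b = _choose(rng, no_gre, n_ngre - with_gre, "ngre-without-GRE")
        assign["ngre"] = np.concatenate([a, b])
    else:
        assign["ngre"] = np.empty(0, dtype=np.int64)

    for name in counts:
        if name not in assign:  # custom classes: unconstrained
            assign[name] = _choose(rng, allidx, counts[name], name)
    return assign


def _intended_flags(planted: set[str]) -> set[str]:
    flags = set(planted)
    if "full_gre" in flags:
        flags.add("gre_half")  # the palindrome's 3' half is a half-site
    return flags


def _plant_one_site(genome: bytearray, center: int, classes: list[str],
                    cfg: CompositionConfig, library_by_class: dict,
                    rng, max_attempts: int = 200) -> list[dict]:
    """Embed one instance per class at the site; verify by scanning; retry
    until the scanned flag set equals the intended one."""
    hw = cfg.peak_halfwidth
    maxlen = max(m.max_length for m in library_by_class.values())
    library = list(library_by_class.values())
    lo, hi = center - hw - maxlen, center + hw + maxlen + 1
    original = bytes(genome[lo:hi])
    intended = _intended_flags(set(classes))

    for _ in range(max_attempts):
        placed: list[dict] = []
        occupied: list[tuple[int, int]] = []
        ok = True
        for cls in classes:
            model = library_by_class[cls]
            text = realize_motif(model, rng)
            L = len(text)
            sd = cfg.classes[cls].offset_sd
            for _try in range(50):
                off = int(round(rng.normal(0.0, sd)))
                start = center + off - L // 2
                if start < center - hw or start + L > center + hw + 1:
                    continue
                if any(start < e and start + L > s for s, e in occupied):
                    continue
                break
            else:
                ok = False
                break
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = text if strand == "+" else reverse_complement(text)
            genome[start:start + L] = embedded.encode("ascii")
            occupied.append((start, start + L))
            placed.append(dict(motif_class=cls, offset=off, strand=strand,
                               sequence=text, start=start))
        if ok:
            window = genome[lo:hi].decode("ascii")
            hits = scan_library(window, library)
            found = {m.motif_class for m in library if hits[m.name]}
            if found == intended:
                return placed
        genome[lo:hi] = original
    raise RuntimeError(
        f"could not plant classes {sorted(intended)} at {center} "
        f"after {max_attempts} attempts")


def plant_sites(genome: str, config: CompositionConfig, seed: int = 0,
                chrom: str = "chr1",
                library: list[MotifModel] | None = None,
                min_spacing: int | None = None,
                ) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Plant binding sites into a motif-free background.

    Returns the modified genome, a per-site truth table (flags, enrichment
    weight) and a per-instance table.  Site centers are spaced at least
    ``min_spacing`` apart (default keeps scan windows plus the longest
    motif disjoint) and away from chromosome ends.
    """
    if library is None:
        library = default_motif_library()
    lib_by_class = {m.motif_class: m for m in library}
    maxlen = max(m.max_length for m in library)
    hw = config.peak_halfwidth
    if min_spacing is None:
        min_spacing = 2 * (hw + maxlen)
    if min_spacing < 2 * hw:
        raise ValueError("min_spacing must be >= 2 * peak_halfwidth")
    rng = np.random.default_rng(seed)
    centers = _place_centers(len(genome), config.n_sites,
                             margin=2 * (hw + maxlen),
                             spacing=min_spacing, rng=rng)
    assign = _assign_classes(config, rng)
    site_classes: list[list[str]] = [[] for _ in range(config.n_sites)]
    for cls, idxs in assign.items():
        if cls not in lib_by_class and len(idxs):
            raise ValueError(f"class {cls!r} has no motif in the library")
        for i in idxs:
            site_classes[int(i)].append(cls)

    buf = bytearray(genome.encode("ascii"))
    site_rows, inst_rows = [], []
    for i, center in enumerate(centers):
        classes = sorted(site_classes[i])
        placed = _plant_one_site(buf, int(center), classes, config,
                                 lib_by_class, rng)
        weight = 1.0 + sum(config.classes[p["motif_class"]].weight
                           for p in placed)
        flags = _intended_flags(set(classes))
        site_rows.append(dict(
            site_id=f"site{i:05d}", chrom=chrom, center=int(center),
            enrichment_weight=weight,
            **{f"has_{c}": (c in flags)
               for c in ("full_gre", "gre_half", "nf1_half", "bhlh", "ngre")}))
        for p in placed:
            inst_rows.append(dict(site_id=f"site{i:05d}", chrom=chrom, **p))
    sites = pd.DataFrame(site_rows)
    instances = pd.DataFrame(
        inst_rows, columns=["site_id", "chrom", "motif_class", "offset",
                            "strand", "sequence", "start"])
    return buf.decode("ascii"), sites, instances


# ---------------------------------------------------------------------------
# tag simulation

def _sample_names(n_conditions: int, n_replicates: int) -> list[str]:
    return [f"{kind}_c{c}_r{r}"
            for kind in ("chip", "input")
            for c in range(1, n_conditions + 1)
            for r in range(1, n_replicates + 1)]


def simulate_tags(genome_length: int, truth: pd.DataFrame,
                  params: ReadSimParams, n_replicates: int = 2,
                  n_conditions: int = 2, seed: int = 0,
                  chrom: str = "chr1") -> dict[str, pd.DataFrame]:
    """Simulate sorted BED6-style read tables for every ChIP/input sample.

    Per site and ChIP sample, the fragment count is Poisson with mean
    ``depth_per_unit * enrichment_weight * condition multiplier``; fragment
    centers are normal around the site center; the tag 5' end is offset
    ``strand_shift`` bp from the fragment center on the side matching its
    strand.  Background tags are uniform; input samples are background only.
    """
    params.validate()
    if params.depth_per_unit * len(truth) == 0 and params.background_rate == 0:
        raise ValueError("zero sequencing depth requested")
    ss = np.random.SeedSequence(seed)
    names = _sample_names(n_conditions, n_replicates)
    children = dict(zip(names, ss.spawn(len(names))))
    centers = truth["center"].to_numpy()
    weights = truth["enrichment_weight"].to_numpy(dtype=float)
    out: dict[str, pd.DataFrame] = {}
    rl = params.read_length
    for name in names:
        rng = np.random.default_rng(children[name])
        kind, cond = name.split("_")[0], int(name.split("_")[1][1:])
        if kind == "chip":
            mult = params.condition_effect if cond == 2 else 1.0
            lam = params.depth_per_unit * weights * mult
            counts = rng.poisson(lam)
            frag_centers = (np.repeat(centers, counts)
                            + rng.normal(0.0, params.frag_dispersion,
                                         counts.sum()))
            n_bg = rng.poisson(params.background_rate * genome_length)
            bg = rng.uniform(0, genome_length, n_bg)
            pos = np.concatenate([frag_centers, bg])
        else:
            n_bg = rng.poisson(params.input_rate * genome_length)
            pos = rng.uniform(0, genome_length, n_bg)
        strand_minus = rng.random(len(pos)) < 0.5
        five_prime = np.where(strand_minus,
                              np.rint(pos) + params.strand_shift,
                              np.rint(pos) - params.strand_shift).astype(np.int64)
        start = np.where(strand_minus, five_prime - rl + 1, five_prime)
        end = start + rl
        clipped = int((start < 0).sum() + (end > genome_length).sum())
        if clipped:
            log.info("%s: clipped %d tags at chromosome bounds", name, clipped)
        start = np.clip(start, 0, genome_length - 1)
        end = np.clip(end, start + 1, genome_length)
        df = pd.DataFrame({
            "chrom": chrom, "start": start, "end": end,
            "name": [f"{name}.{i}" for i in range(len(start))],
            "score": 0,
            "strand": np.where(strand_minus, "-", "+"),
        }).sort_values(["chrom", "start", "end"], kind="mergesort",
                       ignore_index=True)
        out[name] = df
    return out


# ---------------------------------------------------------------------------
# gene models

def write_gene_models(genome_length: int, n_genes: int, seed: int = 0,
                      chrom: str = "chr1") -> pd.DataFrame:
    """Non-overlapping synthetic gene models in refFlat-like form.

    One gene per equal-width slot; exon bounds coincide with transcript
    bounds so the first and last exons double as UTR segments downstream.
    Exon start/end lists are comma-joined strings, as in refFlat tables.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    slot = genome_length // n_genes
    if slot < 4000:
        raise ValueError("genome too small for requested n_genes")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        glen = int(rng.integers(2000, min(20000, slot - 1000)))
        tx_start = i * slot + int(rng.integers(0, slot - glen))
        n_ex = int(rng.integers(2, 9))
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [glen]])
        ex_starts = tx_start + bounds[0::2]
        ex_ends = tx_start + bounds[1::2]
        rows.append(dict(
            gene=f"gene{i + 1:04d}", chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            txStart=tx_start, txEnd=tx_start + glen,
            exonStarts=",".join(map(str, ex_starts)),
            exonEnds=",".join(map(str, ex_ends))))
    return pd.DataFrame(rows)
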