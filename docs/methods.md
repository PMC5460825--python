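# Methods

This note documents the models, parameter choices and numerical details
behind `grchip`, and what the synthetic validation does and does not
demonstrate about real data.

## Tag model and preprocessing

Input is aligned single-end tags (BED6, 0-based half-open everywhere;
conversions happen only in parsers). Deduplication keeps the first tag
per (chromosome, 5' coordinate, strand) — the key is applied *before*
extension so it reflects the original mapped position; the read length
never enters the key. Tags are then extended to 150 bp in their 3'
direction (clipped at chromosome bounds) to approximate sonication
fragments. Densities are scaled to tags per 10 million (factor
`1e7 / total`). Binned tracks use a midpoint rule (each extended tag
increments exactly one bin, default 50 bp), which keeps the track total
equal to the tag count and is sufficient for window statistics; a
full-overlap weighting would change window counts by at most the
fraction of tags straddling bin edges and is deliberately not the
default.

## Hotspot-style peak calling

The published analysis names its in-house caller but not its internals,
so the caller here is a windowed binomial enrichment test documented as
a reimplementation in the same spirit. For each 200-bp window (step
50 bp) the expected ChIP count is

```
E = max(input count in a 25-kb local window x (chip total / input total)
        x (window / local window),
        genome-average ChIP count per window,
        pseudocount = 1)
```

and the p-value is `P(Binomial(N_chip, E / N_chip) >= k)`. Windows at
Benjamini–Hochberg q < 0.01 are merged when separated by at most 150 bp;
the summit is the center of the maximum-count bin (leftmost on ties);
peak "tag density" for ranking is the maximum 200-bp window count scaled
to tags per 10 million. Windows overlapping the repeat mask are removed
before testing; if no mask is supplied the built-in tandem-repeat
detector (unit ≤ 6 bp, total span ≥ 24 bp) masks the genome. An empty
input track degrades to the genome-average background with a warning.

Replicate concordance intersects the two replicates' peak lists
(≥ 1 bp overlap), emitting the union interval per overlapping pair
(chains collapse), the mean of the replicates' best-window densities,
and the denser replicate's summit. Ranking keeps the top fraction
(default 20%, ties broken by smaller p then coordinate); pooling merges
the two groups' lists with union coordinates, maximum density, and an
A/B/both provenance flag.

Because p-value-thresholded calls are not invariant to sequencing depth
for borderline windows, the depth-invariance property is guaranteed only
where window classification is unambiguous; the test suite checks it on
noise-free backgrounds with clear spikes.

## Differential binding

Counting follows the midpoint rule at the pooled peaks (a midpoint
exactly at `end` is outside). Size factors are DESeq-style
median-of-ratios over peaks with all-positive counts. Per-peak raw
dispersions come from the pooled within-group variance of normalized
counts, `alpha = (w - q * mean(1/s)) / q^2`; a parametric trend
`a0 + a1/q` is least-squares fitted over *all* finite raw values
(including negative ones, so shot-noise-only data fits ≈ 0) and clipped
at zero.

Two sharing modes exist. `"maximum"` takes `max(raw, trend, 1e-8)` — the
conservative behavior appropriate when per-peak estimates carry real
information. The default is `"fit-only"` (trend value, floored):
with the duplicate-only design there are two residual degrees of freedom
per peak and the raw moment estimates are essentially noise; keeping
their maximum against the trend inflates roughly half the dispersions by
factors of ~2 in variance and makes the exact test grossly conservative
(null p-values fail uniformity checks catastrophically). Fit-only
sharing is also what the original count-based tools recommended for
minimal designs.

The test conditions on each peak's pooled count `k_s = k_A + k_B`. Group
sums of replicate NB counts with common concentration `q0 = k_s / (S_A +
S_B)` have mean `q0 * S_g` and variance `q0 * S_g + alpha * q0^2 *
sum(s_j^2)`; each split `(a, k_s - a)` gets the product of the two
group-sum pmfs (Poisson when the overdispersion term is negligible), and
the p-value is the normalized mass of splits as likely or less likely
than the observed one. By default the Lancaster mid-p correction is
applied: splits *exactly* as likely as the observed one (1e-9 relative
tolerance) contribute half their mass. Without it, the test's
discreteness concentrates an atom at p = 1 with mass equal to the
conditional mode probability (~0.04–0.06 at typical depths), which by
itself breaks null-uniformity diagnostics; with it, null p-values are
approximately uniform while tail p-values — the ones that matter for
discovery — are essentially unchanged. The strict classical definition
remains available (`mid_p=False`). A peak with zero total yields p = 1
and log2 fold change 0; fold changes use normalized group means with
pseudocount 0.5.

Between-group concordance is the Pearson r of `log2(density + 0.5)`
over pooled peaks, with M = y − x and A = (x + y)/2 tabulated for MA
plots.

## Annotation

TSS is `txStart` for + genes and `txEnd` for − genes; the signed
summit→TSS distance is negative upstream of the gene. Ties go to the
lexicographically first gene id. One exclusive category per peak is
assigned at the summit with precedence promoter > 5'UTR > exon > intron
> 3'UTR > intergenic, where promoter means distance in [−5000, +100] bp.
Synthetic gene models carry no CDS, so the strand-aware first/last exon
segments stand in for UTRs. The gene-proximal subset keeps peaks whose
summit lies inside a gene body or within 5 kb upstream of a TSS
(boundary: −5000 included, −5001 excluded).

## Motif architecture

The library holds five consensus motifs: full GRE `ACANNNTGTYCT` and
nGRE `CTCC(N)0–2GGAGA` (printed consensus strings; the gapped nGRE
expands to one concrete pattern per spacer length and only exact
consensus matches count); GRE half-site `TGTYCT` (the palindrome's 3'
half — no half-site string is printed anywhere authoritative); NF-1
half-site `TTGGCA` (the TTGGC-containing half of the canonical full site
`TTGGC(N5)GCCAA`); and bHLH `CANATGG` with `CAGCTG` selectable as an
alternate E-box. All are configurable.

Scanning is exact consensus matching over a 4-bit base encoding
(degenerate positions are bitmasks; lowercase/masked bases encode to 0
and can never match), on both strands, with a hit and its reverse
complement on the same interval reported once. Frequency counting uses
summit ± 100 bp; positional histograms (10-bp bins) and the nGRE report
use summit ± 1000 bp; both windows are configurable and neither is
stated in the source analysis. Half-site hits nested inside a full-GRE
hit are dropped from histogram counting but the full-GRE hit always sets
the half-site flag (the 3' half of every palindrome instance *is* a
half-site), so `has_full_gre => has_gre_half` is an invariant.

Composite labels partition peaks into GRE/H alone, GRE/H+NF1,
GRE/H+bHLH, GRE/H+NF1+bHLH, non-GRE motifs only, and none. Strength
strata are the top and bottom `floor(n/3)` peaks by descending density.
The nGRE report restricts to nGRE-containing peaks and asks whether a
conventional GRE form sits closer to the summit.

The k-mer enrichment is a deliberate simplification of de novo motif
discovery: reverse-complement-collapsed k-mers (k = 6–16) are scored by
the hypergeometric upper tail of their peak-level occurrence against a
dinucleotide-shuffled background (random Eulerian walk per sequence),
with per-width BH adjustment. It recovers planted fixed-sequence motifs
but has none of the PWM optimization of a real discovery tool.

## Synthetic data: what it emulates and what it does not

The generator exists to make every pipeline claim checkable against
planted truth.

* **Background** is i.i.d. sequence at a target GC (default 0.5) made
  motif-free by iterated redraw of matched spans, so any scanner hit at
  a site is planted, and per-class peak fractions are configuration
  constants rather than estimates. Planted sites are additionally
  verified by scanning and replanted when embedding creates or destroys
  a motif at a junction.
* **Composition default** (`data/default_composition.yaml`): 7298 sites;
  3576 with a full GRE (49.0%); 2987 with a standalone half-site, so
  6563 (89.9%) carry some GRE form and 735 carry neither; 3985 (54.6%)
  NF-1; 1248 (17.1%) bHLH; 126 nGRE, 120 of them co-planted with a GRE
  form. Offset spreads: GRE 15 bp, half-site 25 bp, NF-1/bHLH 60 bp
  (the non-GRE motifs are broader around the summit), nGRE 60 bp.
* **Reads**: per site and sample, fragment counts are Poisson with mean
  `depth_per_unit x (1 + sum of planted class weights) x condition
  multiplier` (defaults: depth 50, weights GRE 1.0, half 0.4, NF-1 0.6,
  bHLH 0.6, nGRE 0.0); fragment centers are normal (sd 40 bp); tag 5'
  ends sit 75 bp outside the fragment center on the matching strand and
  reads are 36 bp; background is uniform at 0.035 tags/bp (ChIP) and
  0.105 tags/bp (input). Defaults give ~1.1 M ChIP tags per sample on
  the 10 Mb default genome. The strand-shift read model is the simplest
  one that produces realistic extended-tag pileups; no read model is
  given in the source analysis, and no fragment-length distribution for
  sonicated hippocampal chromatin is available, so these are asserted
  defaults, not derived ones.
* **Null design**: condition effect 1.0 makes the two conditions
  identically distributed — the generative counterpart of the reference
  study's finding of no context effect.

Not emulated: sequencing errors, mappability structure, copy-number or
diploid effects, real repeat landscapes (the built-in tandem detector is
far simpler than genome-scale repeat annotation), PCR duplication beyond
coincidental 5'-position collisions, and any dependence of GR occupancy
on chromatin state. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under a clean generative model, not
performance on real libraries.

One sizing note: the default composition emulates the *final* analyzed
peak list, so the flagship synthetic analysis keeps every
replicate-concordant peak (top fraction 1.0) rather than re-applying the
20% cut that produced that list in the original study; the ranking
operation itself is exercised separately. At the default density
(7298 sites in 10 Mb) nearby sites can merge into one called peak and a
±1 kb histogram window can touch a neighboring site; truth-table
equalities for the nGRE report are therefore validated on a
wide-spacing configuration (spacing > 2 kb), while summit ± 100 bp
flag-level quantities are unaffected.

## Determinism and problem sizes

All randomness flows from one seed per entry point, split with
`numpy.random.SeedSequence` per sample/stage; reruns are byte-identical.
The shipped analyses and tests use the 10 Mb / 7298-site default for
composition, peak-recovery, stratification and concordance work, and a
2000-peak direct count simulation for null-calibration diagnostics;
brute-force oracles (regex scanning, exhaustive split enumeration,
hand-computed BH) back the scanner, the exact test and the adjustment on
small instances.

## Known limitations

* The caller's parameters (window, local background, q threshold, merge
  gap) are honest defaults, not re-derived from the unpublished original
  implementation; absolute peak counts on real data would differ.
* The exact test's mid-p variant is approximately, not exactly, uniform
  under the null; with deduplicated tags, counts at strong peaks are
  slightly sub-Poisson (5'-position saturation), which makes the test
  marginally conservative in the full pipeline.
* Nearest-TSS annotation considers transcript bounds only (no
  alternative isoforms), and UTR categories depend on the synthetic
  first/last-exon convention when models lack CDS.
* The k-mer stand-in cannot discover degenerate motifs; it is a
  validation tool, not a replacement for PWM-based discovery.
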