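"""End-to-end drivers: simulation bundle and the analysis pipeline.

Stage order follows the original analysis: tag preprocessing -> hotspot
calling per sample -> replicate concordance per group -> top-20% ranking
-> cross-group pooling -> tag counting -> NB differential test ->
nearest-TSS annotation -> motif architecture -> reports.  Every tabular
output is a headered TSV; a metadata JSON records seed, config hash and
version; the log carries per-stage record counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, diffbind, io, motifarch, peakcall, simdata, tagops
from .config import RunConfig, SimConfig

log = logging.getLogger(__name__)


def run_simulation(cfg: SimConfig, outdir, seed: int | None = None) -> dict:
    """Generate the synthetic bundle: genome, truth, tags, gene models."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = 0
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    background = simdata.generate_background_genome(
        cfg.genome_length, cfg.gc, seed=seeds[0])
    genome, sites, instances = simdata.plant_sites(
        background, cfg.composition, seed=seeds[1], chrom=cfg.chrom)
    log.info("planted %d sites (%d motif instances)", len(sites),
             len(instances))
    io.write_fasta({cfg.chrom: genome}, outdir / "genome.fa")
    io.write_tsv(sites, outdir / "truth_sites.tsv")
    io.write_tsv(instances, outdir / "truth_instances.tsv")
    genes = simdata.write_gene_models(cfg.genome_length, cfg.n_genes,
                                      seed=seeds[2], chrom=cfg.chrom)
    annotate.write_gene_models_table(genes, outdir / "gene_models.tsv")
    sample_files = {}
    if cfg.simulate_reads:
        tags = simdata.simulate_tags(cfg.genome_length, sites,
                                     cfg.read_params,
                                     n_replicates=cfg.n_replicates,
                                     n_conditions=cfg.n_conditions,
                                     seed=seeds[3], chrom=cfg.chrom)
        for name, df in tags.items():
            path = outdir / f"{name}.bed"
            io.write_bed(df, path)
            sample_files[name] = str(path)
            log.info("%s: %d tags", name, len(df))
    io.write_run_metadata(outdir, cfg.to_dict(), seed)
    return dict(outdir=str(outdir), samples=sample_files,
                n_sites=len(sites))


def preprocess_sample(path, chrom_sizes, extension_length=150, bin_size=50):
    """Read, deduplicate, extend and bin one sample's tags."""
    reads = io.read_tags(path)
    reads = tagops.deduplicate_tags(reads)
    tags = tagops.extend_tags(reads, chrom_sizes, length=extension_length)
    track = tagops.density_track(tags, chrom_sizes, bin_size=bin_size)
    return tags, track


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis chain; returns the result bundle paths."""
    cfg.validate_paths()
    p = cfg.params
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load genome"
    try:
        genome_seqs = io.parse_fasta(cfg.genome)
        chrom_sizes = {c: len(s) for c, s in genome_seqs.items()}
        if cfg.mask:
            mask = io.parse_bed(cfg.mask)
        else:
            mask = pd.concat(
                [tagops.find_simple_repeats(s, chrom=c)
                 for c, s in genome_seqs.items()], ignore_index=True)
        log.info("mask: %d intervals", len(mask))

        stage = "tag preprocessing"
        tags_by_sample, peaks_by_sample = {}, {}
        for s in cfg.samples:
            chip_tags, chip_track = preprocess_sample(
                s.chip, chrom_sizes, p.extension_length, p.bin_size)
            _, input_track = preprocess_sample(
                s.input, chrom_sizes, p.extension_length, p.bin_size)
            tags_by_sample[s.name] = chip_tags
            stage = f"hotspot calling ({s.name})"
            peaks_by_sample[s.name] = peakcall.call_hotspots(
                chip_track, input_track, p.hotspot, mask=mask)
            log.info("%s: %d hotspot peaks", s.name,
                     len(peaks_by_sample[s.name]))

        stage = "replicate concordance"
        groups = sorted({s.group for s in cfg.samples})
        group_peaks = {}
        for g in groups:
            members = [s.name for s in cfg.samples if s.group == g]
            if len(members) != 2:
                raise ValueError(f"group {g!r} must have two replicates")
            conc = peakcall.concordant_peaks(peaks_by_sample[members[0]],
                                             peaks_by_sample[members[1]])
            group_peaks[g] = peakcall.rank_top_fraction(conc, p.top_fraction)
            log.info("group %s: %d concordant, %d kept (top %.0f%%)", g,
                     len(conc), len(group_peaks[g]), 100 * p.top_fraction)
            io.write_tsv(group_peaks[g], outdir / f"peaks_group_{g}.tsv")

        stage = "pooling"
        pooled = peakcall.pool_nonduplicated(group_peaks[groups[0]],
                                             group_peaks[groups[1]])
        io.write_tsv(pooled, outdir / "peaks_pooled.tsv")
        io.write_bed(pooled.rename(columns={"peak_id": "name"})
                     .assign(score=0, strand="."),
                     outdir / "peaks_pooled.bed")
        log.info("pooled: %d nonduplicated peaks", len(pooled))

        stage = "tag counting"
        counts = diffbind.count_tags(pooled, tags_by_sample)
        io.write_tsv(counts, outdir / "counts.tsv", index=True)

        stage = "differential binding"
        sf = diffbind.size_factors(counts)
        group_of = {s.name: s.group for s in cfg.samples}
        disp = diffbind.estimate_dispersion(counts, sf, group_of)
        diff = diffbind.nb_test(counts, sf, disp, group_of)
        io.write_tsv(diff, outdir / "differential.tsv", index=True)
        n_sig = int((diff["adjusted_p"] < 0.05).sum())
        log.info("differential: %d/%d peaks at adjusted p < 0.05",
                 n_sig, len(diff))

        stage = "intensity concordance"
        dens = _group_densities(counts, group_of, groups)
        ma_table, pearson_r = diffbind.intensity_concordance(
            dens[groups[0]], dens[groups[1]])
        ma_table.insert(0, "peak_id", counts.index)
        io.write_tsv(ma_table, outdir / "ma_table.tsv")
        log.info("between-group Pearson r = %.3f", pearson_r)

        stage = "heat matrix"
        all_tags = pd.concat(tags_by_sample.values(), ignore_index=True)
        ordered, mat = peakcall.density_heat_matrix(
            pooled, all_tags, chrom_sizes, flank=p.heatmap_flank,
            bin_size=p.bin_size)
        hm = pd.DataFrame(mat, index=ordered["peak_id"])
        io.write_tsv(hm, outdir / "heatmap_matrix.tsv", index=True)

        stage = "annotation"
        genes_tab = annotate.read_gene_models(cfg.gene_models)
        genes = annotate.gene_models_from_table(genes_tab)
        ann = annotate.nearest_tss(pooled, genes)
        io.write_tsv(ann, outdir / "annotations.tsv")
        io.write_tsv(annotate.category_fractions(ann).rename("fraction")
                     .rename_axis("category").reset_index(),
                     outdir / "category_fractions.tsv")
        proximal = annotate.select_gene_proximal(pooled, ann, genes)
        io.write_tsv(proximal, outdir / "peaks_gene_proximal.tsv")
        log.info("annotation: %d gene-proximal of %d peaks",
                 len(proximal), len(pooled))

        stage = "motif architecture"
        chrom = next(iter(genome_seqs))
        masked_genome = tagops.mask_sequence(genome_seqs[chrom], mask, chrom)
        hits_count = motifarch.scan_peaks(
            pooled, masked_genome, halfwidth=p.count_halfwidth)
        hits_hist = motifarch.scan_peaks(
            pooled, masked_genome, halfwidth=p.histogram_halfwidth)
        arch = motifarch.classify_architecture(pooled, hits_count)
        io.write_tsv(hits_count, outdir / "motif_hits.tsv")
        io.write_tsv(arch, outdir / "architecture.tsv")
        io.write_tsv(motifarch.class_frequencies(arch).rename("fraction")
                     .rename_axis("motif_class").reset_index(),
                     outdir / "motif_frequencies.tsv")
        _, _, part_freq = motifarch.partition_by_full_gre(arch)
        io.write_tsv(part_freq, outdir / "partition_frequencies.tsv",
                     index=True)
        hist, medians = motifarch.positional_histogram(
            motifarch.drop_nested_half_hits(hits_hist),
            bin_size=p.histogram_bin, halfwidth=p.histogram_halfwidth)
        io.write_tsv(hist, outdir / "positional_histograms.tsv", index=True)
        io.write_tsv(medians.rename_axis("motif").reset_index(),
                     outdir / "median_abs_offsets.tsv")
        strat = motifarch.stratify_by_strength(pooled, arch)
        io.write_tsv(strat, outdir / "strength_stratification.tsv",
                     index=True)
        comp = motifarch.composite_by_strength(pooled, arch)
        io.write_tsv(comp, outdir / "composite_by_strength.tsv", index=True)
        ngre_report, ngre_summary = motifarch.ngre_analysis(hits_hist)
        io.write_tsv(ngre_report, outdir / "ngre_report.tsv")

        if p.run_kmer:
            stage = "k-mer enrichment"
            fg = [motifarch.peak_window(masked_genome, int(r["summit"]),
                                        p.count_halfwidth)[0]
                  for _, r in pooled.iterrows()]
            widths = tuple(w for w in p.kmer_widths
                           if fg and w <= min(len(s) for s in fg))
            kmers = motifarch.kmer_enrichment(fg, widths=widths,
                                              seed=cfg.seed)
            io.write_tsv(kmers.groupby("width").head(25),
                         outdir / "kmer_enrichment_top.tsv")

        io.write_run_metadata(outdir, cfg.to_dict(), cfg.seed)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return dict(outdir=str(outdir), n_peaks=len(pooled),
                n_significant=n_sig, pearson_r=pearson_r,
                ngre_summary=ngre_summary)


def _group_densities(counts: pd.DataFrame, group_of: dict[str, str],
                     groups: list[str]) -> dict[str, np.ndarray]:
    """Per-group peak intensity: mean over the group's samples of
    depth-normalized (tags-per-10M) counts."""
    dens = {}
    for g in groups:
        cols = [c for c in counts.columns if group_of[c] == g]
        scaled = counts[cols] * (1e7 / counts[cols].sum(axis=0))
        dens[g] = scaled.mean(axis=1).to_numpy()
    return dens
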