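"""Architecture flags, partitions, strength strata, nGRE report, k-mers."""

import numpy as np
import pandas as pd
import pytest

from grchip.motifarch import (COMPOSITE_LABELS, canonical_kmer,
                              classify_architecture, composite_by_strength,
                              dinucleotide_shuffle, drop_nested_half_hits,
                              kmer_enrichment, ngre_analysis,
                              partition_by_full_gre, positional_histogram,
                              scan_peaks, stratify_by_strength)
from grchip.motifs import reverse_complement
from grchip.simdata import (ClassConfig, CompositionConfig,
                            generate_background_genome, plant_sites)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["peak_id", "motif", "motif_class",
                                       "offset", "strand", "matched"])


def peaks_frame(n, densities=None):
    if densities is None:
        densities = np.arange(n, dtype=float) + 1
    return pd.DataFrame({"peak_id": [f"p{i}" for i in range(n)],
                         "chrom": "chr1",
                         "start": np.arange(n) * 1000,
                         "end": np.arange(n) * 1000 + 200,
                         "summit": np.arange(n) * 1000 + 100,
                         "density": densities})


class TestClassification:
    def test_full_gre_only_sets_half_flag_and_label(self):
        peaks = peaks_frame(1)
        hits = hits_frame([("p0", "full_gre", "full_gre", 0, "+", "x")])
        arch = classify_architecture(peaks, hits)
        r = arch.iloc[0]
        assert r["has_full_gre"] and r["has_gre_half"]
        assert r["composite"] == "GRE/H alone"

    def test_half_plus_nf1_label(self):
        peaks = peaks_frame(1)
        hits = hits_frame([("p0", "gre_half", "gre_half", 5, "+", "x"),
                           ("p0", "nf1_half", "nf1_half", -20, "-", "y")])
        arch = classify_architecture(peaks, hits)
        assert arch.iloc[0]["composite"] == "GRE/H+NF1"
        assert not arch.iloc[0]["has_full_gre"]

    def test_no_hits_label_none(self):
        arch = classify_architecture(peaks_frame(1), hits_frame([]))
        assert arch.iloc[0]["composite"] == "none"

    def test_ngre_only_is_non_gre_motifs(self):
        hits = hits_frame([("p0", "ngre", "ngre", 3, "+", "x")])
        arch = classify_architecture(peaks_frame(1), hits)
        assert arch.iloc[0]["composite"] == "non-GRE motifs only"

    def test_full_implies_half_invariant(self, small_planted):
        genome, sites, _ = small_planted
        peaks = pd.DataFrame({"peak_id": sites["site_id"], "chrom": "chr1",
                              "summit": sites["center"],
                              "density": sites["enrichment_weight"]})
        arch = classify_architecture(peaks, scan_peaks(peaks, genome))
        assert (~arch["has_full_gre"] | arch["has_gre_half"]).all()


class TestPartition:
    def test_all_full_gre_leaves_second_partition_empty(self):
        hits = hits_frame([(f"p{i}", "full_gre", "full_gre", 0, "+", "x")
                           for i in range(3)])
        arch = classify_architecture(peaks_frame(3), hits)
        with_full, without, freq = partition_by_full_gre(arch)
        assert len(with_full) == 3 and len(without) == 0
        assert ((freq >= 0) & (freq <= 1)).all().all()

    def test_partition_frequencies_recover_planted_fractions(
            self, small_planted):
        genome, sites, _ = small_planted
        peaks = pd.DataFrame({"peak_id": sites["site_id"], "chrom": "chr1",
                              "summit": sites["center"],
                              "density": sites["enrichment_weight"]})
        arch = classify_architecture(peaks, scan_peaks(peaks, genome))
        _, without, freq = partition_by_full_gre(arch)
        n_half_no_full = int((sites["has_gre_half"]
                              & ~sites["has_full_gre"]).sum())
        assert freq.loc["has_gre_half", "without_full_gre"] == \
            pytest.approx(n_half_no_full / len(without))


class TestHistogram:
    def test_all_central_offsets_single_bin(self):
        hits = hits_frame([(f"p{i}", "full_gre", "full_gre", 0, "+", "x")
                           for i in range(5)])
        mat, med = positional_histogram(hits)
        assert mat["full_gre"].sum() == 5
        assert mat.loc[5, "full_gre"] == 5  # bin [0, 10) has center 5
        assert med["full_gre"] == 0.0

    def test_empty_hits_all_zero(self):
        mat, med = positional_histogram(hits_frame([]))
        assert mat.size == 0 or not mat.to_numpy().any()

    def test_tightly_planted_motif_more_central(self, small_planted):
        genome, sites, _ = small_planted
        peaks = pd.DataFrame({"peak_id": sites["site_id"], "chrom": "chr1",
                              "summit": sites["center"],
                              "density": sites["enrichment_weight"]})
        hits = scan_peaks(peaks, genome, halfwidth=100)
        _, med = positional_histogram(hits, halfwidth=100)
        # GREs planted with sd 15 bp, NF-1 with sd 60 bp
        assert med["full_gre"] < med["nf1_half"]

    def test_nested_half_hits_dropped_for_counting(self):
        hits = hits_frame([
            ("p0", "full_gre", "full_gre", 0, "+", "ACATTTTGTTCT"),
            ("p0", "gre_half", "gre_half", 3, "+", "TGTTCT"),
            ("p0", "gre_half", "gre_half", 80, "-", "TGTCCT")])
        out = drop_nested_half_hits(hits)
        assert len(out) == 2
        assert set(out["offset"]) == {0, 80}


class TestStrengthStrata:
    def test_nine_peaks_strata_of_three(self):
        peaks = peaks_frame(9)
        hits = hits_frame([(f"p{i}", "full_gre", "full_gre", 0, "+", "x")
                           for i in range(6, 9)])
        arch = classify_architecture(peaks, hits)
        strat = stratify_by_strength(peaks, arch)
        # densities ascend with index: p6..p8 are the top third
        assert strat.loc["has_full_gre", "top_third"] == 1.0
        assert strat.loc["has_full_gre", "bottom_third"] == 0.0

    def test_identical_peaks_equal_frequencies(self):
        peaks = peaks_frame(6, densities=np.full(6, 7.0))
        hits = hits_frame([(f"p{i}", "nf1_half", "nf1_half", 0, "+", "x")
                           for i in range(6)])
        arch = classify_architecture(peaks, hits)
        strat = stratify_by_strength(peaks, arch)
        assert strat.loc["has_nf1_half", "top_third"] == \
            strat.loc["has_nf1_half", "bottom_third"] == 1.0

    def test_fewer_than_three_rejected(self):
        arch = classify_architecture(peaks_frame(2), hits_frame([]))
        with pytest.raises(ValueError):
            stratify_by_strength(peaks_frame(2), arch)

    def test_composite_fractions_sum_to_one(self):
        peaks = peaks_frame(9)
        hits = hits_frame(
            [(f"p{i}", "full_gre", "full_gre", 0, "+", "x")
             for i in range(5)] +
            [(f"p{i}", "nf1_half", "nf1_half", 0, "+", "x")
             for i in range(3, 9)])
        arch = classify_architecture(peaks, hits)
        comp = composite_by_strength(peaks, arch)
        assert comp["top_third"].sum() == pytest.approx(1.0)
        assert comp["bottom_third"].sum() == pytest.approx(1.0)
        assert list(comp.index) == COMPOSITE_LABELS

    def test_single_label_fraction_one(self):
        peaks = peaks_frame(3)
        hits = hits_frame([(f"p{i}", "full_gre", "full_gre", 0, "+", "x")
                           for i in range(3)])
        arch = classify_architecture(peaks, hits)
        comp = composite_by_strength(peaks, arch)
        assert comp.loc["GRE/H alone", "top_third"] == 1.0


class TestNgre:
    def test_gre_closer_flag(self):
        hits = hits_frame([("p0", "ngre", "ngre", 300, "+", "x"),
                           ("p0", "gre_half", "gre_half", 10, "+", "y")])
        report, summary = ngre_analysis(hits)
        assert bool(report.iloc[0]["gre_closer"])
        assert summary["n_without_gre_form"] == 0

    def test_ngre_only_counted_as_no_gre(self):
        hits = hits_frame([("p0", "ngre", "ngre", 5, "+", "x")])
        report, summary = ngre_analysis(hits)
        assert summary["n_with_ngre"] == 1
        assert summary["n_without_gre_form"] == 1
        assert summary["n_gre_closer"] == 0
        assert summary["n_ngre_not_most_central"] == 0
        assert summary["mean_abs_offset_by_class"]["ngre"] == 5.0

    def test_planted_truth_counts_recovered(self):
        # 20 nGRE sites, 17 with a co-planted central GRE form; wide
        # spacing keeps each histogram window free of neighboring sites
        g = generate_background_genome(200_000, 0.5, seed=51)
        cfg = CompositionConfig(n_sites=20, peak_halfwidth=100, classes={
            "gre_half": ClassConfig(count=17, offset_sd=15, weight=0.4),
            "ngre": ClassConfig(count=20, offset_sd=60, weight=0.0),
        }, ngre_with_gre=17)
        genome, sites, _ = plant_sites(g, cfg, seed=52, min_spacing=2200)
        peaks = pd.DataFrame({"peak_id": sites["site_id"], "chrom": "chr1",
                              "summit": sites["center"],
                              "density": sites["enrichment_weight"]})
        hits = scan_peaks(peaks, genome, halfwidth=1000)
        _, summary = ngre_analysis(hits)
        assert summary["n_with_ngre"] == 20
        assert summary["n_without_gre_form"] == 3


class TestKmers:
    def test_planted_twelve_mer_ranks_first(self):
        rng = np.random.default_rng(53)
        core = "ACATGCTGTTCT"  # one concrete GRE realization
        fg = []
        for _ in range(60):
            s = "".join(rng.choice(list("ACGT"), 100))
            pos = int(rng.integers(0, 88))
            fg.append(s[:pos] + core + s[pos + 12:])
        tab = kmer_enrichment(fg, widths=(12,), seed=0)
        assert tab.iloc[0]["kmer"] == canonical_kmer(core)
        assert tab.iloc[0]["q_value"] < 0.05

    def test_identical_background_no_enrichment(self):
        rng = np.random.default_rng(54)
        fg = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
        tab = kmer_enrichment(fg, background=list(fg), widths=(6,))
        assert (tab["q_value"] >= 0.05).all()

    def test_reverse_complement_collapsed(self):
        assert canonical_kmer("ACGTTT") == canonical_kmer(
            reverse_complement("ACGTTT"))
        tab = kmer_enrichment(["AAACGTTTT"], background=["CCCCCCCCC"],
                              widths=(6,))
        kmers = set(tab["kmer"])
        assert all(canonical_kmer(k) == k for k in kmers)

    def test_width_exceeding_window_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGTACGT"], widths=(12,))

    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = np.random.default_rng(55)
        s = "".join(rng.choice(list("ACGT"), 200))
        t = dinucleotide_shuffle(s, rng)
        def dinucs(x):
            c = {}
            for a, b in zip(x[:-1], x[1:]):
                c[a + b] = c.get(a + b, 0) + 1
            return c
        assert dinucs(s) == dinucs(t)
        assert t != s
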