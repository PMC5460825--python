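"""Synthetic-data generator: motif-free guarantee, exact-count planting,
null fidelity, determinism."""

import numpy as np
import pandas as pd
import pytest

from grchip.motifs import compile_motif, default_motif_library, scan_library
from grchip.simdata import (ClassConfig, CompositionConfig, ReadSimParams,
                            default_composition, generate_background_genome,
                            plant_sites, simulate_tags, write_gene_models)
from grchip.annotate import gene_models_from_table

from conftest import small_composition
from oracles import regex_hits


class TestBackground:
    def test_motif_free_by_independent_regex_scan(self, small_genome,
                                                  motif_library):
        for model in motif_library:
            assert regex_hits(small_genome, model.patterns) == set()

    def test_halfsite_free_megabase(self):
        half = compile_motif("gre_half", "TGTYCT", "gre_half")
        g = generate_background_genome(1_000_000, 0.5, [half], seed=7)
        assert regex_hits(g, half.patterns) == set()

    def test_deterministic_for_fixed_seed(self):
        a = generate_background_genome(12_000, 0.4, seed=5)
        b = generate_background_genome(12_000, 0.4, seed=5)
        assert a == b
        assert a != generate_background_genome(12_000, 0.4, seed=6)

    def test_gc_content_near_target(self):
        g = generate_background_genome(50_000, 0.6, seed=8)
        gc = (g.count("G") + g.count("C")) / len(g)
        assert abs(gc - 0.6) < 0.02

    def test_length_and_bounds_validation(self):
        with pytest.raises(ValueError):
            generate_background_genome(5000, 0.5)
        with pytest.raises(ValueError):
            generate_background_genome(20_000, 1.5)


class TestPlanting:
    def test_exact_counts_per_class(self, small_planted):
        _, sites, _ = small_planted
        cfg = small_composition()
        counts = cfg.resolved_counts()
        assert int(sites["has_full_gre"].sum()) == counts["full_gre"]
        assert int(sites["has_nf1_half"].sum()) == counts["nf1_half"]
        assert int(sites["has_bhlh"].sum()) == counts["bhlh"]
        assert int(sites["has_ngre"].sum()) == counts["ngre"]
        # the half-site flag includes full-GRE sites (implication)
        assert int(sites["has_gre_half"].sum()) == \
            counts["full_gre"] + counts["gre_half"]

    def test_full_gre_site_scan_recovers_half_site(self, small_planted,
                                                   motif_library):
        genome, sites, _ = small_planted
        site = sites[sites["has_full_gre"]].iloc[0]
        c = int(site["center"])
        window = genome[c - 100:c + 101]
        hits = scan_library(window, motif_library)
        assert len(hits["full_gre"]) >= 1
        assert len(hits["gre_half"]) >= 1

    def test_scanned_flags_match_truth_flags(self, small_planted,
                                             motif_library):
        genome, sites, _ = small_planted
        for _, s in sites.iterrows():
            c = int(s["center"])
            hits = scan_library(genome[c - 100:c + 101], motif_library)
            for m in motif_library:
                assert bool(hits[m.name]) == bool(s[f"has_{m.motif_class}"])

    def test_planting_nothing_leaves_genome_unchanged(self, small_genome):
        cfg = CompositionConfig(n_sites=10, peak_halfwidth=100, classes={})
        genome, sites, instances = plant_sites(small_genome, cfg, seed=9)
        assert genome == small_genome
        assert len(instances) == 0
        assert not sites[[c for c in sites.columns
                          if c.startswith("has_")]].any().any()

    def test_enrichment_weight_is_one_plus_class_weights(self, small_planted):
        _, sites, instances = small_planted
        cfg = small_composition()
        for _, s in sites.iterrows():
            planted = instances[instances["site_id"] == s["site_id"]]
            expect = 1.0 + sum(cfg.classes[c].weight
                               for c in planted["motif_class"])
            assert s["enrichment_weight"] == pytest.approx(expect)

    def test_instances_within_halfwidth(self, small_planted):
        _, sites, instances = small_planted
        centers = sites.set_index("site_id")["center"]
        for _, ins in instances.iterrows():
            c = centers[ins["site_id"]]
            assert c - 100 <= ins["start"]
            assert ins["start"] + len(ins["sequence"]) <= c + 101

    def test_genome_too_small_raises(self):
        g = generate_background_genome(10_000, 0.5, seed=1)
        with pytest.raises(ValueError, match="too small"):
            plant_sites(g, small_composition(100), seed=1)

    def test_default_composition_accounting(self):
        cfg = default_composition()
        counts = cfg.resolved_counts()
        assert cfg.n_sites == 7298
        n_gre = counts["full_gre"] + counts["gre_half"]
        assert cfg.n_sites - n_gre == 735  # sites with neither GRE form
        assert counts["ngre"] - cfg.ngre_with_gre == 6

    def test_invalid_class_config_rejected(self):
        with pytest.raises(ValueError):
            ClassConfig(count=5, offset_sd=-1).validate()
        with pytest.raises(ValueError):
            ClassConfig(rate=1.5).resolve_count(10)
        with pytest.raises(ValueError):
            ClassConfig(count=20).resolve_count(10)


class TestTagSimulation:
    def test_null_condition_counts_match_across_groups(self):
        # condition effect 1.0: per-site Poisson means identical across
        # conditions; Monte-Carlo means agree within sampling error
        centers = np.arange(30) * 2000 + 1000
        sites = pd.DataFrame({"site_id": [f"s{i}" for i in range(30)],
                              "chrom": "chr1", "center": centers,
                              "enrichment_weight": 2.0})
        params = ReadSimParams(depth_per_unit=100, background_rate=0.001,
                               input_rate=0.001)
        tags = simulate_tags(62_000, sites, params, seed=11)
        n1 = sum(len(tags[f"chip_c1_r{r}"]) for r in (1, 2))
        n2 = sum(len(tags[f"chip_c2_r{r}"]) for r in (1, 2))
        assert abs(n1 - n2) / max(n1, n2) < 0.05

    def test_mean_counts_scale_with_enrichment_weight(self):
        sites = pd.DataFrame({
            "site_id": ["a", "b"], "chrom": "chr1",
            "center": [5_000, 15_000], "enrichment_weight": [1.0, 2.0]})
        params = ReadSimParams(depth_per_unit=200, frag_dispersion=20,
                               background_rate=1e-4, input_rate=1e-4)
        tot = np.zeros(2)
        for seed in range(10):
            tags = simulate_tags(20_000, sites, params, n_conditions=1,
                                 n_replicates=2, seed=seed)
            for name, df in tags.items():
                if not name.startswith("chip"):
                    continue
                mids = (df["start"] + df["end"]) // 2
                tot[0] += ((mids > 4_000) & (mids < 6_000)).sum()
                tot[1] += ((mids > 14_000) & (mids < 16_000)).sum()
        assert tot[1] / tot[0] == pytest.approx(2.0, rel=0.1)

    def test_condition_effect_multiplies_second_condition(self):
        sites = pd.DataFrame({"site_id": ["a"], "chrom": "chr1",
                              "center": [10_000],
                              "enrichment_weight": [2.0]})
        params = ReadSimParams(depth_per_unit=500, background_rate=1e-4,
                               input_rate=1e-4, condition_effect=3.0)
        n1 = n2 = 0
        for seed in range(5):
            tags = simulate_tags(20_000, sites, params, seed=seed)
            n1 += len(tags["chip_c1_r1"]) + len(tags["chip_c1_r2"])
            n2 += len(tags["chip_c2_r1"]) + len(tags["chip_c2_r2"])
        assert n2 / n1 == pytest.approx(3.0, rel=0.1)

    def test_deterministic_and_sorted_output(self):
        sites = pd.DataFrame({"site_id": ["a"], "chrom": "chr1",
                              "center": [10_000],
                              "enrichment_weight": [2.0]})
        p = ReadSimParams()
        t1 = simulate_tags(20_000, sites, p, seed=13)
        t2 = simulate_tags(20_000, sites, p, seed=13)
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])
            assert t1[name]["start"].is_monotonic_increasing

    def test_input_samples_are_background_only(self):
        sites = pd.DataFrame({"site_id": ["a"], "chrom": "chr1",
                              "center": [10_000],
                              "enrichment_weight": [50.0]})
        p = ReadSimParams(depth_per_unit=100, background_rate=1e-3,
                          input_rate=1e-3)
        tags = simulate_tags(20_000, sites, p, seed=14)
        mids = (tags["input_c1_r1"]["start"] + tags["input_c1_r1"]["end"]) // 2
        near = ((mids > 9_000) & (mids < 11_000)).sum()
        # uniform background: ~10% of tags in 10% of the genome
        assert near < 0.3 * len(mids)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ReadSimParams(depth_per_unit=-1).validate()


class TestGeneModels:
    def test_requested_gene_count_and_strand_aware_tss(self):
        gm = write_gene_models(1_000_000, 3, seed=15)
        assert len(gm) == 3
        models = gene_models_from_table(gm)
        for m in models:
            assert m.tss == (m.tx_start if m.strand == "+" else m.tx_end)

    def test_round_trip_through_annotate_reader(self, tmp_path):
        from grchip.annotate import read_gene_models, write_gene_models_table
        gm = write_gene_models(500_000, 5, seed=16)
        path = tmp_path / "genes.tsv"
        write_gene_models_table(gm, path)
        back = read_gene_models(path)
        pd.testing.assert_frame_equal(gm, back)

    def test_genes_do_not_overlap(self):
        gm = write_gene_models(300_000, 10, seed=17)
        ordered = gm.sort_values("txStart")
        assert (ordered["txStart"].to_numpy()[1:]
                >= ordered["txEnd"].to_numpy()[:-1]).all()

    def test_too_small_genome_raises(self):
        with pytest.raises(ValueError):
            write_gene_models(10_000, 100, seed=18)
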