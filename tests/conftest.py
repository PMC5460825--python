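"""Shared fixtures: small planted datasets and the full-scale default run.

The ``default_run`` fixture is the flagship synthetic experiment: the
default composition (7298 sites mirroring the reported motif accounting)
planted on a 10 Mb motif-free background, two conditions x two replicates
of ChIP plus matched inputs under the null (condition effect 1.0), pushed
through the whole pipeline.  It is session-scoped because it takes a
couple of minutes; the pipeline keeps every concordant peak
(top fraction 1.0) since the planted site set already emulates the
post-selection peak list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from grchip.config import RunConfig, SampleSpec, SimConfig, StageParams
from grchip.motifs import default_motif_library
from grchip.pipeline import run_pipeline, run_simulation
from grchip.simdata import (ClassConfig, CompositionConfig,
                            generate_background_genome, plant_sites)

FLAGSHIP_SEED = 1


@pytest.fixture(scope="session")
def small_genome() -> str:
    """60 kb motif-free background."""
    return generate_background_genome(60_000, 0.5, seed=101)


def small_composition(n_sites: int = 40) -> CompositionConfig:
    return CompositionConfig(n_sites=n_sites, peak_halfwidth=100, classes={
        "full_gre": ClassConfig(count=n_sites // 2, offset_sd=15, weight=1.0),
        "gre_half": ClassConfig(count=n_sites // 4, offset_sd=25, weight=0.4),
        "nf1_half": ClassConfig(count=n_sites // 2, offset_sd=60, weight=0.6),
        "bhlh": ClassConfig(count=n_sites // 5, offset_sd=60, weight=0.6),
        "ngre": ClassConfig(count=n_sites // 10, offset_sd=60, weight=0.0),
    }, ngre_with_gre=max(0, n_sites // 10 - 1))


@pytest.fixture(scope="session")
def small_planted(small_genome):
    """40 sites planted into the 60 kb background."""
    genome, sites, instances = plant_sites(
        small_genome, small_composition(), seed=102)
    return genome, sites, instances


@pytest.fixture(scope="session")
def motif_library():
    return default_motif_library()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> dict:
    """Default-scale simulation + full pipeline (null design)."""
    root = tmp_path_factory.mktemp("default_run")
    sim_cfg = SimConfig()
    run_simulation(sim_cfg, root / "sim", seed=FLAGSHIP_SEED)
    samples = [
        SampleSpec(f"chip_c{c}_r{r}", "A" if c == 1 else "B",
                   str(root / "sim" / f"chip_c{c}_r{r}.bed"),
                   str(root / "sim" / f"input_c{c}_r{r}.bed"))
        for c in (1, 2) for r in (1, 2)]
    cfg = RunConfig(
        genome=str(root / "sim" / "genome.fa"),
        gene_models=str(root / "sim" / "gene_models.tsv"),
        samples=samples,
        params=StageParams(run_kmer=False, top_fraction=1.0),
        seed=FLAGSHIP_SEED, outdir=str(root / "run"))
    result = run_pipeline(cfg)
    out = {
        "root": root,
        "sim": root / "sim",
        "run": Path(result["outdir"]),
        "result": result,
        "truth_sites": pd.read_csv(root / "sim" / "truth_sites.tsv",
                                   sep="\t"),
        "genome_path": root / "sim" / "genome.fa",
        "pooled": pd.read_csv(Path(result["outdir"]) / "peaks_pooled.tsv",
                              sep="\t"),
        "counts": pd.read_csv(Path(result["outdir"]) / "counts.tsv",
                              sep="\t", index_col=0),
        "architecture": pd.read_csv(
            Path(result["outdir"]) / "architecture.tsv", sep="\t"),
    }
    return out


def covered(centers: np.ndarray, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean per truth center: contained in some peak interval."""
    hit = np.zeros(len(centers), dtype=bool)
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    j = np.searchsorted(starts, centers, side="right") - 1
    running_max_end = np.maximum.accumulate(ends)
    ok = j >= 0
    hit[ok] = running_max_end[j[ok]] > centers[ok]
    return hit
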