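"""Structured run configuration with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .peakcall import HotspotParams
from .simdata import CompositionConfig, ReadSimParams, default_composition


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class SampleSpec:
    """One ChIP sample with its matched input."""

    name: str
    group: str
    chip: str
    input: str


@dataclass
class StageParams:
    """Tunable stage parameters with the pipeline's standard defaults."""

    extension_length: int = 150
    bin_size: int = 50
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    top_fraction: float = 0.2
    count_halfwidth: int = 100
    histogram_halfwidth: int = 1000
    histogram_bin: int = 10
    heatmap_flank: int = 3000
    kmer_widths: tuple[int, ...] = (6, 8, 10, 12, 14, 16)
    run_kmer: bool = True


@dataclass
class RunConfig:
    """Analysis-pipeline configuration (tags through motif architecture)."""

    genome: str
    gene_models: str
    samples: list[SampleSpec]
    mask: str | None = None
    params: StageParams = field(default_factory=StageParams)
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self):
        groups = {s.group for s in self.samples}
        if len(groups) != 2:
            raise ValueError("exactly two sample groups required")

    def validate_paths(self):
        for p in [self.genome, self.gene_models, self.mask] + \
                [x for s in self.samples for x in (s.chip, s.input)]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    _check_keys(raw, {"paths", "samples", "params", "seed", "outdir"},
                "top level")
    paths = raw.get("paths", {})
    _check_keys(paths, {"genome", "gene_models", "mask"}, "paths")
    samples = []
    for s in raw.get("samples", []):
        _check_keys(s, {"name", "group", "chip", "input"}, "samples")
        samples.append(SampleSpec(**s))
    params_d = dict(raw.get("params", {}))
    _check_keys(params_d, {f.name for f in
                           StageParams.__dataclass_fields__.values()},
                "params")
    if "hotspot" in params_d:
        _check_keys(params_d["hotspot"],
                    {f.name for f in
                     HotspotParams.__dataclass_fields__.values()}, "hotspot")
        params_d["hotspot"] = HotspotParams(**params_d["hotspot"])
    if "kmer_widths" in params_d:
        params_d["kmer_widths"] = tuple(params_d["kmer_widths"])
    base = Path(path).parent

    def _resolve(p):
        return None if p is None else str((base / p))

    return RunConfig(
        genome=_resolve(paths["genome"]),
        gene_models=_resolve(paths["gene_models"]),
        mask=_resolve(paths.get("mask")),
        samples=[SampleSpec(s.name, s.group, _resolve(s.chip),
                            _resolve(s.input)) for s in samples],
        params=StageParams(**params_d),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "results/run")))


@dataclass
class SimConfig:
    """Synthetic-dataset configuration for the simulate stage."""

    genome_length: int = 10_000_000
    gc: float = 0.5
    n_genes: int = 200
    chrom: str = "chr1"
    composition: CompositionConfig = field(default_factory=default_composition)
    read_params: ReadSimParams = field(default_factory=ReadSimParams)
    n_conditions: int = 2
    n_replicates: int = 2
    simulate_reads: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def load_sim_config(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {f.name for f in SimConfig.__dataclass_fields__.values()}
    _check_keys(raw, allowed, "simulate config")
    if "composition" in raw and raw["composition"] not in (None, "default"):
        raw["composition"] = CompositionConfig.from_dict(raw["composition"])
    elif "composition" in raw:
        raw["composition"] = default_composition()
    if "read_params" in raw:
        raw["read_params"] = ReadSimParams(**raw["read_params"])
    return SimConfig(**raw)
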