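"""End-to-end orchestration of the binding-specificity workflow.

Stages — simulate selection reads, prepare cassettes, discover the
motif, scan and annotate a genome, fit binding kinetics, compare
expression — hand off through plain files in the output directory so
each stage is independently runnable and testable. A run manifest
records per-stage parameters and SHA-256 hashes of inputs/outputs;
reruns with identical config and seed give identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .datasets import CONSENSUS, BLI_CONCENTRATIONS
from .discovery import discover_motif
from .expression import differential_expression, to_frame
from .kinetics import Sensorgram, fit_global
from .pwm import ConsensusSpec, consensus_string
from .readprep import ReadRecord, prepare_cassettes, sample_reads
from .scan import annotate_hits, scan_genome
from .simulate import (ExpressionSimSpec, SelectionLibraryConfig,
                       SyntheticGenomeSpec, build_synthetic_genome,
                       planted_read_pool, simulate_expression,
                       simulate_sensorgram)


@dataclass
class PipelineConfig:
    """Parameters for every stage; anything omitted uses the defaults
    of the underlying module."""
    seed: int = 0
    outdir: str = "pipeline_out"
    # selection / library
    n_reads: int = 500
    planted_fraction: float = 0.7
    consensus: str = CONSENSUS
    cassette_length: int = 24
    # discovery
    width_range: tuple = (12, 20)
    palindromic: bool = True
    n_starts: int = 5
    # genome scan
    genome_length: int = 20000
    n_planted_sites: int = 4
    p_threshold: float = 1e-4
    window: tuple = (-200, 20)
    # kinetics
    kon: float = 131308.0
    koff: float = 2.907e-4
    rmax: float = 1.0
    # expression
    n_genes: int = 200
    planted_logfc: dict = field(default_factory=lambda: {"gene0000": 2.62})
    noise_sd: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if len(self.consensus) > self.cassette_length:
            raise ValueError("consensus longer than cassette")
        if self.genome_length < len(self.consensus):
            raise ValueError("genome too short for planted consensus")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    completed: bool = False

    def record(self, name: str, outputs: list[Path], **params) -> None:
        self.stages.append({
            "stage": name,
            "params": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "completed": self.completed}, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on synthetic inputs; returns the manifest.

    Failure in any stage halts the run; the manifest (written to the
    output directory either way) records partial completion.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    manifest_path = out / "manifest.json"
    try:
        _run_stages(config, out, manifest)
        manifest.completed = True
    finally:
        manifest.write(manifest_path)
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path,
                manifest: RunManifest) -> None:
    rng = np.random.default_rng(cfg.seed)
    library = SelectionLibraryConfig(cassette_length=cfg.cassette_length,
                                     seed=cfg.seed)

    # simulate: selection reads
    reads, planted = planted_read_pool(
        cfg.consensus, cfg.n_reads, cfg.planted_fraction, library,
        seed=int(rng.integers(2 ** 31)))
    reads_fa = out / "reads.fasta"
    tio.write_fasta(reads_fa, reads)
    manifest.record("simulate_reads", [reads_fa], n_reads=cfg.n_reads,
                    planted_fraction=cfg.planted_fraction)

    # prep: cassette extraction + dedup + subsample
    records = [ReadRecord(f"read{i+1}", s) for i, s in enumerate(reads)]
    cassettes = prepare_cassettes(records, library)
    n_sample = min(len(cassettes.sequences), cfg.n_reads)
    sampled = sample_reads(cassettes, n_sample,
                           seed=int(rng.integers(2 ** 31)))
    cass_fa = out / "cassettes.fasta"
    tio.write_fasta(cass_fa, sampled)
    manifest.record("prep", [cass_fa], **cassettes.stats)

    # discover
    model = discover_motif(sampled, cfg.width_range,
                           palindromic=cfg.palindromic,
                           n_starts=cfg.n_starts,
                           seed=int(rng.integers(2 ** 31)))
    motif_path = out / "motif.meme"
    tio.write_meme(motif_path, model.pwm, name="selected",
                   nsites=model.n_sites, e_value=model.e_value)
    manifest.record("discover", [motif_path], width=model.width,
                    log10_e_value=model.log10_e_value,
                    consensus=consensus_string(model.pwm, ConsensusSpec()))

    # scan + annotate a synthetic genome with planted sites
    gap = cfg.genome_length // (cfg.n_planted_sites + 1)
    sites = tuple((cfg.consensus, gap * (i + 1), "+")
                  for i in range(cfg.n_planted_sites))
    genes = tuple((f"g{i+1}", "+", gap * (i + 1) + 30, f"op{i+1}",
                   "1/2") for i in range(cfg.n_planted_sites))
    genome, gene_df, element_df = build_synthetic_genome(
        SyntheticGenomeSpec(length=cfg.genome_length, planted_sites=sites,
                            gene_models=genes,
                            seed=int(rng.integers(2 ** 31))))
    hits = scan_genome(model.pwm, genome, p_threshold=cfg.p_threshold)
    annos = annotate_hits(hits, gene_df, element_df, window=cfg.window)
    hits_tsv = out / "hits.tsv"
    tio.write_hits(hits_tsv, hits)
    bed = out / "hits.bed"
    tio.write_bed(bed, hits)
    manifest.record("scan", [hits_tsv, bed], n_hits=len(hits),
                    n_proximal=sum(a.proximal for a in annos))

    # kinetics on simulated sensorgrams
    frames = simulate_sensorgram(cfg.kon, cfg.koff, cfg.rmax,
                                 list(BLI_CONCENTRATIONS),
                                 noise_sd=0.0, seed=cfg.seed)
    sens_csv = out / "sensorgrams.csv"
    tio.write_sensorgrams(sens_csv, frames)
    fit = fit_global([Sensorgram.from_frame(f) for f in frames])
    fit_json = out / "kinetic_fit.json"
    fit_json.write_text(json.dumps(
        {"kon": fit.kon, "koff": fit.koff, "kd": fit.kd,
         "r_squared": fit.r_squared}, indent=2))
    manifest.record("blifit", [sens_csv, fit_json], kd=fit.kd,
                    r_squared=fit.r_squared)

    # expression comparison
    matrix = simulate_expression(ExpressionSimSpec(
        n_genes=cfg.n_genes, planted_logfc=cfg.planted_logfc,
        noise_sd=cfg.noise_sd, seed=int(rng.integers(2 ** 31))))
    expr_tsv = out / "expression.tsv"
    tio.write_expression(expr_tsv, matrix)
    rows = differential_expression(matrix)
    dge_tsv = out / "dge.tsv"
    to_frame(rows).to_csv(dge_tsv, sep="\t", index=False)
    manifest.record("dge", [expr_tsv, dge_tsv],
                    n_significant=sum(r.adj_p < 0.05 for r in rows))
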