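"""End-to-end orchestration: simulate → scan → annotate → context → stats.

A run is driven by a RunConfig (YAML-loadable); every stage writes its
artifacts with a provenance header (tool version, config hash, seed) and
appends per-stage counts to the run log, so reruns with the same config
are byte-identical and the candidate partition can be audited afterwards.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, seqs
from .annotate import Thresholds, annotate_genome
from .context import (
    CompartmentMap,
    assign_compartment,
    cluster_insertions,
    derive_pericentromeric_euchromatin,
    associate_genes,
    windowed_density,
)
from .errors import ConfigurationError
from .families import build_family_library, read_library, write_library
from .search import ScanParams, index_genome, scan
from .simulate import SamplingParams, default_blueprints, synthesize_genome
from .stats import condition_ratio_by_age, divergence_histogram, summarize_tables

log = logging.getLogger("ltrscape")

MODES = ("simulate", "scan", "annotate", "context", "stats", "all")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "ltrscape_run"
    # simulation
    n_families: int = 12
    n_insertions: int = 160
    arm_length: int = 700_000
    n_arms: int = 2
    pe_size: int = 60_000  # scaled-down pericentromeric-euchromatin walk
    # inputs for non-simulate runs (default to the simulate outputs)
    genome: str | None = None
    library: str | None = None
    segments: str | None = None
    compartments: str | None = None
    genes: str | None = None
    # analysis parameters
    window: int = 50_000
    cluster_distance: int = 10_000
    cluster_mode: str = "edge"
    gene_flank: int = 1000
    thresholds: dict = field(default_factory=dict)
    scan_params: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def meta(self) -> dict:
        return {"tool": f"ltrscape {__version__}", "config": self.hash(), "seed": self.seed}

    def out(self, name: str) -> Path:
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p / name

    def thresholds_obj(self) -> Thresholds:
        return Thresholds(**self.thresholds)

    def scan_obj(self) -> ScanParams:
        return ScanParams(**self.scan_params)


def _require(cfg: RunConfig, name: str, default_name: str) -> Path:
    path = getattr(cfg, name) or str(Path(cfg.outdir) / default_name)
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"required input {name!r} not found: {p}")
    return p


def run_simulate(cfg: RunConfig) -> dict:
    families = build_family_library(cfg.n_families, seed=cfg.seed)
    blueprints = default_blueprints(cfg.arm_length, cfg.n_arms)
    params = SamplingParams(n_insertions=cfg.n_insertions, **cfg.sampling)
    sg = synthesize_genome(blueprints, families, params=params, seed=cfg.seed)
    meta = cfg.meta()
    seqs.write_fasta(cfg.out("genome.fa"), sg.genome)
    write_library(families, cfg.out("library.fa"), cfg.out("library_segments.tsv"))
    io.write_bed(sg.compartments, cfg.out("compartments.bed"), meta)
    io.write_gff3(sg.genes, cfg.out("genes.gff3"), meta)
    io.write_table(sg.truth_frame(), cfg.out("truth.tsv"), meta)
    log.info("simulate: %d arms, %d planted copies", len(sg.genome), len(sg.truth))
    return {"planted": len(sg.truth)}


def run_scan(cfg: RunConfig) -> dict:
    genome = seqs.read_fasta(_require(cfg, "genome", "genome.fa"))
    families = read_library(
        _require(cfg, "library", "library.fa"),
        _require(cfg, "segments", "library_segments.tsv"),
    )
    params = cfg.scan_obj()
    candidates = scan(families, genome, params, index=index_genome(genome, params.k))
    rows = [
        {
            "family": c.family, "strand": c.strand, "arm": c.arm,
            "start": c.start + 1, "end": c.end,
            "cons_start": c.cons_start + 1, "cons_end": c.cons_end,
            "n_hsps": len(c.alignments),
            "score": sum(h.score for h in c.alignments),
        }
        for c in candidates
    ]
    io.write_table(pd.DataFrame(rows), cfg.out("candidates.tsv"), cfg.meta())
    log.info("scan: candidates found=%d", len(candidates))
    return {"candidates": len(candidates)}


def _scan_and_annotate(cfg: RunConfig):
    genome = seqs.read_fasta(_require(cfg, "genome", "genome.fa"))
    families = read_library(
        _require(cfg, "library", "library.fa"),
        _require(cfg, "segments", "library_segments.tsv"),
    )
    params = cfg.scan_obj()
    candidates = scan(families, genome, params, index=index_genome(genome, params.k))
    result = annotate_genome(genome, families, candidates, cfg.thresholds_obj())
    return genome, families, candidates, result


def run_annotate(cfg: RunConfig) -> dict:
    _genome, _families, candidates, result = _scan_and_annotate(cfg)
    io.write_copies(result.copies, cfg.out("copies.tsv"), cfg.meta())
    c = result.counts
    log.info(
        "annotate: candidates=%d rejected_family=%d rejected_overlap=%d "
        "unreliable=%d annotated=%d",
        c["candidates"], c["rejected_family"], c["rejected_overlap"],
        c["unreliable"], c["annotated"],
    )
    return dict(result.counts)


def run_context(cfg: RunConfig) -> dict:
    copies = io.read_copies(_require_path(cfg, "copies.tsv"))
    cmap = CompartmentMap.from_intervals(
        io.read_bed(_require(cfg, "compartments", "compartments.bed"))
    )
    cmap = derive_pericentromeric_euchromatin(cmap, cfg.pe_size)
    genes = io.read_gff3(_require(cfg, "genes", "genes.gff3"))
    meta = cfg.meta()

    for c in copies:
        c.compartment = assign_compartment(c, cmap)
    cluster_rows = []
    n_clustered_total = 0
    cluster_id = 0
    for arm in sorted({c.arm for c in copies}):
        arm_copies = [c for c in copies if c.arm == arm]
        clusters, n_clustered = cluster_insertions(
            arm_copies, cfg.cluster_distance, cfg.cluster_mode
        )
        n_clustered_total += n_clustered
        for cl in clusters:
            if len(cl) < 2:
                continue
            cluster_id += 1
            for i in cl:
                arm_copies[i].cluster = cluster_id
                cluster_rows.append(
                    {"cluster": cluster_id, "arm": arm, "copy_id": arm_copies[i].id}
                )
    io.write_copies(copies, cfg.out("copies.tsv"), meta)
    io.write_table(pd.DataFrame(cluster_rows), cfg.out("clusters.tsv"), meta)

    npe_copies = [c for c in copies if c.compartment == "NPE"]
    assoc = associate_genes(npe_copies, genes, cfg.gene_flank)
    io.write_table(
        pd.DataFrame([a.__dict__ for a in assoc]), cfg.out("associations.tsv"), meta
    )

    windows = []
    for arm in sorted(cmap.arms):
        df = windowed_density(copies, arm, cmap.arm_length(arm), cfg.window)
        df.insert(0, "arm", arm)
        windows.append(df)
    io.write_table(pd.concat(windows, ignore_index=True), cfg.out("windows.tsv"), meta)
    log.info(
        "context: copies=%d in_clusters=%d gene_associations=%d",
        len(copies), n_clustered_total, len(assoc),
    )
    return {
        "copies": len(copies),
        "in_clusters": n_clustered_total,
        "gene_associations": len(assoc),
    }


def _require_path(cfg: RunConfig, name: str) -> Path:
    p = Path(cfg.outdir) / name
    if not p.exists():
        raise ConfigurationError(f"required input not found: {p}")
    return p


def run_stats(cfg: RunConfig) -> dict:
    copies = io.read_copies(_require_path(cfg, "copies.tsv"))
    cmap = CompartmentMap.from_intervals(
        io.read_bed(_require(cfg, "compartments", "compartments.bed"))
    )
    cmap = derive_pericentromeric_euchromatin(cmap, cfg.pe_size)
    genes = io.read_gff3(_require(cfg, "genes", "genes.gff3"))
    meta = cfg.meta()

    arms_df, het_df, eu_df = summarize_tables(copies, cmap, genes, cfg.cluster_mode)
    io.write_table(arms_df, cfg.out("table_arms.tsv"), meta)
    io.write_table(het_df, cfg.out("table_heterochromatin.tsv"), meta)
    io.write_table(eu_df, cfg.out("table_euchromatin.tsv"), meta)

    hist = divergence_histogram(copies)
    report = {"divergence_histogram": hist}
    try:
        report["condition_ratio_by_age"] = condition_ratio_by_age(copies)
    except Exception as exc:  # empty age class on tiny runs
        report["condition_ratio_by_age"] = {"error": str(exc)}
    io.write_json(report, cfg.out("stats.json"), meta)
    log.info("stats: tables and report written")
    return {"regions": len(het_df) + len(eu_df) + len(arms_df)}


STAGES = {
    "simulate": run_simulate,
    "scan": run_scan,
    "annotate": run_annotate,
    "context": run_context,
    "stats": run_stats,
}


def run(cfg: RunConfig, mode: str = "all") -> dict:
    """Execute one stage or the full chain; returns the per-stage counts."""
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    stages = ["simulate", "annotate", "context", "stats"] if mode == "all" else [mode]
    manifest = {"version": __version__, "config": cfg.hash(), "seed": cfg.seed, "stages": {}}
    for stage in stages:
        try:
            manifest["stages"][stage] = STAGES[stage](cfg)
        except Exception:
            log.error("stage %s failed", stage)
            raise
    io.write_json(manifest, cfg.out("manifest.json"))
    return manifest
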