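"""End-to-end orchestration: simulate -> process -> scan -> mesas/consensus.

Every stage is a pure function of the configuration and its inputs; a rerun
with the same config reproduces the same outputs.  All analysis thresholds
default to the printed values of the protocol this pipeline implements
(mapq >= 5, scan p < 1e-3, mesa increase >= 30 with motif p <= 0.0025 at
offsets 8-10, trailing gap <= 5, 100 bp consensus/overlap windows, +/-250 bp
density windows with 20 bp triangular smoothing and a 1/500 width
threshold, 100 edges/strand sampled at increase >= 100).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Any

import yaml

from . import io as efio
from .density import motif_density_profile
from .mesas import (
    call_mesas,
    detect_edges,
    mesa_statistics,
    pair_mesas,
    sample_edge_matrix,
)
from .motifs import MotifModel, forkhead_like_motif, read_matrix_file, scan_sequence
from .peaks import (
    Peak,
    call_summits,
    chip_efficiency,
    consensus_summits,
    motif_presence_stats,
    write_summits_bed,
)
from .reads import BOTTOM, TOP, build_depth_track, export_bedgraph, filter_reads
from .simulate import (
    SimConfig,
    generate_genome,
    plant_loci,
    simulate_exo_reads,
    write_dataset,
)

logger = logging.getLogger("exofoot")


class ConfigurationError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the protocol's printed values."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    seed: int = 0
    # external inputs (override simulation when all given)
    genome_path: str | None = None
    reads_path: str | None = None
    blacklist_path: str | None = None
    motif_path: str | None = None
    motif_format: str = "jaspar"
    # analysis parameters
    min_mapq: int = 5
    scan_p_threshold: float = 1e-3
    mesa_min_increase: int = 30
    mesa_offset_min: int = 8
    mesa_offset_max: int = 10
    mesa_p_max: float = 0.0025
    trailing_gap_max: int = 5
    consensus_window: int = 100
    overlap_window: int = 100
    density_halfwidth: int = 250
    smoothing_window: int = 20
    width_threshold: float = 1.0 / 500.0
    motif_stat_p_max: float = 0.0025
    sample_n_per_strand: int = 100
    sample_window: int = 100
    sample_min_increase: int = 100
    summit_min_height: float = 30.0
    summit_min_separation: int = 200
    peak_halfwidth: int = 100
    n_replicates: int = 3

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        """Fail fast, before any compute, on missing inputs."""
        for label, path in (
            ("genome_path", self.genome_path),
            ("reads_path", self.reads_path),
            ("blacklist_path", self.blacklist_path),
            ("motif_path", self.motif_path),
        ):
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"{label} does not exist: {path}")
        if (self.genome_path is None) != (self.reads_path is None):
            raise ConfigurationError(
                "genome_path and reads_path must be given together"
            )


def _load_motif(config: PipelineConfig) -> MotifModel:
    if config.motif_path is not None:
        return read_matrix_file(config.motif_path, config.motif_format)
    return forkhead_like_motif()


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict[str, Any]:
    """Run every stage, write all outputs under ``out_dir``, return the summary."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    motif = _load_motif(config)
    summary: dict[str, Any] = {"seed": config.seed}

    simulated = config.genome_path is None
    if simulated:
        logger.info("stage simulate: genome %d bp, %d single + %d paired loci",
                    config.sim.genome_length, config.sim.n_single_loci,
                    config.sim.n_paired_loci)
        genome = generate_genome(
            config.sim.genome_length, config.sim.gc_fraction, config.sim.seed
        )
        genome, truth = plant_loci(genome, config.sim, motif)
        reads = simulate_exo_reads(truth, config.sim)
        write_dataset(genome, reads, truth, os.path.join(out_dir, "dataset"),
                      config.sim)
        contig = config.sim.contig
    else:
        logger.info("stage load: %s / %s", config.genome_path, config.reads_path)
        genomes = efio.read_fasta(config.genome_path)
        contig, genome = next(iter(genomes.items()))
        if config.reads_path.endswith(".bed"):
            reads = efio.read_reads_bed(config.reads_path)
        else:
            reads = efio.read_sam(config.reads_path)
        truth = None

    blacklist = (
        efio.read_interval_bed(config.blacklist_path)
        if config.blacklist_path
        else None
    )
    filtered = filter_reads(reads, config.min_mapq, blacklist)
    logger.info("stage filter: %d of %d reads retained", len(filtered), len(reads))
    track = build_depth_track(filtered, len(genome), contig)
    export_bedgraph(track, TOP, os.path.join(out_dir, "depth_top.bedgraph"))
    export_bedgraph(track, BOTTOM, os.path.join(out_dir, "depth_bottom.bedgraph"))
    summary["n_reads"] = len(reads)
    summary["n_reads_filtered"] = len(filtered)

    logger.info("stage scan: motif %s, p < %g", motif.name, config.scan_p_threshold)
    hits = scan_sequence(genome, motif, config.scan_p_threshold, contig)
    efio.write_hits_bed(os.path.join(out_dir, "motif_hits.bed"), hits)
    summary["n_motif_hits"] = len(hits)

    logger.info("stage mesas: min increase %d", config.mesa_min_increase)
    edges = detect_edges(track, TOP, config.mesa_min_increase) + detect_edges(
        track, BOTTOM, config.mesa_min_increase
    )
    mesas = call_mesas(
        edges,
        hits,
        config.mesa_min_increase,
        (config.mesa_offset_min, config.mesa_offset_max),
        config.mesa_p_max,
    )
    pairs = pair_mesas(mesas, config.trailing_gap_max)
    stats = mesa_statistics(mesas, pairs)
    _write_mesas(out_dir, mesas, pairs, stats)
    sample_table, sample_density = sample_edge_matrix(
        edges, hits, config.sample_n_per_strand, config.sample_window,
        config.sample_min_increase, seed=config.seed,
    )
    sample_table.to_csv(os.path.join(out_dir, "edge_sample.tsv"), sep="\t", index=False)
    sample_density.to_csv(
        os.path.join(out_dir, "edge_sample_density.tsv"), sep="\t", index=False
    )
    summary.update(
        n_edges=len(edges),
        n_mesas=stats.n_mesas,
        n_pairs=stats.n_pairs,
        modal_edge_to_motif=stats.edge_to_motif_mode,
        modal_edge_distance=stats.edge_distance_mode,
        modal_motif_overlap=stats.motif_overlap_mode,
    )

    logger.info("stage summits")
    summits = call_summits(track, config.summit_min_height, config.summit_min_separation)
    write_summits_bed(os.path.join(out_dir, "summits.bed"), summits)
    summary["n_summits"] = len(summits)
    positions = [p.summit for p in summits]

    if simulated and config.n_replicates >= 3:
        logger.info("stage consensus: %d replicates", config.n_replicates)
        rep_peaks = []
        for r in range(3):
            rep_reads = filter_reads(
                simulate_exo_reads(truth, config.sim, stream=r + 1),
                config.min_mapq, blacklist,
            )
            rep_track = build_depth_track(rep_reads, len(genome), contig)
            rep_peaks.append(
                call_summits(rep_track, config.summit_min_height,
                             config.summit_min_separation)
            )
        consensus = consensus_summits(*rep_peaks, window=config.consensus_window)
        write_summits_bed(
            os.path.join(out_dir, "consensus_summits.bed"),
            [Peak(c.contig, c.summit, c.strength) for c in consensus],
        )
        summary["n_consensus_summits"] = len(consensus)

    if positions:
        logger.info("stage density")
        profile = motif_density_profile(
            positions, hits, config.density_halfwidth,
            config.smoothing_window, config.width_threshold,
        )
        profile.to_frame().to_csv(
            os.path.join(out_dir, "motif_density.tsv"), sep="\t", index=False
        )
        summary["characteristic_width"] = profile.characteristic_width
        if filtered:
            summary["chip_efficiency"] = chip_efficiency(
                filtered, summits, config.peak_halfwidth
            )
        frequency, _ = motif_presence_stats(
            positions, hits, config.consensus_window, config.motif_stat_p_max
        )
        summary["motif_frequency"] = frequency

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    cfg_echo = dataclasses.asdict(config)
    with open(os.path.join(out_dir, "pipeline_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg_echo, fh, sort_keys=True)
    logger.info("pipeline complete: %s", os.path.join(out_dir, "summary.json"))
    return summary


def _write_mesas(out_dir, mesas, pairs, stats) -> None:
    with open(os.path.join(out_dir, "mesas.bed"), "w") as fh:
        for i, m in enumerate(mesas):
            fh.write(
                f"{m.edge.contig}\t{m.edge.position}\t{m.edge.position + 1}"
                f"\tmesa{i:06d}\t{m.edge.depth_increase}\t{m.edge.strand}"
                f"\t{m.motif.start}\t{m.motif.end}\t{m.motif.pvalue:.6g}"
                f"\t{m.edge_to_motif}\n"
            )
    with open(os.path.join(out_dir, "mesa_pairs.bed"), "w") as fh:
        for i, p in enumerate(pairs):
            fh.write(
                f"{p.top.edge.contig}\t{p.top.edge.position}"
                f"\t{p.bottom.edge.position + 1}\tpair{i:06d}\t0\t+"
                f"\t{p.edge_distance}\t{p.motif_overlap}\t{p.trailing_gap}\n"
            )
    with open(os.path.join(out_dir, "mesa_histograms.tsv"), "w") as fh:
        fh.write("statistic\tvalue\tcount\n")
        for label, hist in (
            ("edge_to_motif", stats.edge_to_motif_hist),
            ("edge_distance", stats.edge_distance_hist),
            ("motif_overlap", stats.motif_overlap_hist),
        ):
            for v, c in hist.items():
                fh.write(f"{label}\t{v}\t{c}\n")
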