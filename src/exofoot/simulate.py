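"""Synthetic ChIP-exo / ChIP-seq datasets with a truth layer.

The simulator emulates the two library structures that distinguish the
assays.  In ChIP-exo, lambda exonuclease digests each strand 5'->3' up to
the protein-DNA crosslink, so a stably bound factor leaves two overlapping
read populations whose 5' ends pile up at the protection boundary of each
strand.  In conventional ChIP-seq, reads are the sequenced ends of sonicated
fragments, giving two populations shifted to opposite sides of the site.

Loci are planted as motif instances written into a random genome, with
protection edges recorded a fixed offset upstream (in strand reading
direction) of each motif start.  Paired loci carry palindromically oriented
motif dimers protected on both strands.  Every planted locus is recorded in
a :class:`TruthRecord` so detection can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import io as efio
from .motifs import MotifModel, reverse_complement
from .reads import BOTTOM, TOP, AlignedRead

#: minimum separation between planted footprints, in bases
LOCUS_SPACING = 2000
_SLOT = LOCUS_SPACING + 100
_MARGIN = 600


class CapacityError(ValueError):
    """The genome is too short to host the requested loci."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Coverage, jitter, background and low-mapq defaults are free parameters
    of the simulator chosen at realistic Illumina ChIP-exo scale; the
    geometric defaults (36 nt reads, 9 bp edge-to-motif offset, 33 bp
    paired-edge distance, 3 bp palindromic overlap) are the characteristic
    footprint geometry of a forkhead-family factor.
    """

    genome_length: int = 1_000_000
    gc_fraction: float = 0.41
    n_single_loci: int = 100
    n_paired_loci: int = 0
    edge_motif_offset: int = 9
    paired_edge_distance: int = 33
    motif_overlap: int = 3
    pairing_mode: str = "by_edge_distance"
    reads_per_locus: float = 100.0
    background_rate: float = 0.5
    jitter_sd: float = 1.0
    read_length: int = 36
    lowmapq_fraction: float = 0.05
    motif_instance_mode: str = "consensus"
    contig: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.n_single_loci < 0 or self.n_paired_loci < 0:
            raise ValueError("locus counts must be non-negative")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.pairing_mode not in ("by_edge_distance", "by_motif_overlap"):
            raise ValueError(f"unknown pairing_mode: {self.pairing_mode!r}")
        if self.motif_instance_mode not in ("consensus", "sampled"):
            raise ValueError(f"unknown motif_instance_mode: {self.motif_instance_mode!r}")
        if not 0 <= self.lowmapq_fraction <= 1:
            raise ValueError("lowmapq_fraction must be in [0, 1]")
        if self.jitter_sd < 0 or self.background_rate < 0 or self.reads_per_locus < 0:
            raise ValueError("rates must be non-negative")

    def rng(self, stream: int, substream: int = 0) -> np.random.Generator:
        """Independent deterministic generator per (seed, stream)."""
        return np.random.default_rng([self.seed, stream, substream])


@dataclasses.dataclass
class TruthRecord:
    """One planted locus: motif interval(s), protection edge(s), kind."""

    locus_id: str
    kind: str  # single_top | single_bottom | paired | background
    motif_intervals: list[tuple[int, int, str]]
    protection_edges: list[tuple[int, str]]
    contig: str = "chr1"


def generate_genome(length: int, gc_fraction: float = 0.41, seed: int = 0) -> str:
    """Random genome with i.i.d. bases at the given GC content."""
    if length < 0:
        raise ValueError("genome length must be non-negative")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 0, 0])
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")
    ).decode("ascii")


def _instance(motif: MotifModel, mode: str, rng: np.random.Generator) -> str:
    return motif.consensus if mode == "consensus" else motif.sample_instance(rng)


def plant_loci(
    genome: str, config: SimConfig, motif: MotifModel
) -> tuple[str, list[TruthRecord]]:
    """Write motif instances into the genome and record the truth.

    Single loci get one motif and one protection edge ``edge_motif_offset``
    bases upstream of the motif start in reading direction (a bottom-strand
    motif therefore has its edge at a *higher* reference coordinate than
    its interval).  Paired loci get palindromically oriented motif dimers
    positioned by ``pairing_mode``, with an edge on each strand.  Planted
    footprints are kept >= 2 kb apart.
    """
    L = motif.length
    if L >= 100:
        raise ValueError("motif length must be < 100")
    off = config.edge_motif_offset
    n_total = config.n_single_loci + config.n_paired_loci
    if n_total == 0:
        return genome, []

    usable = len(genome) - 2 * _MARGIN
    n_slots = max(usable // _SLOT, 0)
    if n_slots < n_total:
        need = 2 * _MARGIN + n_total * _SLOT
        raise CapacityError(
            f"genome of {len(genome)} bp hosts at most {n_slots} loci "
            f"{LOCUS_SPACING} bp apart; {n_total} requested "
            f"(needs >= {need} bp, short by {need - len(genome)} bp)"
        )

    rng = config.rng(1)
    slots = np.sort(rng.permutation(n_slots)[:n_total])
    jitters = rng.integers(0, 80, size=n_total)
    single_is_top = rng.random(config.n_single_loci) < 0.5

    seq = bytearray(genome, "ascii")
    truth: list[TruthRecord] = []

    def write(start: int, word: str) -> None:
        seq[start : start + len(word)] = word.encode("ascii")

    for i in range(n_total):
        anchor = _MARGIN + int(slots[i]) * _SLOT + int(jitters[i])
        locus_id = f"locus{i:05d}"
        if i < config.n_single_loci:
            inst = _instance(motif, config.motif_instance_mode, rng)
            if single_is_top[i]:
                s = anchor
                write(s, inst)
                truth.append(
                    TruthRecord(locus_id, "single_top", [(s, s + L, TOP)],
                                [(s - off, TOP)], config.contig)
                )
            else:
                s = anchor
                write(s, reverse_complement(inst))
                truth.append(
                    TruthRecord(locus_id, "single_bottom", [(s, s + L, BOTTOM)],
                                [(s + L - 1 + off, BOTTOM)], config.contig)
                )
        else:
            top_inst = _instance(motif, config.motif_instance_mode, rng)
            bottom_inst = _instance(motif, config.motif_instance_mode, rng)
            s = anchor
            if config.pairing_mode == "by_motif_overlap":
                mb_s = s + L - config.motif_overlap
            else:  # by_edge_distance
                # bottom edge = top edge + D;  edges sit `off` upstream of
                # each motif start in its strand's reading direction
                e_top = s - off
                e_bot = e_top + config.paired_edge_distance
                mb_s = e_bot - off + 1 - L
            mb_e = mb_s + L
            write(s, top_inst)
            write(mb_s, reverse_complement(bottom_inst))
            truth.append(
                TruthRecord(
                    locus_id,
                    "paired",
                    [(s, s + L, TOP), (mb_s, mb_e, BOTTOM)],
                    [(s - off, TOP), (mb_e - 1 + off, BOTTOM)],
                    config.contig,
                )
            )
    return seq.decode("ascii"), truth


# ----------------------------------------------------------------------
# read simulation

def _jitter(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n, dtype=np.int64)
    trunc = int(np.ceil(3 * sd))
    return np.clip(np.rint(rng.normal(0.0, sd, n)), -trunc, trunc).astype(np.int64)


def _background_reads(
    rng: np.random.Generator, config: SimConfig
) -> list[tuple[int, str]]:
    n = rng.poisson(config.background_rate * config.genome_length / 1000.0)
    hi = config.genome_length - config.read_length + 1
    if hi <= 0 or n == 0:
        return []
    starts = rng.integers(0, hi, size=n)
    strands = rng.integers(0, 2, size=n)
    return [(int(s), TOP if t == 0 else BOTTOM) for s, t in zip(starts, strands)]


def _assign_mapq(
    rng: np.random.Generator, intervals: list[tuple[int, int, str]],
    config: SimConfig,
) -> list[AlignedRead]:
    n = len(intervals)
    low = rng.random(n) < config.lowmapq_fraction
    low_q = rng.integers(0, 5, size=n)
    high_q = rng.integers(5, 61, size=n)
    return [
        AlignedRead(config.contig, s, e, strand,
                    int(low_q[i]) if low[i] else int(high_q[i]))
        for i, (s, e, strand) in enumerate(intervals)
    ]


def simulate_exo_reads(
    truth: Sequence[TruthRecord], config: SimConfig, stream: int = 0
) -> list[AlignedRead]:
    """ChIP-exo reads: strand-specific 5' ends pinned at protection edges.

    Each protection edge emits Poisson(``reads_per_locus``) reads on its
    own strand whose 5' ends sit at the edge position plus rounded Gaussian
    jitter (truncated at +/-3 sd); reads extend ``read_length`` bases in
    reading direction.  Uniform background reads are added at
    ``background_rate`` per kb.  ``stream`` selects an independent noise
    realization (replicates) under the same seed.
    """
    rng = config.rng(2, stream)
    L = config.read_length
    intervals: list[tuple[int, int, str]] = []
    for record in truth:
        for pos, strand in record.protection_edges:
            n = rng.poisson(config.reads_per_locus)
            fives = pos + _jitter(rng, config.jitter_sd, n)
            for p in fives:
                if strand == TOP:
                    s, e = int(p), int(p) + L
                else:
                    s, e = int(p) - L + 1, int(p) + 1
                if s >= 0 and e <= config.genome_length:
                    intervals.append((s, e, strand))
    for p, strand in _background_reads(rng, config):
        intervals.append((p, p + L, strand))
    return _assign_mapq(rng, intervals, config)


def simulate_seq_reads(
    truth: Sequence[TruthRecord],
    fragment_mean: float,
    fragment_sd: float,
    config: SimConfig,
    stream: int = 0,
) -> list[AlignedRead]:
    """ChIP-seq reads: sequenced ends of fragments centred on the sites.

    Fragments of Gaussian length are sampled around each planted motif
    midpoint; the top-strand read is the first ``read_length`` bases of a
    fragment, the bottom-strand read the last, so the two strands' 5'-end
    distributions sit on opposite sides of the site.
    """
    if fragment_mean <= config.read_length:
        raise ValueError(
            f"fragment_mean ({fragment_mean}) must exceed read_length "
            f"({config.read_length})"
        )
    rng = config.rng(3, stream)
    L = config.read_length
    intervals: list[tuple[int, int, str]] = []
    for record in truth:
        for ms, me, _ in record.motif_intervals:
            mid = (ms + me) // 2
            n = rng.poisson(config.reads_per_locus)
            if n == 0:
                continue
            lengths = np.rint(rng.normal(fragment_mean, fragment_sd, n))
            lengths = np.maximum(lengths, L).astype(np.int64)
            centers = mid + _jitter(rng, config.jitter_sd, n)
            starts = centers - lengths // 2
            ends = starts + lengths
            strands = rng.integers(0, 2, size=n)
            for fs, fe, t in zip(starts, ends, strands):
                if t == 0:
                    s, e, strand = int(fs), int(fs) + L, TOP
                else:
                    s, e, strand = int(fe) - L, int(fe), BOTTOM
                if s >= 0 and e <= config.genome_length:
                    intervals.append((s, e, strand))
    for p, strand in _background_reads(rng, config):
        intervals.append((p, p + L, strand))
    return _assign_mapq(rng, intervals, config)


# ----------------------------------------------------------------------
# dataset serialization

def write_truth_bed(path: str, truth: Sequence[TruthRecord]) -> None:
    """Truth as BED6: one row per motif interval, edge encoded in the name."""
    with open(path, "w") as fh:
        for rec in truth:
            for (ms, me, strand), (ep, es) in zip(
                rec.motif_intervals, rec.protection_edges
            ):
                name = f"{rec.locus_id};{rec.kind};edge={ep}{es}"
                fh.write(f"{rec.contig}\t{ms}\t{me}\t{name}\t0\t{strand}\n")


def read_truth_bed(path: str) -> list[TruthRecord]:
    records: dict[str, TruthRecord] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            contig, s, e, name, _, strand = line.split("\t")
            locus_id, kind, edge = name.split(";")
            ep = edge.removeprefix("edge=")
            epos, estrand = int(ep[:-1]), ep[-1]
            rec = records.get(locus_id)
            if rec is None:
                rec = TruthRecord(locus_id, kind, [], [], contig)
                records[locus_id] = rec
            rec.motif_intervals.append((int(s), int(e), strand))
            rec.protection_edges.append((epos, estrand))
    return list(records.values())


def write_dataset(
    genome: str,
    reads: Sequence[AlignedRead],
    truth: Sequence[TruthRecord],
    out_dir: str,
    config: SimConfig | None = None,
) -> dict[str, str]:
    """Write genome FASTA, reads (sorted SAM + BED6), truth BED, config echo."""
    os.makedirs(out_dir, exist_ok=True)
    contig = config.contig if config else (truth[0].contig if truth else "chr1")
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "sam": os.path.join(out_dir, "reads.sam"),
        "bed": os.path.join(out_dir, "reads.bed"),
        "truth": os.path.join(out_dir, "truth.bed"),
        "config": os.path.join(out_dir, "config.yaml"),
    }
    efio.write_fasta(paths["genome"], {contig: genome})
    order_reads = sorted(reads, key=lambda r: (r.start, r.end, r.strand, r.mapq))
    efio.write_sam(paths["sam"], order_reads, {contig: len(genome)})
    efio.write_reads_bed(paths["bed"], order_reads)
    write_truth_bed(paths["truth"], truth)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            dataclasses.asdict(config) if config else {}, fh, sort_keys=True
        )
    return paths


# ----------------------------------------------------------------------
# strand mirroring (used by symmetry checks)

def mirror_dataset(
    genome: str,
    reads: Iterable[AlignedRead],
    truth: Iterable[TruthRecord],
) -> tuple[str, list[AlignedRead], list[TruthRecord]]:
    """Reverse-complement a dataset: coordinates reflect, strands swap."""
    n = len(genome)
    flip = {TOP: BOTTOM, BOTTOM: TOP}
    kinds = {"single_top": "single_bottom", "single_bottom": "single_top"}
    m_reads = [
        AlignedRead(r.contig, n - r.end, n - r.start, flip[r.strand], r.mapq)
        for r in reads
    ]
    m_truth = [
        TruthRecord(
            t.locus_id,
            kinds.get(t.kind, t.kind),
            [(n - e, n - s, flip[st]) for s, e, st in t.motif_intervals],
            [(n - 1 - p, flip[st]) for p, st in t.protection_edges],
            t.contig,
        )
        for t in truth
    ]
    return reverse_complement(genome), m_reads, m_truth
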