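import numpy as np
import pytest

from exofoot import (
    SimConfig,
    build_depth_track,
    filter_reads,
    forkhead_like_motif,
    generate_genome,
    plant_loci,
    scan_sequence,
    simulate_exo_reads,
)


@pytest.fixture(scope="session")
def fkh():
    """The built-in synthetic forkhead-family motif (10 bp)."""
    return forkhead_like_motif()


def make_dataset(config, motif):
    """Simulate genome + loci + exo reads and derive track/hits once."""
    genome = generate_genome(config.genome_length, config.gc_fraction, config.seed)
    genome, truth = plant_loci(genome, config, motif)
    reads = simulate_exo_reads(truth, config)
    track = build_depth_track(filter_reads(reads, 5), config.genome_length)
    hits = scan_sequence(genome, motif, 1e-3, config.contig)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "track": track,
        "hits": hits,
    }


@pytest.fixture(scope="session")
def clean_dataset(fkh):
    """Noise-free dataset: jitter 0, background 0, every read at an edge."""
    config = SimConfig(
        genome_length=250_000,
        n_single_loci=20,
        n_paired_loci=10,
        jitter_sd=0.0,
        background_rate=0.0,
        lowmapq_fraction=0.0,
        seed=101,
    )
    return make_dataset(config, fkh)


@pytest.fixture(scope="session")
def noisy_dataset(fkh):
    """Realistic noise levels for recovery tests."""
    config = SimConfig(
        genome_length=300_000,
        n_single_loci=25,
        n_paired_loci=10,
        reads_per_locus=60.0,
        jitter_sd=1.0,
        background_rate=0.5,
        seed=202,
    )
    return make_dataset(config, fkh)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
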