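"""Simulator contracts: genome composition, planted geometry, read models."""

import numpy as np
import pytest

from exofoot import io as efio
from exofoot.motifs import reverse_complement
from exofoot.reads import BOTTOM, TOP, build_depth_track
from exofoot.simulate import (
    CapacityError,
    SimConfig,
    generate_genome,
    mirror_dataset,
    plant_loci,
    read_truth_bed,
    simulate_exo_reads,
    simulate_seq_reads,
    write_dataset,
    write_truth_bed,
)


# ----------------------------------------------------------------------
# genome generation


def test_zero_length_genome():
    assert generate_genome(0, 0.5, seed=1) == ""


def test_negative_length_rejected():
    with pytest.raises(ValueError):
        generate_genome(-1, 0.5)


def test_gc_zero_gives_at_alphabet():
    g = generate_genome(10_000, 0.0, seed=7)
    assert set(g) <= {"A", "T"}


def test_gc_fraction_within_binomial_ci():
    n, gc = 100_000, 0.4
    g = generate_genome(n, gc, seed=3)
    observed = (g.count("G") + g.count("C")) / n
    sd = np.sqrt(gc * (1 - gc) / n)
    assert abs(observed - gc) < 3 * sd


def test_genome_reproducible():
    assert generate_genome(5000, 0.5, seed=9) == generate_genome(5000, 0.5, seed=9)


# ----------------------------------------------------------------------
# locus planting


def test_no_loci_is_noop(fkh):
    cfg = SimConfig(genome_length=10_000, n_single_loci=0, n_paired_loci=0)
    g = generate_genome(10_000, 0.4, seed=1)
    out, truth = plant_loci(g, cfg, fkh)
    assert out == g and truth == []


def test_capacity_error_names_shortfall(fkh):
    cfg = SimConfig(genome_length=5000, n_single_loci=10)
    with pytest.raises(CapacityError, match="short by"):
        plant_loci(generate_genome(5000, 0.4, seed=1), cfg, fkh)


def test_single_locus_edge_offset_convention(fkh):
    """Each edge sits edge_motif_offset upstream of the motif start in
    reading direction; on the bottom strand that is a higher coordinate."""
    cfg = SimConfig(
        genome_length=300_000, n_single_loci=30, edge_motif_offset=9, seed=5
    )
    g, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 5), cfg, fkh)
    assert len(truth) == 30
    for rec in truth:
        (ms, me, strand) = rec.motif_intervals[0]
        (ep, estrand) = rec.protection_edges[0]
        assert estrand == strand
        if strand == TOP:
            assert rec.kind == "single_top" and ep == ms - 9
            assert g[ms:me] == fkh.consensus
        else:
            assert rec.kind == "single_bottom" and ep == (me - 1) + 9
            assert g[ms:me] == reverse_complement(fkh.consensus)


def test_paired_by_motif_overlap_geometry(fkh):
    cfg = SimConfig(
        genome_length=200_000,
        n_single_loci=0,
        n_paired_loci=10,
        pairing_mode="by_motif_overlap",
        motif_overlap=3,
        seed=6,
    )
    g, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 6), cfg, fkh)
    L = fkh.length
    for rec in truth:
        (ts, te, _), (bs, be, bstrand) = rec.motif_intervals
        assert bstrand == BOTTOM
        assert bs == ts + L - 3 and be - bs == L
        assert min(te, be) - max(ts, bs) == 3  # interval intersection
        assert g[bs:be] == reverse_complement(fkh.consensus)


def test_paired_by_edge_distance_geometry(fkh):
    cfg = SimConfig(
        genome_length=200_000,
        n_single_loci=0,
        n_paired_loci=10,
        pairing_mode="by_edge_distance",
        paired_edge_distance=33,
        seed=7,
    )
    g, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 7), cfg, fkh)
    for rec in truth:
        (et, es), (eb, ebs) = rec.protection_edges
        assert (es, ebs) == (TOP, BOTTOM)
        assert eb - et == 33
        # both planted instances remain exact consensus in this geometry
        (ts, te, _), (bs, be, _) = rec.motif_intervals
        assert g[ts:te] == fkh.consensus
        assert g[bs:be] == reverse_complement(fkh.consensus)


def test_footprint_spacing_at_least_2kb(fkh):
    cfg = SimConfig(genome_length=500_000, n_single_loci=60, seed=8)
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 8), cfg, fkh)
    positions = sorted(t.motif_intervals[0][0] for t in truth)
    assert min(np.diff(positions)) >= 2000


# ----------------------------------------------------------------------
# ChIP-exo reads


def test_noise_free_reads_pinned_to_edges(clean_dataset):
    edges = {
        (p, s) for t in clean_dataset["truth"] for p, s in t.protection_edges
    }
    for r in clean_dataset["reads"]:
        assert (r.five_prime, r.strand) in edges
        assert r.length == 36


def test_top_strand_read_span_from_edge(fkh):
    cfg = SimConfig(
        genome_length=100_000,
        n_single_loci=1,
        jitter_sd=0.0,
        background_rate=0.0,
        seed=11,
    )
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 11), cfg, fkh)
    reads = simulate_exo_reads(truth, cfg)
    (ep, es) = truth[0].protection_edges[0]
    for r in reads:
        if es == TOP:
            assert (r.start, r.end) == (ep, ep + 36)
        else:
            assert (r.start, r.end) == (ep - 35, ep + 1)


def test_total_footprint_reads_poisson_scale(fkh):
    cfg = SimConfig(
        genome_length=1_000_000,
        n_single_loci=200,
        reads_per_locus=50.0,
        background_rate=0.0,
        seed=12,
    )
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 12), cfg, fkh)
    n = len(simulate_exo_reads(truth, cfg))
    assert abs(n - 10_000) < 4 * np.sqrt(10_000)


def test_paired_locus_read_populations_overlap(fkh):
    """Top- and bottom-strand reads cover the protected region jointly."""
    cfg = SimConfig(
        genome_length=100_000,
        n_single_loci=0,
        n_paired_loci=1,
        jitter_sd=0.0,
        background_rate=0.0,
        seed=13,
    )
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 13), cfg, fkh)
    reads = simulate_exo_reads(truth, cfg)
    top = [r for r in reads if r.strand == TOP]
    bottom = [r for r in reads if r.strand == BOTTOM]
    assert top and bottom
    assert top[0].start < bottom[0].end and bottom[0].start < top[0].end


def test_lowmapq_fraction_scale(fkh):
    cfg = SimConfig(
        genome_length=1_000_000,
        n_single_loci=150,
        lowmapq_fraction=0.2,
        seed=14,
    )
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 14), cfg, fkh)
    reads = simulate_exo_reads(truth, cfg)
    frac = sum(r.mapq < 5 for r in reads) / len(reads)
    assert abs(frac - 0.2) < 0.02


def test_coverage_conservation(clean_dataset):
    track = build_depth_track(
        clean_dataset["reads"], clean_dataset["config"].genome_length
    )
    total = track.top_depth.sum() + track.bottom_depth.sum()
    assert total == len(clean_dataset["reads"]) * 36


def test_exo_determinism(clean_dataset):
    cfg = clean_dataset["config"]
    again = simulate_exo_reads(clean_dataset["truth"], cfg)
    assert again == clean_dataset["reads"]


# ----------------------------------------------------------------------
# ChIP-seq reads


def test_seq_reads_shifted_populations(fkh):
    """Fixed 200 bp fragments put strand-wise 5' ends ~100 bp either side."""
    cfg = SimConfig(
        genome_length=200_000,
        n_single_loci=5,
        reads_per_locus=200.0,
        jitter_sd=0.0,
        background_rate=0.0,
        seed=15,
    )
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 15), cfg, fkh)
    reads = simulate_seq_reads(truth, 200.0, 0.0, cfg)
    ms, me, _ = truth[0].motif_intervals[0]
    mid = (ms + me) // 2
    near = [r for r in reads if abs(r.five_prime - mid) < 400]
    top_mean = np.mean([r.five_prime for r in near if r.strand == TOP]) - mid
    bot_mean = np.mean([r.five_prime for r in near if r.strand == BOTTOM]) - mid
    assert top_mean == pytest.approx(-100, abs=2)
    assert bot_mean == pytest.approx(100, abs=2)


def test_seq_zero_loci_only_background(fkh):
    cfg = SimConfig(
        genome_length=50_000, n_single_loci=0, background_rate=2.0, seed=16
    )
    reads = simulate_seq_reads([], 200.0, 20.0, cfg)
    assert 0 < len(reads) < 500


def test_seq_fragment_mean_must_exceed_read_length(fkh):
    cfg = SimConfig(genome_length=50_000, n_single_loci=0)
    with pytest.raises(ValueError, match="fragment_mean"):
        simulate_seq_reads([], 36.0, 5.0, cfg)


def test_seq_determinism(fkh):
    cfg = SimConfig(genome_length=80_000, n_single_loci=5, seed=17)
    _, truth = plant_loci(generate_genome(cfg.genome_length, 0.4, 17), cfg, fkh)
    a = simulate_seq_reads(truth, 180.0, 25.0, cfg)
    b = simulate_seq_reads(truth, 180.0, 25.0, cfg)
    assert a == b


# ----------------------------------------------------------------------
# dataset writing and mirroring


def test_dataset_round_trip(tmp_path, clean_dataset):
    cfg = clean_dataset["config"]
    paths = write_dataset(
        clean_dataset["genome"],
        clean_dataset["reads"],
        clean_dataset["truth"],
        str(tmp_path / "ds"),
        cfg,
    )
    genome = efio.read_fasta(paths["genome"])[cfg.contig]
    assert genome == clean_dataset["genome"]
    reads = efio.read_sam(paths["sam"])
    assert sorted(reads, key=lambda r: (r.start, r.end, r.strand, r.mapq)) == sorted(
        clean_dataset["reads"], key=lambda r: (r.start, r.end, r.strand, r.mapq)
    )
    assert efio.read_reads_bed(paths["bed"]) == reads
    truth = read_truth_bed(paths["truth"])
    assert len(truth) == len(clean_dataset["truth"])
    assert truth[0] == clean_dataset["truth"][0]


def test_dataset_byte_identical_across_reruns(tmp_path, fkh):
    from exofoot.simulate import generate_genome

    def build(out):
        cfg = SimConfig(genome_length=60_000, n_single_loci=5, seed=21)
        g = generate_genome(cfg.genome_length, cfg.gc_fraction, cfg.seed)
        g, truth = plant_loci(g, cfg, fkh)
        reads = simulate_exo_reads(truth, cfg)
        return write_dataset(g, reads, truth, out, cfg)

    p1 = build(str(tmp_path / "a"))
    p2 = build(str(tmp_path / "b"))
    for key in ("genome", "sam", "bed", "truth", "config"):
        assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


def test_truth_bed_round_trip(tmp_path, clean_dataset):
    path = tmp_path / "truth.bed"
    write_truth_bed(str(path), clean_dataset["truth"])
    assert read_truth_bed(str(path)) == clean_dataset["truth"]


def test_mirror_swaps_truth_records(clean_dataset):
    g, reads, truth = (
        clean_dataset["genome"],
        clean_dataset["reads"],
        clean_dataset["truth"],
    )
    mg, mreads, mtruth = mirror_dataset(g, reads, truth)
    assert len(mg) == len(g)
    kinds = {t.kind for t in truth}
    assert {t.kind for t in mtruth} == {
        {"single_top": "single_bottom", "single_bottom": "single_top"}.get(k, k)
        for k in kinds
    }
    # double mirror is the identity
    g2, r2, t2 = mirror_dataset(mg, mreads, mtruth)
    assert g2 == g and r2 == reads
    assert [sorted(t.motif_intervals) for t in t2] == [
        sorted(t.motif_intervals) for t in truth
    ]
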