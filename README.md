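# exofoot

ChIP-exo footprint analysis: strand-specific exonuclease borders,
palindromic dimer pairing, consensus summits and motif-density resolution
statistics — with a synthetic ChIP-exo / ChIP-seq read simulator for
validation against planted ground truth.

## The problem

ChIP-exo adds a lambda-exonuclease digestion step to chromatin
immunoprecipitation: the enzyme chews each DNA strand 5'→3' until it is
blocked by the crosslinked protein. A stably bound transcription factor
therefore leaves a sharp, reproducible boundary of read 5' ends on each
strand — near-base-pair resolution, versus the fragment-length blur of
ChIP-seq. For forkhead-family pioneer factors (FoxA1/FoxA2) the protected
plateaus of read depth are so stereotyped that they resemble geological
*mesas*: the strand-specific coverage jumps by tens to hundreds of reads at
a single nucleotide, with the forkhead motif a fixed ~9 bp downstream of the
jump and oriented with the strand. Two opposite-strand mesas flanking one
locus, with motifs in palindromic (head-to-head) register, indicate a
homodimer protecting both strands.

`exofoot` is for computational biologists who want to detect and
characterize these structures from aligned reads, and to benchmark the
detection with simulations in which every footprint's position, strand and
geometry are known.

## What it computes

- **Read processing** — mapping-quality filtering (default `mapq >= 5`),
  blacklist exclusion (any shared base disqualifies), strand-split per-base
  coverage tracks `d⁺[i]`, `d⁻[i]` and bedGraph export.
- **Edge detection** — positions where coverage rises in one step in strand
  reading direction: `d⁺[i] − d⁺[i−1] ≥ θ` on the top strand,
  `d⁻[i] − d⁻[i+1] ≥ θ` on the bottom (default `θ = 30`).
- **Motif scanning** — position weight matrices scored as log₂-odds against
  a 0-order background, with *exact* p-values (the tail probability
  `P(score ≥ s)` under the background, by dynamic-programming convolution of
  per-position score distributions); both strands scanned at `p < 10⁻³`.
- **Mesa calling** — an edge becomes a mesa when a same-strand motif with
  `p ≤ 0.0025` starts 8–10 bp downstream of it. **Pairing** joins a top and
  bottom mesa whose motifs face head-to-head with 3' ends within 5 bp.
- **Consensus summits** — a greedy strongest-first rule: a summit is
  consensus when all three replicates place a summit within 100 bp of the
  strongest one. Overlap between consensus sets is counted asymmetrically.
- **Motif density / characteristic width** — motif starts histogrammed over
  summit ± 250 bp, normalized by total motif count, smoothed with a 21-tap
  isosceles-triangle moving average (20 bp window), and summarized as the
  width of the contiguous region around the maximum where density exceeds
  1/500 per base — a single-number measure of summit-calling precision.
- **Simulator** — plants single and palindromic-dimer footprints (≥ 2 kb
  apart) in a random genome and emits ChIP-exo reads (two overlapping
  strand populations with 5' ends pinned at the protection edges, plus
  Gaussian jitter and uniform background) or ChIP-seq reads (two shifted
  populations from fragment ends), together with a truth BED.

## Worked example

```python
from exofoot import (SimConfig, forkhead_like_motif, generate_genome, plant_loci,
                     simulate_exo_reads, filter_reads, build_depth_track,
                     scan_sequence, detect_edges, call_mesas, pair_mesas,
                     mesa_statistics, TOP, BOTTOM)

motif = forkhead_like_motif()   # synthetic forkhead-family PWM, consensus TGTTTACATG
config = SimConfig(genome_length=500_000, n_single_loci=40, n_paired_loci=15, seed=7)
genome = generate_genome(config.genome_length, config.gc_fraction, config.seed)
genome, truth = plant_loci(genome, config, motif)
reads = filter_reads(simulate_exo_reads(truth, config), min_mapq=5)
track = build_depth_track(reads, config.genome_length)
hits = scan_sequence(genome, motif, p_threshold=1e-3, contig="chr1")
edges = detect_edges(track, TOP, 30) + detect_edges(track, BOTTOM, 30)
mesas = call_mesas(edges, hits, min_increase=30, offset_range=(8, 10), p_max=0.0025)
pairs = pair_mesas(mesas, max_trailing_gap=5)
stats = mesa_statistics(mesas, pairs)
print(f"mesas: {stats.n_mesas}   pairs: {stats.n_pairs}")
print(f"edge-to-motif offsets: {stats.edge_to_motif_hist} (mode {stats.edge_to_motif_mode})")
print(f"paired edge distances: {stats.edge_distance_hist} (mode {stats.edge_distance_mode})")
print(f"motif overlaps: {stats.motif_overlap_hist} (mode {stats.motif_overlap_mode})")
```

prints

```
mesas: 68   pairs: 13
edge-to-motif offsets: {8: 2, 9: 61, 10: 5} (mode 9)
paired edge distances: {32: 2, 33: 11} (mode 33)
motif overlaps: {4: 13} (mode 4)
```

The 40 single loci and 15 dimers were planted with a 9 bp edge-to-motif
offset and a 33 bp inter-edge distance; with 1 bp read jitter the detection
recovers the modal offset (9) and modal distance (33) exactly, with the
small side-mass at 8/10 and 32 reflecting jittered edges. Not every planted
edge clears the 30-read step at this coverage, hence 68 of 110 edges called
— raise `reads_per_locus` or lower `min_increase` to trade sensitivity.

The same analyses are available from the shell:

```
exofoot simulate --out dataset/
exofoot mesas --reads dataset/reads.sam --genome dataset/genome.fa --out mesas/
exofoot run-all --seed 7 --out run/
```

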