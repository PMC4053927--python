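# Methods

## Model of the assay

ChIP-exo couples immunoprecipitation with lambda-exonuclease digestion.
The enzyme degrades each strand 5'→3' until blocked at the protein–DNA
crosslink, so the 5' ends of sequenced reads accumulate at the protection
boundary on each strand. `exofoot` models a stable footprint as a pair of
quantities per strand: an **edge** (the first protected base in strand
reading direction) and a plateau of whole-read coverage beginning there.
Coverage is whole-read (every base between a read's start and end
contributes), not 5'-end counting: only whole-read coverage produces the
flat-topped plateau whose trailing drop is an artifact of the fixed read
length, which is what the edge detector's step statistic relies on. This is
the single most consequential convention in the package.

Strand conventions used throughout:

- Coordinates are 0-based half-open internally; SAM is emitted 1-based via
  pysam. "Top" is `+`, "bottom" is `-`.
- A bottom-strand read's 5' end is its **rightmost** base; "downstream",
  "offset" and "trailing" are always in strand reading direction. A
  bottom-strand motif's reading-direction start is the right end of its
  interval, and its edge sits at a *higher* reference coordinate.
- An edge at `e` with a motif starting (reading direction) at `m` has
  `edge_to_motif = m − e` on the top strand and `e − m` on the bottom; the
  canonical forkhead geometry is `edge_to_motif = 9`, i.e. 8 intervening
  protected bases between the edge and the motif's first base.

## Detection procedure

1. **Filtering.** Reads with `mapq < 5` are discarded; reads sharing ≥ 1
   base with a blacklist interval are discarded (strictest reading of
   "overlapping"). Both thresholds are configurable.
2. **Edges.** Top strand: positions `i` with `d⁺[i] − d⁺[i−1] ≥ θ`; bottom:
   `d⁻[i] − d⁻[i+1] ≥ θ`. Contig boundaries count as zero depth. The
   default `θ = 30` reads presumes deep per-site pileups (~100 reads per
   edge); simulations at lighter coverage scale it to roughly 30 % of the
   expected per-site read count (the benchmark runs at 50 reads per locus
   use `θ = 15`), keeping the threshold-to-coverage ratio of the default.
3. **Mesas.** An edge qualifies when a same-strand motif hit with
   `p ≤ 0.0025` starts 8–10 bp downstream. Among several candidates the
   lowest p-value wins, ties to the smallest offset (a deterministic rule;
   the choice is otherwise arbitrary).
4. **Pairing.** A top and a bottom mesa pair when the top edge is left of
   the bottom edge and the motifs' 3' ends — the ends that face each other
   in head-to-head register — lie within 5 bp. "Trailing end" is read as
   the 3' end. Pairing is one-to-one, greedy by smallest trailing gap with
   ties broken by smallest inter-edge distance. Both keys are invariant
   under reverse-complementing the dataset, so pairing commutes with strand
   mirroring; a coordinate-based tie-break would not be.
5. **Geometry statistics.** Integer histograms and modal values of
   `edge_to_motif`, inter-edge distance and motif interval overlap
   (negative overlap = gap). Modal ties resolve to the smallest value.

## Motif scanning

PWMs are built from count matrices (JASPAR or TRANSFAC dialects via
Bio.motifs, or arrays) with an additive pseudocount (default 1.0) and
scored as log₂-odds against a 0-order background (uniform by default; a
sequence-derived background is available — which background an external
scanner would use is generally unknowable, so the default is the neutral
choice). The p-value of a score is the exact tail probability that a random
background word of the motif's length scores at least as high, computed by
dynamic-programming convolution of the per-position score distributions on
an integer lattice of 10⁻³ bits per unit. Scanning thresholds are strict
(`p < threshold`) while mesa validation is inclusive (`p ≤ 0.0025`),
matching the respective conventions of the quantities involved. Zero
probability cells are floored at −10 bits so every word keeps a finite
score; the floor is far below any tail of interest, and tests verify the
table against exhaustive enumeration for short motifs. Windows containing
non-ACGT characters are skipped. Bottom-strand windows are scored through
the reverse-complement matrix and assigned p-values from the forward
table, which is exactly the tail of the reverse-complement word's score.

## Summits, consensus, density

The summit caller is deliberately naive — greedy selection of the highest
remaining combined-strand position with a suppression radius — and is
clearly not a model-based peak caller; externally produced summit BED
files are accepted anywhere peaks are consumed. Consensus across three
replicates is anchor-based: the globally strongest unconsumed summit is an
anchor, and a consensus is emitted only if every other replicate still has
a summit within 100 bp of the anchor (nearest member per replicate,
distance inclusive). Anchor-based grouping (rather than requiring all
pairwise distances ≤ 100 bp) is the design choice where either reading was
defensible. Overlap between two summit sets is asymmetric by construction:
each side counts its own summits that have ≥ 1 partner within 100 bp, so
one broad peak facing two sharp ones contributes once on one side and
twice on the other.

Motif density around summits: motif starts (configurable to midpoints) are
histogrammed over summit ± 250 bp, inclusive at both boundaries, and
normalized by the total motif count in all windows (per-motif-total, taken
literally, not per-summit). Smoothing is a weighted moving average with a
symmetric 21-tap isosceles-triangle kernel for the default 20 bp window —
weight `11 − |k|` at lag `k` — realized with per-output renormalized
weights at the profile edges, so a uniform density is exactly invariant;
total mass is exactly preserved whenever the profile's support stays a
kernel-width away from the window edges (true for any centered profile;
the alternative input-side renormalization would conserve edge mass
instead but distort uniform profiles). The **characteristic width** is the
length of the maximal contiguous run of offsets, containing the global
maximum, where smoothed density strictly exceeds 1/500 per base; requiring
contiguity around the maximum keeps disjoint noise islands out of the
statistic. Read-density profiles around summits are scaled per 10⁷ reads
("per 10 million" being the concrete realization of read-count
normalization).

## The simulator

`SimConfig` defines the study conditions; its defaults are fixed once:

| parameter | default | meaning / rationale |
|---|---|---|
| `genome_length` | 1 Mb | i.i.d. random genome; large enough for hundreds of spaced loci |
| `gc_fraction` | 0.41 | human-like GC content |
| `read_length` | 36 | short-read single-end length typical of the assay |
| `edge_motif_offset` | 9 bp | canonical forkhead edge-to-motif distance |
| `paired_edge_distance` | 33 bp | canonical inter-edge distance of dimer footprints |
| `motif_overlap` | 3 bp | canonical palindromic register of motif dimers |
| `reads_per_locus` | 100 | Poisson mean per edge; deep-pileup regime where the 30-read rule applies |
| `jitter_sd` | 1 bp | sd of rounded Gaussian 5'-end jitter, truncated at ±3 sd (digestion is near-base-precise but not exact) |
| `background_rate` | 0.5 reads/kb | uniform nonspecific background |
| `lowmapq_fraction` | 0.05 | reads assigned `mapq < 5`, exercising the filter |

Jitter sd, background rate, low-mapq fraction, coverage and GC content are
free parameters of the simulator (no published measurement pins them);
they were chosen once at realistic Illumina scale and are not tuned per
experiment. Planted footprints are kept ≥ 2 kb apart (slotted placement)
so loci never interact.

ChIP-exo reads: each protection edge emits Poisson(`reads_per_locus`)
reads on its own strand with 5' ends at the edge plus integer jitter
(reads live on an integer lattice, hence rounding; truncation at ±3 sd
keeps outliers off neighbouring loci). ChIP-seq reads: Gaussian-length
fragments centred on motif midpoints, sequenced from either end with equal
probability, giving the two shifted 5'-end populations characteristic of
that assay.

Paired-locus geometry is parameterized **two ways** because the three
canonical numbers (offset 9, edge distance 33, overlap 3) cannot be
jointly satisfied by any single motif length: `by_edge_distance` fixes the
inter-edge distance and derives the bottom motif position; the distance
`D`, offset `o` and length `L` then imply overlap `2L + 2o − D − 1` and
trailing gap `|2L + 2o − D − 2|`. `by_motif_overlap` fixes the overlap `v`
(trailing gap `v − 1`, edge distance `2L + 2o − v − 1`). Each benchmark
fixes one mode. The bundled synthetic forkhead-family PWM is 10 bp
(consensus `TGTTTACATG`): with `L = 10`, `by_edge_distance = 33` yields
overlap 4 and trailing gap 3 (within the 5 bp pairing rule), and the
weakly constrained 3' tail was chosen so the 4 bp overlap region `CATG` is
its own reverse complement — both dimer motifs are written as exact
consensus in that mode. In `by_motif_overlap = 3` mode the 3 bp overlap
region cannot satisfy both strands (no odd-length DNA word is its own
reverse complement); the bottom instance is written last and intact, and
only weak tail positions of the top instance are altered, costing ~3 bits
against a ~15-bit consensus score, far inside the `p ≤ 0.0025` rule.

**What the simulator does not model:** sequencing errors, PCR duplicates,
mappability structure (low-mapq labels are assigned at random rather than
arising from repeats), chromatin accessibility, inter-locus interference,
partial occupancy, and real genome sequence composition. Passing recovery
tests therefore demonstrates correctness of the detection geometry and its
statistics under the stated noise model — not performance on real
libraries, where edge sharpness, background structure and motif degeneracy
are all less favourable.

## Benchmarks the package ships

- Parameter recovery: 300 single footprints (3 Mb, 50 reads/locus, 1 bp
  jitter, 0.5 reads/kb background) recover modal `edge_to_motif = 9`; 300
  dimers in `by_edge_distance` mode recover modal distance 33; 300 dimers
  in `by_motif_overlap` mode recover modal overlap 3.
- Noise-free exactness: at zero jitter and zero background every planted
  edge is recovered at its exact coordinate with no false calls.
- Consensus: three independently noisy replicates of 200 sites recover
  ≥ 95 % through the 100 bp consensus rule.
- Resolution ordering: summit sets jittered at 10 bp sd always have a
  strictly smaller characteristic width than at 30 bp sd; real-data width
  values depend on real libraries and are out of the simulator's reach, so
  only the ordering (and an exact rectangular-profile oracle) is asserted.
- Oracle equivalence: exact p-values and scanning match brute-force
  enumeration for short motifs; depth tracks match per-base counting.
- Strand-mirror invariance: reverse-complementing a dataset maps every
  mesa to the mirrored coordinate on the opposite strand and preserves all
  pair statistics.

Problem sizes (3 Mb genomes, 300 loci, ≤ 500 sites for consensus) were
chosen so each benchmark isolates one claim at comfortable statistical
power while the whole suite runs in seconds.

## Known limitations

- The edge detector is a fixed-threshold step filter; it has no local
  background model and will miss edges whose coverage undershoots the
  threshold (Poisson thinning at light coverage) and split jittered edges
  across adjacent positions (visible as ±1 side-mass in offset
  histograms).
- `pair_mesas` is O(n_top × n_bottom) per contig; fine for thousands of
  mesas, not for millions.
- The exact p-value lattice (10⁻³ bits) makes scores and p-values
  reproducible but quantized; ties at a threshold are resolved by the
  strict/inclusive conventions above.
- The summit caller is intentionally simple; quantitative peak heights and
  widths from it should not be compared against model-based callers.
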