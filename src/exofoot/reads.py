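"""Aligned-read filtering and strand-specific per-base depth tracks.

Reads are kept in 0-based half-open reference coordinates.  "Top" strand is
"+" and "bottom" is "-"; a bottom-strand read's 5' end is its *rightmost*
base, matching the direction of lambda-exonuclease digestion.  Depth is
whole-read coverage (every base of the read contributes), which is what
gives exonuclease-protection plateaus their flat-topped "mesa" shape.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

TOP = "+"
BOTTOM = "-"
STRANDS = (TOP, BOTTOM)


class CoordinateError(ValueError):
    """A read lies outside its contig's bounds."""


@dataclasses.dataclass(slots=True)
class AlignedRead:
    """One mapped read: contig, 0-based half-open interval, strand, mapq."""

    contig: str
    start: int
    end: int
    strand: str
    mapq: int = 0

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError(f"read has non-positive length: {self}")
        if self.start < 0:
            raise ValueError(f"read start < 0: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5' end position: leftmost base on top, rightmost on bottom."""
        return self.start if self.strand == TOP else self.end - 1


def filter_reads(
    reads: Sequence[AlignedRead],
    min_mapq: int = 5,
    blacklist: Iterable[tuple[str, int, int]] | None = None,
) -> list[AlignedRead]:
    """Keep reads with ``mapq >= min_mapq`` and no blacklist overlap.

    ``blacklist`` holds half-open ``(contig, start, end)`` intervals in read
    coordinates; sharing even a single base with one disqualifies a read.
    Input order is preserved.
    """
    trees: dict[str, IntervalTree] = {}
    if blacklist is not None:
        for contig, start, end in blacklist:
            if end > start:
                trees.setdefault(contig, IntervalTree()).addi(start, end)

    kept = []
    for read in reads:
        if read.mapq < min_mapq:
            continue
        tree = trees.get(read.contig)
        if tree is not None and tree.overlap(read.start, read.end):
            continue
        kept.append(read)
    return kept


@dataclasses.dataclass
class StrandedDepthTrack:
    """Per-base whole-read coverage, split by strand, for one contig."""

    contig: str
    top_depth: np.ndarray
    bottom_depth: np.ndarray
    n_reads_used: int

    @property
    def length(self) -> int:
        return len(self.top_depth)

    def combined(self) -> np.ndarray:
        return self.top_depth + self.bottom_depth

    def depth(self, strand: str) -> np.ndarray:
        return self.top_depth if strand == TOP else self.bottom_depth


def build_depth_track(
    reads: Sequence[AlignedRead],
    contig_length: int,
    contig: str | None = None,
) -> StrandedDepthTrack:
    """Coverage-depth arrays from reads on one contig.

    ``depth[i]`` on a strand is the number of that strand's reads whose
    interval contains ``i``.  Raises :class:`CoordinateError` naming the
    first read that exceeds the contig bounds.
    """
    if contig is None:
        contig = reads[0].contig if reads else "contig"
    diffs = {s: np.zeros(contig_length + 1, dtype=np.int64) for s in STRANDS}
    for read in reads:
        if read.contig != contig:
            raise CoordinateError(f"read on {read.contig!r}, expected {contig!r}: {read}")
        if read.end > contig_length or read.start < 0:
            raise CoordinateError(
                f"read outside contig bounds [0, {contig_length}): {read}"
            )
        diffs[read.strand][read.start] += 1
        diffs[read.strand][read.end] -= 1
    return StrandedDepthTrack(
        contig=contig,
        top_depth=diffs[TOP][:-1].cumsum(),
        bottom_depth=diffs[BOTTOM][:-1].cumsum(),
        n_reads_used=len(reads),
    )


def export_bedgraph(track: StrandedDepthTrack, strand: str, path: str) -> None:
    """Write one strand of a depth track as run-length-encoded bedGraph.

    Intervals are 0-based half-open; zero-depth runs are omitted, so the
    file expands back to the depth array exactly.
    """
    depth = track.depth(strand)
    try:
        with open(path, "w") as fh:
            if len(depth):
                breaks = np.flatnonzero(np.diff(depth)) + 1
                starts = np.concatenate([[0], breaks])
                ends = np.concatenate([breaks, [len(depth)]])
                for s, e in zip(starts, ends):
                    v = depth[s]
                    if v != 0:
                        fh.write(f"{track.contig}\t{s}\t{e}\t{v}\n")
    except OSError as exc:
        raise OSError(f"cannot write bedGraph to {path}: {exc}") from exc


def read_bedgraph(path: str, contig_length: int) -> np.ndarray:
    """Expand a bedGraph file back into a per-base depth array."""
    depth = np.zeros(contig_length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            _, s, e, v = line.split("\t")
            depth[int(s) : int(e)] = int(float(v))
    return depth
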