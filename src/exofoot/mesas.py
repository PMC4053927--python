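"""Exonuclease-border ("mesa") detection, motif validation and pairing.

A mesa is a plateau of strand-specific read depth that begins at a sharp
single-nucleotide increase — the point where lambda exonuclease was blocked
by a stably bound protein.  A candidate edge becomes a mesa when a
correctly oriented motif sits a characteristic 8-10 bp downstream (in
strand reading direction) with a sufficiently strong match.  Opposite-
strand mesas whose motifs face each other in palindromic (head-to-head)
register are paired, the signature of a homodimer protecting both strands.

All "downstream"/"trailing" language is in strand reading direction: the
bottom strand reads right-to-left, so a bottom-strand mesa's edge is the
rightmost elevated base and its motif lies at lower reference coordinates.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import MotifHit
from .reads import BOTTOM, TOP, StrandedDepthTrack


@dataclasses.dataclass(slots=True)
class Edge:
    """A single-nucleotide depth increase in strand reading direction."""

    contig: str
    position: int
    strand: str
    depth_increase: int


@dataclasses.dataclass(slots=True)
class Mesa:
    """An edge validated by a correctly oriented, well-placed motif."""

    edge: Edge
    motif: MotifHit
    edge_to_motif: int


@dataclasses.dataclass(slots=True)
class MesaPair:
    """Two opposite-strand mesas with motifs in palindromic register."""

    top: Mesa
    bottom: Mesa
    edge_distance: int   # bottom edge - top edge, reference coordinates
    motif_overlap: int   # intersection length of the motif intervals (<0 = gap)
    trailing_gap: int    # distance between the two motifs' 3' ends


@dataclasses.dataclass
class MesaStatistics:
    """Histograms and modes of the mesa/pair geometry."""

    n_mesas: int
    n_pairs: int
    edge_to_motif_hist: dict[int, int]
    edge_to_motif_mode: int | None
    edge_distance_hist: dict[int, int]
    edge_distance_mode: int | None
    motif_overlap_hist: dict[int, int]
    motif_overlap_mode: int | None


def detect_edges(
    track: StrandedDepthTrack, strand: str, min_increase: int = 30
) -> list[Edge]:
    """Positions where depth rises by >= ``min_increase`` in one step.

    Top strand: ``depth[i] - depth[i-1]``; bottom strand (read right to
    left): ``depth[i] - depth[i+1]``.  Contig boundaries count as depth 0.
    """
    if min_increase < 1:
        raise ValueError("min_increase must be >= 1")
    depth = track.depth(strand)
    if strand == TOP:
        inc = depth - np.concatenate(([0], depth[:-1]))
    else:
        inc = depth - np.concatenate((depth[1:], [0]))
    positions = np.flatnonzero(inc >= min_increase)
    return [
        Edge(track.contig, int(p), strand, int(inc[p])) for p in positions
    ]


def _reading_start(hit: MotifHit) -> int:
    """Motif start in its own reading direction (3' trailing end is the
    other extremity)."""
    return hit.start if hit.strand == TOP else hit.end - 1


def _trailing_end(hit: MotifHit) -> int:
    return hit.end - 1 if hit.strand == TOP else hit.start


def call_mesas(
    edges: Sequence[Edge],
    hits: Sequence[MotifHit],
    min_increase: int = 30,
    offset_range: tuple[int, int] = (8, 10),
    p_max: float = 0.0025,
) -> list[Mesa]:
    """Validate edges into mesas by motif orientation and placement.

    A mesa requires a same-strand hit with ``pvalue <= p_max`` whose
    reading-direction start lies ``offset_range`` bases downstream of the
    edge.  Among several candidates the lowest p-value wins, ties going to
    the smallest offset.
    """
    lo, hi = offset_range
    by_strand: dict[str, list[MotifHit]] = {TOP: [], BOTTOM: []}
    for h in hits:
        if h.pvalue <= p_max:
            by_strand[h.strand].append(h)
    keyed = {
        s: sorted(hs, key=_reading_start) for s, hs in by_strand.items()
    }
    starts = {
        s: np.array([_reading_start(h) for h in hs], dtype=np.int64)
        for s, hs in keyed.items()
    }

    mesas: list[Mesa] = []
    for edge in edges:
        if edge.depth_increase < min_increase:
            continue
        arr = starts[edge.strand]
        if edge.strand == TOP:
            wlo, whi = edge.position + lo, edge.position + hi
        else:
            wlo, whi = edge.position - hi, edge.position - lo
        i0 = int(np.searchsorted(arr, wlo, side="left"))
        i1 = int(np.searchsorted(arr, whi, side="right"))
        best = None
        for h in keyed[edge.strand][i0:i1]:
            if h.contig != edge.contig:
                continue
            if edge.strand == TOP:
                offset = _reading_start(h) - edge.position
            else:
                offset = edge.position - _reading_start(h)
            key = (h.pvalue, offset)
            if best is None or key < best[0]:
                best = (key, h, offset)
        if best is not None:
            mesas.append(Mesa(edge=edge, motif=best[1], edge_to_motif=best[2]))
    return mesas


def pair_mesas(mesas: Sequence[Mesa], max_trailing_gap: int = 5) -> list[MesaPair]:
    """One-to-one pairing of top and bottom mesas in palindromic register.

    Candidates require the top edge left of the bottom edge and the two
    motifs' 3' ends (the ends facing each other head-to-head) within
    ``max_trailing_gap`` bases.  Pairs are chosen greedily by smallest
    trailing gap, ties by smallest edge distance (both are invariant under
    reverse-complementing the dataset, so pairing commutes with strand
    mirroring); each mesa joins at most one pair.
    """
    tops = [m for m in mesas if m.edge.strand == TOP]
    bottoms = [m for m in mesas if m.edge.strand == BOTTOM]
    candidates = []
    for ti, t in enumerate(tops):
        for bi, b in enumerate(bottoms):
            if t.edge.contig != b.edge.contig:
                continue
            if not t.edge.position < b.edge.position:
                continue
            gap = abs(_trailing_end(t.motif) - _trailing_end(b.motif))
            if gap <= max_trailing_gap:
                distance = b.edge.position - t.edge.position
                candidates.append((gap, distance, t.edge.position, ti, bi))
    candidates.sort()
    used_t: set[int] = set()
    used_b: set[int] = set()
    pairs: list[MesaPair] = []
    for gap, _, _, ti, bi in candidates:
        if ti in used_t or bi in used_b:
            continue
        used_t.add(ti)
        used_b.add(bi)
        t, b = tops[ti], bottoms[bi]
        overlap = min(t.motif.end, b.motif.end) - max(t.motif.start, b.motif.start)
        pairs.append(
            MesaPair(
                top=t,
                bottom=b,
                edge_distance=b.edge.position - t.edge.position,
                motif_overlap=overlap,
                trailing_gap=gap,
            )
        )
    pairs.sort(key=lambda p: p.top.edge.position)
    return pairs


def _mode(counter: Counter) -> int | None:
    if not counter:
        return None
    best = max(counter.values())
    return min(v for v, c in counter.items() if c == best)


def mesa_statistics(
    mesas: Sequence[Mesa], pairs: Sequence[MesaPair] = ()
) -> MesaStatistics:
    """Integer histograms and modal values of the recovered geometry."""
    e2m = Counter(m.edge_to_motif for m in mesas)
    ed = Counter(p.edge_distance for p in pairs)
    ov = Counter(p.motif_overlap for p in pairs)
    return MesaStatistics(
        n_mesas=len(mesas),
        n_pairs=len(pairs),
        edge_to_motif_hist=dict(sorted(e2m.items())),
        edge_to_motif_mode=_mode(e2m),
        edge_distance_hist=dict(sorted(ed.items())),
        edge_distance_mode=_mode(ed),
        motif_overlap_hist=dict(sorted(ov.items())),
        motif_overlap_mode=_mode(ov),
    )


def sample_edge_matrix(
    edges: Sequence[Edge],
    hits: Sequence[MotifHit],
    n_per_strand: int = 100,
    window: int = 100,
    min_increase: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Motif positions around a random sample of strong edges.

    Samples up to ``n_per_strand`` edges per strand with
    ``depth_increase >= min_increase`` and lists, for each, every motif
    start (both strands) within a ``window``-base window centred on the
    edge, as offsets in the edge's reading direction.  Returns the
    per-edge table and per-offset motif-density rows for each motif
    strand class (same / opposite relative to the edge).
    """
    rng = np.random.default_rng(seed)
    half = window // 2
    rows = []
    densities = []
    hstart = np.array([_reading_start(h) for h in hits], dtype=np.int64)
    order = np.argsort(hstart)
    hstart = hstart[order]
    hsorted = [hits[i] for i in order]

    for strand in (TOP, BOTTOM):
        qual = [e for e in edges if e.strand == strand and e.depth_increase >= min_increase]
        if len(qual) < n_per_strand:
            warnings.warn(
                f"only {len(qual)} qualifying {strand}-strand edges "
                f"(requested {n_per_strand}); sampling all"
            )
            sample = qual
        else:
            idx = rng.choice(len(qual), size=n_per_strand, replace=False)
            sample = [qual[i] for i in sorted(idx)]
        counts = {"same": np.zeros(2 * half + 1), "opposite": np.zeros(2 * half + 1)}
        for k, e in enumerate(sample):
            lo = int(np.searchsorted(hstart, e.position - half, side="left"))
            hi = int(np.searchsorted(hstart, e.position + half, side="right"))
            for h in hsorted[lo:hi]:
                if h.contig != e.contig:
                    continue
                offset = (
                    _reading_start(h) - e.position
                    if strand == TOP
                    else e.position - _reading_start(h)
                )
                if abs(offset) > half:
                    continue
                cls = "same" if h.strand == strand else "opposite"
                counts[cls][offset + half] += 1
                rows.append(
                    {
                        "edge_index": k,
                        "edge_strand": strand,
                        "edge_position": e.position,
                        "motif_strand": h.strand,
                        "orientation": cls,
                        "offset": offset,
                        "pvalue": h.pvalue,
                    }
                )
        n = max(len(sample), 1)
        for cls in ("same", "opposite"):
            for off in range(-half, half + 1):
                densities.append(
                    {
                        "edge_strand": strand,
                        "orientation": cls,
                        "offset": off,
                        "density": counts[cls][off + half] / n,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "edge_index", "edge_strand", "edge_position",
            "motif_strand", "orientation", "offset", "pvalue",
        ],
    )
    return table, pd.DataFrame(densities)
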