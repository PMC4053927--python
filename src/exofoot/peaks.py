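"""Summit calling, consensus across replicates, overlap and peak statistics.

The summit caller here is a deliberately naive greedy local-maximum picker
(not a MACS reimplementation): it exists so synthetic pipelines run
end-to-end, and externally called summit BED files are accepted as drop-in
replacements everywhere a peak list is consumed.

Consensus follows the strongest-first rule: a site is a consensus summit
only when *all* replicates place a summit within the window of the
strongest peak, and the consensus is anchored at that strongest summit.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .motifs import MotifHit
from .reads import AlignedRead, StrandedDepthTrack


@dataclasses.dataclass(slots=True)
class Peak:
    contig: str
    summit: int
    height: float

    def __post_init__(self):
        if self.summit < 0 or self.height < 0:
            raise ValueError(f"summit and height must be non-negative: {self}")


@dataclasses.dataclass(slots=True)
class ConsensusSummit:
    contig: str
    summit: int
    strength: float
    member_summits: tuple[int, ...]


@dataclasses.dataclass(slots=True)
class OverlapCounts:
    a_only: int
    b_only: int
    a_shared: int
    b_shared: int


def call_summits(
    track: StrandedDepthTrack, min_height: float = 30, min_separation: int = 100
) -> list[Peak]:
    """Greedy local maxima of combined-strand depth.

    Repeatedly takes the highest remaining position (ties to the lower
    coordinate), emits it as a summit, and suppresses everything within
    ``min_separation`` of it, until the remaining maximum falls below
    ``min_height``.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    depth = track.combined().astype(float)
    peaks: list[Peak] = []
    while True:
        i = int(depth.argmax())
        h = float(depth[i])
        if h < min_height:
            break
        peaks.append(Peak(track.contig, i, h))
        depth[max(0, i - min_separation) : i + min_separation + 1] = -np.inf
    peaks.sort(key=lambda p: p.summit)
    return peaks


def consensus_summits(
    rep_a: Sequence[Peak],
    rep_b: Sequence[Peak],
    rep_c: Sequence[Peak],
    window: int = 100,
) -> list[ConsensusSummit]:
    """Summits supported by all three replicates within ``window`` bases.

    Greedy by strength: the globally strongest unconsumed peak anchors a
    candidate; if every other replicate still has a summit within
    ``window`` of the anchor (nearest one, ties to the lower coordinate),
    a consensus is emitted at the anchor and all members are consumed;
    otherwise the anchor alone is consumed.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    replicates = [list(rep_a), list(rep_b), list(rep_c)]
    consumed = [[False] * len(r) for r in replicates]
    pool = [
        (-(p.height), p.contig, p.summit, ri, pi)
        for ri, rep in enumerate(replicates)
        for pi, p in enumerate(rep)
    ]
    pool.sort()

    out: list[ConsensusSummit] = []
    for _, contig, summit, ri, pi in pool:
        if consumed[ri][pi]:
            continue
        consumed[ri][pi] = True
        anchor = replicates[ri][pi]
        members: dict[int, int] = {ri: pi}
        for rj in range(3):
            if rj == ri:
                continue
            best = None
            for pj, q in enumerate(replicates[rj]):
                if consumed[rj][pj] or q.contig != contig:
                    continue
                d = abs(q.summit - anchor.summit)
                if d <= window:
                    key = (d, q.summit)
                    if best is None or key < best[0]:
                        best = (key, pj)
            if best is None:
                members = None
                break
            members[rj] = best[1]
        if members is None:
            continue
        for rj, pj in members.items():
            consumed[rj][pj] = True
        out.append(
            ConsensusSummit(
                contig=contig,
                summit=anchor.summit,
                strength=anchor.height,
                member_summits=tuple(
                    replicates[rj][members[rj]].summit for rj in range(3)
                ),
            )
        )
    out.sort(key=lambda c: (c.contig, c.summit))
    return out


def overlap_consensus(
    set_a: Sequence[ConsensusSummit],
    set_b: Sequence[ConsensusSummit],
    window: int = 100,
) -> OverlapCounts:
    """Asymmetric overlap: a summit is shared if the other set has one
    within ``window`` (inclusive) on the same contig.  ``a_shared`` and
    ``b_shared`` may differ when one peak faces several partners."""
    if window < 0:
        raise ValueError("window must be non-negative")

    def shared(xs: Sequence[ConsensusSummit], ys: Sequence[ConsensusSummit]) -> int:
        by_contig: dict[str, list[int]] = {}
        for y in ys:
            by_contig.setdefault(y.contig, []).append(y.summit)
        for v in by_contig.values():
            v.sort()
        n = 0
        for x in xs:
            arr = by_contig.get(x.contig)
            if not arr:
                continue
            a = np.asarray(arr)
            i = int(np.searchsorted(a, x.summit))
            near = []
            if i < len(a):
                near.append(abs(int(a[i]) - x.summit))
            if i > 0:
                near.append(abs(int(a[i - 1]) - x.summit))
            if near and min(near) <= window:
                n += 1
        return n

    a_shared = shared(set_a, set_b)
    b_shared = shared(set_b, set_a)
    return OverlapCounts(
        a_only=len(set_a) - a_shared,
        b_only=len(set_b) - b_shared,
        a_shared=a_shared,
        b_shared=b_shared,
    )


def enrichment_profile(
    track: StrandedDepthTrack,
    summits: Sequence[int],
    halfwidth: int,
    total_reads: int,
) -> tuple[np.ndarray, int]:
    """Mean combined depth around summits, scaled per 10 million reads.

    Returns ``(profile, n_skipped)`` where ``profile[k]`` is the mean depth
    at offset ``k - halfwidth`` and ``n_skipped`` counts summits too close
    to the contig ends to contribute.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if len(summits) == 0:
        raise ValueError("empty summit list: nothing to average")
    depth = track.combined().astype(float)
    acc = np.zeros(2 * halfwidth + 1)
    used = skipped = 0
    for s in summits:
        if s - halfwidth < 0 or s + halfwidth + 1 > len(depth):
            skipped += 1
            continue
        acc += depth[s - halfwidth : s + halfwidth + 1]
        used += 1
    if used == 0:
        raise ValueError("all summits fell too close to the contig ends")
    return acc / used * (1e7 / total_reads), skipped


def chip_efficiency(
    reads: Sequence[AlignedRead], peaks: Sequence[Peak], peak_halfwidth: int
) -> float:
    """Fraction of reads overlapping any summit +/- ``peak_halfwidth`` window."""
    if len(reads) == 0:
        raise ValueError("undefined ratio: zero reads")
    if len(peaks) == 0:
        return 0.0
    windows: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        windows.setdefault(p.contig, []).append(
            (max(0, p.summit - peak_halfwidth), p.summit + peak_halfwidth + 1)
        )
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, ivals in windows.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = (
            np.array([x[0] for x in out]),
            np.array([x[1] for x in out]),
        )
    n_in = 0
    for r in reads:
        m = merged.get(r.contig)
        if m is None:
            continue
        starts, ends = m
        i = int(np.searchsorted(ends, r.start, side="right"))
        if i < len(starts) and starts[i] < r.end:
            n_in += 1
    return n_in / len(reads)


def motif_presence_stats(
    summits: Sequence[int],
    hits: Sequence[MotifHit],
    window: int = 100,
    p_max: float = 0.0025,
) -> tuple[float, list[float | None]]:
    """Motif frequency and per-region strongest motif p-value.

    A region is ``summit +/- window`` (inclusive); the frequency is the
    fraction of regions holding at least one hit with ``pvalue < p_max``,
    and the strongest motif is the minimum p-value among *all* hits whose
    start lies in the region (``None`` when the region is empty).
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    if len(summits) == 0:
        raise ValueError("empty summit list")
    starts = np.array(sorted(h.start for h in hits), dtype=np.int64)
    by_start = sorted(hits, key=lambda h: h.start)
    n_with = 0
    strongest: list[float | None] = []
    for s in summits:
        lo = int(np.searchsorted(starts, s - window, side="left"))
        hi = int(np.searchsorted(starts, s + window, side="right"))
        region = by_start[lo:hi]
        if region:
            best = min(h.pvalue for h in region)
            strongest.append(best)
            if any(h.pvalue < p_max for h in region):
                n_with += 1
        else:
            strongest.append(None)
    return n_with / len(summits), strongest


# ----------------------------------------------------------------------
# summit BED I/O (MACS summit-BED compatible)

def write_summits_bed(path: str, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.contig}\t{p.summit}\t{p.summit + 1}\tpeak{i:06d}\t{p.height:g}\n")


def read_summits_bed(path: str) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            height = float(fields[4]) if len(fields) > 4 else 0.0
            peaks.append(Peak(fields[0], int(fields[1]), height))
    return peaks
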