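"""Position weight matrices with exact p-values and two-strand scanning.

A motif is modelled as a position probability matrix scored in log2-odds
(bits) against a 0-order background.  The p-value of a score is the tail
probability, under the background, that a random word of the motif's length
scores at least as high — computed exactly by dynamic-programming
convolution of the per-position score distributions on a discretized score
lattice.  Scanning slides the matrix over both strands of a sequence;
bottom-strand windows are scored through the reverse-complement matrix and
reported at their reference coordinates.
"""

from __future__ import annotations

import dataclasses
import io as _io
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}
_BASE_CODE.update({ord(b.lower()): i for i, b in enumerate(BASES)})
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

#: log2-odds assigned to zero-probability cells so every word keeps a
#: finite score; far below anything reachable near usual thresholds.
LOG_ODDS_FLOOR = -10.0

#: score lattice resolution, in bits
SCORE_RESOLUTION = 1e-3


class DegenerateMatrixError(ValueError):
    """A count row is all zero and no pseudocount rescues it."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3; anything else -> 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, 4, dtype=np.int64)
    for byte, code in _BASE_CODE.items():
        codes[raw == byte] = code
    return codes


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]


@dataclasses.dataclass(slots=True)
class MotifHit:
    """A scored motif occurrence on one strand of a reference sequence.

    Coordinates are 0-based half-open on the reference; ``strand`` is "+"
    (top) or "-" (bottom).  ``score`` is log2-odds in bits, ``pvalue`` the
    exact background tail probability of that score.
    """

    contig: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float


def exact_pvalue_table(
    log_odds: np.ndarray,
    background: np.ndarray,
    granularity: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Build the exact score-tail table for a log-odds matrix.

    Scores are discretized to an integer lattice (``SCORE_RESOLUTION`` bits
    per unit, or finer if ``granularity`` demands more bins) and the
    distribution of the total score of a random background word is obtained
    by convolving the per-position distributions.

    Returns ``(int_scores, tail, min_total)`` where ``int_scores`` is the
    integer score matrix used for scanning, ``tail[k]`` is
    ``P(score_int >= min_total + k)``, and ``tail[0] == 1``.
    """
    log_odds = np.asarray(log_odds, dtype=float)
    background = np.asarray(background, dtype=float)
    eps = SCORE_RESOLUTION
    span = float((log_odds.max(axis=1) - log_odds.min(axis=1)).sum())
    if granularity is not None and granularity >= 1:
        eps = min(eps, span / granularity) if span > 0 else eps
    int_scores = np.rint(log_odds / eps).astype(np.int64)

    dist = np.array([1.0])
    min_total = 0
    for row in int_scores:
        rmin, rmax = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + (rmax - rmin), dtype=float)
        for b in range(4):
            off = int(row[b]) - rmin
            new[off : off + len(dist)] += background[b] * dist
        dist = new
        min_total += rmin
    tail = dist[::-1].cumsum()[::-1]
    # guard against accumulated round-off; total mass is 1 by construction
    tail = np.minimum(tail / tail[0], 1.0)
    return int_scores, tail, min_total


class MotifModel:
    """A probability matrix with log-odds scores and an exact p-value table.

    Parameters
    ----------
    counts:
        length x 4 non-negative matrix (columns A, C, G, T).
    pseudocount:
        added to every cell before row normalization.
    background:
        4-vector of base probabilities; uniform if omitted.
    """

    def __init__(
        self,
        counts: Sequence[Sequence[float]] | np.ndarray,
        pseudocount: float = 1.0,
        background: Sequence[float] | None = None,
        name: str = "motif",
        granularity: int | None = None,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a length x 4 matrix (A,C,G,T)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        work = counts + pseudocount
        rowsums = work.sum(axis=1)
        if (rowsums <= 0).any():
            bad = int(np.flatnonzero(rowsums <= 0)[0])
            raise DegenerateMatrixError(
                f"row {bad} has zero total count and zero pseudocount"
            )
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or (background <= 0).any():
            raise ValueError("background must be 4 positive probabilities")
        background = background / background.sum()

        self.name = name
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.background = background
        self.probabilities = work / rowsums[:, None]
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probabilities / background[None, :])
        self.log_odds = np.maximum(lo, LOG_ODDS_FLOOR)
        self._int_scores, self._tail, self._min_total = exact_pvalue_table(
            self.log_odds, background, granularity
        )
        # reverse-complement integer matrix: scoring a window with it equals
        # scoring the window's reverse complement with the forward matrix
        self._int_scores_rc = self._int_scores[::-1][:, _COMPLEMENT]

    # ------------------------------------------------------------------
    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        """The same motif read on the opposite strand."""
        rc_counts = self.counts[::-1][:, [3, 2, 1, 0]]
        return MotifModel(
            rc_counts,
            pseudocount=self.pseudocount,
            background=self.background[[3, 2, 1, 0]],
            name=self.name + "_rc",
        )

    def sample_instance(self, rng: np.random.Generator) -> str:
        """Draw one word from the probability matrix."""
        return "".join(
            BASES[rng.choice(4, p=row)] for row in self.probabilities
        )

    # ------------------------------------------------------------------
    def score(self, word: str) -> float:
        """Log2-odds score of one word, in bits (lattice-rounded)."""
        codes = encode_sequence(word)
        if len(codes) != self.length or (codes > 3).any():
            raise ValueError("word must be ACGT of the motif's length")
        s = int(self._int_scores[np.arange(self.length), codes].sum())
        return s * SCORE_RESOLUTION

    def pvalue_of_int(self, int_score: np.ndarray | int) -> np.ndarray | float:
        idx = np.clip(np.asarray(int_score) - self._min_total, 0, len(self._tail) - 1)
        out = self._tail[idx]
        return float(out) if np.isscalar(int_score) else out

    def pvalue(self, word: str) -> float:
        codes = encode_sequence(word)
        s = int(self._int_scores[np.arange(self.length), codes].sum())
        return float(self.pvalue_of_int(s))

    def min_score(self) -> float:
        return self._min_total * SCORE_RESOLUTION


def build_motif(
    counts,
    pseudocount: float = 1.0,
    background=None,
    name: str = "motif",
    granularity: int | None = None,
) -> MotifModel:
    """Construct a :class:`MotifModel` from a count matrix."""
    return MotifModel(counts, pseudocount, background, name, granularity)


def background_from_sequence(seq: str) -> np.ndarray:
    """0-order background estimated from a sequence (ACGT only)."""
    codes = encode_sequence(seq)
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts += 1.0  # never return a zero probability
    return counts / counts.sum()


def scan_sequence(
    seq: str,
    model: MotifModel,
    p_threshold: float = 1e-3,
    contig: str = "seq",
) -> list[MotifHit]:
    """All motif occurrences on both strands with p-value < ``p_threshold``.

    Every length-L window is scored on the top strand and, through the
    reverse-complement matrix, on the bottom strand; windows containing
    non-ACGT characters are skipped.  Hits are reported at reference
    coordinates, sorted by start, and use a strict ``<`` threshold.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    L = model.length
    codes = encode_sequence(seq)
    n = len(codes) - L + 1
    if n <= 0:
        return []

    invalid = (codes > 3).astype(np.int64)
    bad_cum = np.concatenate([[0], invalid.cumsum()])
    window_ok = (bad_cum[L:] - bad_cum[:-L]) == 0
    safe = np.where(codes > 3, 0, codes)

    scores_top = np.zeros(n, dtype=np.int64)
    scores_bot = np.zeros(n, dtype=np.int64)
    for j in range(L):
        col = safe[j : j + n]
        scores_top += model._int_scores[j][col]
        scores_bot += model._int_scores_rc[j][col]

    hits: list[MotifHit] = []
    for strand, scores in (("+", scores_top), ("-", scores_bot)):
        p = model.pvalue_of_int(scores)
        sel = np.flatnonzero(window_ok & (p < p_threshold))
        for i in sel:
            hits.append(
                MotifHit(
                    contig=contig,
                    start=int(i),
                    end=int(i) + L,
                    strand=strand,
                    score=float(scores[i]) * SCORE_RESOLUTION,
                    pvalue=float(p[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ----------------------------------------------------------------------
# matrix file readers (JASPAR / TRANSFAC dialects, via Bio.motifs)

def read_matrix_file(path: str, fmt: str = "jaspar") -> MotifModel:
    """Read the first count matrix from a JASPAR- or TRANSFAC-style file.

    ``fmt`` is "jaspar" or "transfac".  Returns an unscored count matrix
    wrapped in a :class:`MotifModel` with default pseudocount and uniform
    background; rebuild with :func:`build_motif` for other settings.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, fmt)
        record = next(iter(records))
    counts = np.array([list(record.counts[b]) for b in BASES], dtype=float).T
    name = getattr(record, "name", None) or getattr(record, "matrix_id", None) or "motif"
    return MotifModel(counts, name=str(name))


def write_jaspar(model: MotifModel, path: str) -> None:
    """Write a model's count matrix in JASPAR (pfm) layout."""
    buf = _io.StringIO()
    buf.write(f">{model.name}\n")
    for i, base in enumerate(BASES):
        row = " ".join(f"{v:.2f}" for v in model.counts[:, i])
        buf.write(f"{base}  [ {row} ]\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def forkhead_like_motif(pseudocount: float = 1.0, background=None) -> MotifModel:
    """A synthetic forkhead-family PWM (consensus TGTTTACATG).

    Built for this package's simulations — not a database matrix.  The
    7-bp TGTTTAC core is strongly constrained, as in forkhead-family
    motifs; the 3-bp 3' tail is weakly constrained so palindromically
    overlapping dimer instances remain high-scoring.
    """
    strong = {b: [1, 1, 1, 1] for b in BASES}
    for b in BASES:
        strong[b][BASES.index(b)] = 97
    weak = {b: [20, 20, 20, 20] for b in BASES}
    for b in BASES:
        weak[b][BASES.index(b)] = 40
    rows = [strong[b] for b in "TGTTTAC"] + [weak[b] for b in "ATG"]
    return MotifModel(
        np.array(rows, dtype=float),
        pseudocount=pseudocount,
        background=background,
        name="FKH_synthetic",
    )
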