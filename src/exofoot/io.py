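"""File I/O: FASTA (Biopython), SAM (pysam), BED6 and interval BED.

Internal coordinates are 0-based half-open everywhere; SAM is written
1-based as the format requires (pysam handles the shift).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import BOTTOM, TOP, AlignedRead


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    try:
        SeqIO.write(records, path, "fasta")
    except OSError as exc:
        raise OSError(f"cannot write FASTA to {path}: {exc}") from exc


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ----------------------------------------------------------------------
# SAM

def write_sam(
    path: str, reads: Sequence[AlignedRead], contig_lengths: Mapping[str, int]
) -> None:
    """Write reads as a coordinate-sorted SAM file with @SQ headers."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
        }
    )
    order = {name: i for i, name in enumerate(contig_lengths)}
    sorted_reads = sorted(reads, key=lambda r: (order[r.contig], r.start, r.end, r.strand))
    try:
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for i, read in enumerate(sorted_reads):
                seg = pysam.AlignedSegment(header)
                seg.query_name = f"read{i:08d}"
                seg.flag = 16 if read.strand == BOTTOM else 0
                seg.reference_id = order[read.contig]
                seg.reference_start = read.start
                seg.mapping_quality = read.mapq
                seg.cigarstring = f"{read.length}M"
                out.write(seg)
    except OSError as exc:
        raise OSError(f"cannot write SAM to {path}: {exc}") from exc


def read_sam(path: str) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(path, "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand=BOTTOM if seg.is_reverse else TOP,
                    mapq=seg.mapping_quality,
                )
            )
    return reads


# ----------------------------------------------------------------------
# BED

def write_reads_bed(path: str, reads: Sequence[AlignedRead]) -> None:
    """Reads as BED6: name is a serial, score carries the mapq."""
    try:
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\tread{i:08d}\t{r.mapq}\t{r.strand}\n")
    except OSError as exc:
        raise OSError(f"cannot write BED to {path}: {exc}") from exc


def read_reads_bed(path: str) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            mapq = int(float(fields[4])) if len(fields) > 4 else 0
            strand = fields[5] if len(fields) > 5 else TOP
            reads.append(AlignedRead(contig, start, end, strand, mapq))
    return reads


def write_hits_bed(path: str, hits) -> None:
    """Motif hits as BED6+2: extra columns are log2-odds score and p-value."""
    try:
        with open(path, "w") as fh:
            for i, h in enumerate(hits):
                fh.write(
                    f"{h.contig}\t{h.start}\t{h.end}\thit{i:08d}\t0\t{h.strand}"
                    f"\t{h.score:.4f}\t{h.pvalue:.6g}\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write hits BED to {path}: {exc}") from exc


def read_hits_bed(path: str):
    from .motifs import MotifHit

    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            hits.append(
                MotifHit(f[0], int(f[1]), int(f[2]), f[5],
                         float(f[6]), float(f[7]))
            )
    return hits


def read_interval_bed(path: str) -> list[tuple[str, int, int]]:
    """Plain (contig, start, end) triples from a BED file (blacklists etc.)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
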