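"""Long-read-to-assembly alignments and per-contig allele pileups.

The polisher consumes reads already mapped to the draft assembly (SAM).  Each
alignment is reduced to a per-reference-column *allele*:

* a single base for an aligned (match or mismatch) column,
* ``"-"`` for a reference column the read deletes,
* a multi-base string for an aligned base followed by an insertion, which is
  attached to the reference column of its left anchor base.

Anchoring insertions to the preceding reference column keeps every column of
the pileup indexable by reference position, which the K-mer score chain
consensus relies on.  Coordinates are 0-based half-open throughout; SAM's
1-based convention exists only inside pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S, _CIGAR_H = 0, 1, 2, 3, 4, 5
_CIGAR_P, _CIGAR_EQ, _CIGAR_X = 6, 7, 8
_CONSUMES_BOTH = {_CIGAR_M, _CIGAR_EQ, _CIGAR_X}
_KNOWN_OPS = {_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_S, _CIGAR_H, _CIGAR_EQ, _CIGAR_X}


@dataclass
class AlignedRead:
    """One primary alignment of a long read to one draft contig."""

    read_id: str
    contig: str
    start: int  # 0-based inclusive reference coordinate
    end: int  # 0-based exclusive
    mapq: int
    alleles: dict[int, str]  # column index -> allele string
    sequence: str

    def covers(self, start: int, end: int) -> bool:
        """Whether the alignment fully spans [start, end)."""
        return self.start <= start and self.end >= end


@dataclass
class Pileup:
    """Per-contig columns of read alleles with valid depth.

    ``columns[p]`` maps each observed allele string at reference position
    ``p`` to the set of read ids supporting it; ``valid_depth[p]`` is the
    number of reads contributing an allele at ``p`` after filtering.
    """

    contig: str
    ref_seq: str
    columns: list[dict[str, set[str]]]
    valid_depth: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.ref_seq)


class AlignmentFormatError(ValueError):
    """Raised for malformed SAM records or unusable CIGARs."""


def _alleles_from_cigar(
    cigartuples: list[tuple[int, int]],
    seq: str,
    ref_start: int,
    read_id: str,
) -> tuple[dict[int, str], int]:
    """Walk a CIGAR, producing the column->allele map and the reference end."""
    alleles: dict[int, str] = {}
    rpos = ref_start
    qpos = 0
    for op, length in cigartuples:
        if op not in _KNOWN_OPS:
            raise AlignmentFormatError(
                f"read {read_id!r}: unsupported CIGAR operation code {op}"
            )
        if op in _CONSUMES_BOTH:
            for i in range(length):
                alleles[rpos + i] = seq[qpos + i]
            rpos += length
            qpos += length
        elif op == _CIGAR_I:
            # attach to the left anchor column; a leading insertion has no
            # anchor inside the alignment and is dropped.  An insertion whose
            # anchor is a deletion allele replaces it (the read has these
            # bases *instead of* the anchor's reference base).
            anchor = rpos - 1
            if anchor in alleles:
                ins = seq[qpos : qpos + length]
                if alleles[anchor] == "-":
                    alleles[anchor] = ins
                else:
                    alleles[anchor] += ins
            qpos += length
        elif op == _CIGAR_D:
            for i in range(length):
                alleles[rpos + i] = "-"
            rpos += length
        elif op == _CIGAR_S:
            qpos += length
        # H: consumes nothing we track
    return alleles, rpos


def load_alignments(
    sam_path: str | Path,
    region: str | None = None,
    min_mapq: int = 1,
) -> list[AlignedRead]:
    """Load primary long-read alignments from a SAM/BAM file.

    Secondary (0x100), supplementary (0x800) and unmapped records are
    dropped, as are records below ``min_mapq`` (default 1: multi-mappers
    reported at MAPQ 0 are excluded).  ``region`` restricts to one contig or
    ``contig:start-end`` (0-based half-open; requires an index for BAM, plain
    iteration with filtering for SAM).
    """
    sam_path = Path(sam_path)
    reads: list[AlignedRead] = []
    contig_filter: str | None = None
    span_filter: tuple[int, int] | None = None
    if region is not None:
        if ":" in region:
            contig_filter, span = region.split(":", 1)
            lo, hi = span.split("-", 1)
            span_filter = (int(lo), int(hi))
        else:
            contig_filter = region
    with pysam.AlignmentFile(str(sam_path), check_sq=True) as fh:
        if not fh.header.references:
            raise AlignmentFormatError(f"{sam_path}: SAM header lacks @SQ lines")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if contig_filter is not None and rec.reference_name != contig_filter:
                continue
            seq = rec.query_sequence
            if seq is None or rec.cigartuples is None:
                logger.warning("read %s: missing SEQ or CIGAR, skipped", rec.query_name)
                continue
            alleles, ref_end = _alleles_from_cigar(
                rec.cigartuples, seq, rec.reference_start, rec.query_name
            )
            if span_filter is not None and (
                ref_end <= span_filter[0] or rec.reference_start >= span_filter[1]
            ):
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=ref_end,
                    mapq=rec.mapping_quality,
                    alleles=alleles,
                    sequence=seq,
                )
            )
    return reads


def build_pileup(contig_seq: str, reads: list[AlignedRead], contig: str = "") -> Pileup:
    """Assemble per-column allele support over one contig.

    All reads must belong to the same contig; coordinates beyond the contig
    length raise :class:`AlignmentFormatError`.
    """
    n = len(contig_seq)
    columns: list[dict[str, set[str]]] = [dict() for _ in range(n)]
    depth = np.zeros(n, dtype=np.int32)
    if reads and not contig:
        contig = reads[0].contig
    for read in reads:
        if contig and read.contig != contig:
            raise AlignmentFormatError(
                f"read {read.read_id!r} on contig {read.contig!r}, expected {contig!r}"
            )
        if read.end > n or read.start < 0:
            raise AlignmentFormatError(
                f"read {read.read_id!r} spans [{read.start},{read.end}) beyond "
                f"contig length {n}"
            )
        for pos, allele in read.alleles.items():
            col = columns[pos]
            if allele in col:
                col[allele].add(read.read_id)
            else:
                col[allele] = {read.read_id}
            depth[pos] += 1
    return Pileup(contig=contig, ref_seq=contig_seq, columns=columns, valid_depth=depth)
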