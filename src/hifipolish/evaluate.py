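"""Assembly assessment: K-mer changes, overcorrection, QV, switch errors.

Two complementary K-mer change metrics quantify overcorrection risk:

* **changed K-mers** — K-mers present in a polished assembly but not in the
  assembly it was derived from.  A single new K-mer of length k can drag in
  up to ``2k - 1`` overlapping new K-mers, so even one substitution inflates
  this count by up to 2k-1.
* **potential overcorrection K-mers** — the subset of changed K-mers that are
  *also* absent from the sample's short reads.  Haplotype switches add
  changed K-mers but no overcorrection K-mers (the other haplotype's K-mers
  are real sequence); true overcorrections add both.

Quality values are Phred-scaled error rates (QV = -10*log10(error)):

* the K-mer QV derives the per-base error rate from the fraction of assembly
  K-mers supported by short reads, ``E = 1 - (shared/total)**(1/k)``;
* the alignment QV pools match/block lengths of (pseudo-)read-to-assembly
  PAF records, ``QV = -10*log10(1 - match/block)``, after removing
  alignments with coverage <= 90% or identity <= 98% (inclusive removal).

The switch-error metric assigns each heterozygous site of the polished
sequence to a parental haplotype by its distinguishing K-mer and counts
adjacent pairs of het sites with different assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .kmer_db import KmerDB, _window_codes

QV_CEILING = 99.0  # reported for zero-error cases


@dataclass
class PafRecord:
    """One alignment line in minimap2 PAF format (columns 1-12)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int

    @property
    def coverage(self) -> float:
        """Alignment block length over query length."""
        return self.blocklen / self.qlen if self.qlen else 0.0

    @property
    def identity(self) -> float:
        return self.nmatch / self.blocklen if self.blocklen else 0.0


@dataclass
class SwitchErrorResult:
    switches: int
    het_sites: int  # sites successfully assigned to a haplotype
    rate: float  # switches / (het_sites - 1); 0 when fewer than 2 sites
    n_unassigned: int = 0
    degenerate: bool = False  # fewer than 2 assignable sites


@dataclass
class EvalReport:
    """Aggregated assessment of one polished assembly."""

    changed_kmers: int = 0
    overcorrection_kmers: int = 0
    kmer_qv: float = float("nan")
    alignment_qv: float = float("nan")
    switch_errors: int = 0
    switch_rate: float = 0.0
    n_filtered_alignments: int = 0

    def to_dict(self) -> dict:
        return {
            "changed_kmers": self.changed_kmers,
            "overcorrection_kmers": self.overcorrection_kmers,
            "kmer_qv": self.kmer_qv,
            "alignment_qv": self.alignment_qv,
            "switch_errors": self.switch_errors,
            "switch_rate": self.switch_rate,
            "n_filtered_alignments": self.n_filtered_alignments,
        }


def _as_sequences(assembly: str | Sequence[str]) -> list[str]:
    if isinstance(assembly, str):
        return [assembly]
    return list(assembly)


def kmer_code_set(assembly: str | Sequence[str], k: int) -> np.ndarray:
    """Sorted unique canonical K-mer codes of an assembly."""
    chunks = [_window_codes(seq, k) for seq in _as_sequences(assembly)]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def changed_kmers(
    polished: str | Sequence[str], original: str | Sequence[str], k: int = 21
) -> int:
    """Count K-mers present in the polished assembly but not the original."""
    pset = kmer_code_set(polished, k)
    oset = kmer_code_set(original, k)
    return int(np.setdiff1d(pset, oset, assume_unique=True).size)


def overcorrection_kmers(
    polished: str | Sequence[str],
    original: str | Sequence[str],
    short_read_db: KmerDB,
) -> int:
    """Count K-mers in the polished assembly absent from both the original
    assembly and the short reads."""
    k = short_read_db.k
    pset = kmer_code_set(polished, k)
    oset = kmer_code_set(original, k)
    new = np.setdiff1d(pset, oset, assume_unique=True)
    if new.size == 0:
        return 0
    db_codes = np.sort(short_read_db.code_set())
    return int(np.setdiff1d(new, db_codes, assume_unique=True).size)


def read_paf(path: str | Path) -> list[PafRecord]:
    """Parse a PAF file (minimap2 dialect; tags beyond column 12 ignored)."""
    records: list[PafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: PAF line has {len(fields)} fields, "
                    "expected at least 12"
                )
            try:
                records.append(
                    PafRecord(
                        qname=fields[0],
                        qlen=int(fields[1]),
                        qstart=int(fields[2]),
                        qend=int(fields[3]),
                        strand=fields[4],
                        tname=fields[5],
                        tlen=int(fields[6]),
                        tstart=int(fields[7]),
                        tend=int(fields[8]),
                        nmatch=int(fields[9]),
                        blocklen=int(fields[10]),
                        mapq=int(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line") from exc
    return records


def alignment_qv(
    paf_records: Iterable[PafRecord] | str | Path,
    min_coverage: float = 0.90,
    min_identity: float = 0.98,
) -> tuple[float, int]:
    """Phred-scaled QV from pooled alignment identity.

    Records with coverage <= ``min_coverage`` or identity <= ``min_identity``
    are removed (inclusive, as the filters are stated); the QV is
    ``-10*log10(1 - sum(match)/sum(block))`` over the survivors, capped at
    99 when every base matches.  Returns ``(qv, n_kept)``; no surviving
    records give ``(nan, 0)``.
    """
    if isinstance(paf_records, (str, Path)):
        paf_records = read_paf(paf_records)
    kept = [
        r
        for r in paf_records
        if r.coverage > min_coverage and r.identity > min_identity
    ]
    if not kept:
        return float("nan"), 0
    match = sum(r.nmatch for r in kept)
    block = sum(r.blocklen for r in kept)
    if match >= block:
        return QV_CEILING, len(kept)
    return -10.0 * math.log10(1.0 - match / block), len(kept)


def kmer_qv(
    assembly: str | Sequence[str], short_read_db: KmerDB, k: int | None = None
) -> float:
    """Phred-scaled QV from the short-read support of assembly K-mers.

    The per-base error rate is ``E = 1 - (shared/total)**(1/k)`` over all
    K-mer instances of the assembly; QV = -10*log10(E), capped at 99 when
    every K-mer is supported.  Raises ``ValueError`` on an assembly with no
    K-mers.
    """
    k = k or short_read_db.k
    if k != short_read_db.k:
        raise ValueError(f"k={k} does not match database k={short_read_db.k}")
    chunks = [_window_codes(seq, k) for seq in _as_sequences(assembly)]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        raise ValueError("assembly contains no K-mers")
    codes = np.concatenate(chunks)
    db_codes = np.sort(short_read_db.code_set())
    shared = int(np.isin(codes, db_codes, assume_unique=False).sum())
    total = int(codes.size)
    if shared >= total:
        return QV_CEILING
    error = 1.0 - (shared / total) ** (1.0 / k)
    return -10.0 * math.log10(error)


def _het_sites_from_alignment(hap1: str, hap2: str) -> list[tuple[int, int]]:
    """(hap1 pos, hap2 pos) of each differing site, via edlib alignment."""
    res = edlib.align(hap2, hap1, task="path", mode="NW")
    sites: list[tuple[int, int]] = []
    p1 = p2 = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            p1 += n
            p2 += n
        elif op == "X":
            for i in range(n):
                sites.append((p1 + i, p2 + i))
            p1 += n
            p2 += n
        elif op == "D":  # in hap1 (target), absent from hap2
            sites.append((p1, max(0, p2 - 1)))
            p1 += n
        elif op == "I":  # in hap2 (query), absent from hap1
            sites.append((max(0, p1 - 1), p2))
            p2 += n
    return sites


def _cigar_ops(cigar: str) -> Iterable[tuple[int, str]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def switch_error(
    polished: str | Sequence[str],
    hap1_truth: str,
    hap2_truth: str,
    k: int = 21,
    het_sites: list[tuple[int, int]] | None = None,
) -> SwitchErrorResult:
    """Count haplotype switches along the polished sequence.

    Each heterozygous site (derived from the two truth haplotypes, or passed
    in as ``(hap1_pos, hap2_pos)`` pairs) is assigned to a haplotype by which
    distinguishing K-mer — the k-base window centred on the site in either
    haplotype — appears in the polished assembly.  Sites whose K-mers appear
    in both or neither are unassigned and excluded from adjacent pairs.  A
    switch is an adjacent pair of assigned sites with different haplotypes;
    the rate is switches per adjacent pair.
    """
    if het_sites is None:
        het_sites = _het_sites_from_alignment(hap1_truth, hap2_truth)
    pset = set(kmer_code_set(polished, k).tolist())
    half = k // 2

    def _code(seq: str, pos: int) -> int | None:
        lo = max(0, min(len(seq) - k, pos - half))
        window = seq[lo : lo + k]
        if len(window) < k or any(c not in "ACGT" for c in window):
            return None
        codes = _window_codes(window, k)
        return int(codes[0]) if codes.size else None

    assignments: list[int] = []
    n_unassigned = 0
    for p1, p2 in het_sites:
        c1 = _code(hap1_truth, p1)
        c2 = _code(hap2_truth, p2)
        in1 = c1 is not None and c1 in pset
        in2 = c2 is not None and c2 in pset
        if c1 is not None and c1 == c2:
            continue  # window does not distinguish the haplotypes
        if in1 and not in2:
            assignments.append(1)
        elif in2 and not in1:
            assignments.append(2)
        else:
            n_unassigned += 1
    switches = sum(
        1 for a, b in zip(assignments, assignments[1:]) if a != b
    )
    n = len(assignments)
    if n < 2:
        return SwitchErrorResult(0, n, 0.0, n_unassigned, degenerate=True)
    return SwitchErrorResult(switches, n, switches / (n - 1), n_unassigned)


def evaluate_assembly(
    polished: str | Sequence[str],
    original: str | Sequence[str],
    short_read_db: KmerDB | None = None,
    k: int = 21,
    paf: Iterable[PafRecord] | str | Path | None = None,
    hap_truth: tuple[str, str] | None = None,
) -> EvalReport:
    """Convenience aggregator producing a full :class:`EvalReport`."""
    report = EvalReport()
    report.changed_kmers = changed_kmers(polished, original, k)
    if short_read_db is not None:
        report.overcorrection_kmers = overcorrection_kmers(
            polished, original, short_read_db
        )
        report.kmer_qv = kmer_qv(polished, short_read_db)
    if paf is not None:
        report.alignment_qv, report.n_filtered_alignments = alignment_qv(paf)
    if hap_truth is not None:
        res = switch_error(polished, hap_truth[0], hap_truth[1], k=k)
        report.switch_errors = res.switches
        report.switch_rate = res.rate
    return report
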