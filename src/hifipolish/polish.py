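"""Per-contig polishing: phasing, final consensus, residual-LQR resolution.

After phasing has removed reads from conflicting haplotypes/repeat copies,
the K-mer score chain consensus is regenerated from the surviving reads.  A
few low-quality regions (LQRs) usually remain; they are resolved by the
short-read K-mer evidence:

* no valid K-mer spans the region  -> keep the reference (draft) sequence,
  the conservative choice that avoids overcorrection;
* exactly one or several valid K-mers span it -> splice in the K-mer with
  the highest short-read count (ties prefer the reference-matching K-mer,
  then the lexicographically smallest);
* the region is longer than k     -> splice the most common spanning read
  subsequence, accepted only if every one of its K-mers is valid, else fall
  back to the reference.

All edits are applied in the reference-column frame: the consensus is a
per-column emission (base, empty string for a deletion, base+insertion
string), so splices never require realignment and the edit ledger maps
1:1 onto draft coordinates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .alignment_io import AlignedRead, build_pileup
from .kmer_db import KmerDB, db_for_k
from .ksc import LQR, detect_lqps, ksc_consensus, merge_lqrs
from .phasing import (
    IterationRecord,
    LqrKmerSet,
    PhasingParams,
    extract_lqr_kmers,
    iterate_phasing,
)

logger = logging.getLogger(__name__)

RULE_REFERENCE = "reference_kmer"
RULE_BEST_COUNT = "best_count_kmer"
RULE_MAJORITY = "majority"


@dataclass
class ResidualResolution:
    """How one residual LQR was resolved."""

    lqr: LQR
    rule: str
    chosen_kmer: str


@dataclass
class PolishReport:
    """Per-contig polishing summary."""

    contig: str
    n_lqrs_initial: int = 0
    n_iterations: int = 0
    n_reads_discarded: int = 0
    converged: bool = True
    residual_resolutions: list[ResidualResolution] = field(default_factory=list)
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    iteration_log: list[IterationRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "contig": self.contig,
            "n_lqrs_initial": self.n_lqrs_initial,
            "n_iterations": self.n_iterations,
            "n_reads_discarded": self.n_reads_discarded,
            "converged": self.converged,
            "n_edits": len(self.edits),
            "edits": [
                {"position": p, "ref": r, "alt": a} for p, r, a in self.edits
            ],
            "residual_resolutions": [
                {
                    "start": rr.lqr.start,
                    "end": rr.lqr.end,
                    "rule": rr.rule,
                    "chosen_kmer": rr.chosen_kmer,
                }
                for rr in self.residual_resolutions
            ],
            "warnings": self.warnings,
        }


def resolve_residual_lqr(
    lqr: LQR,
    kmer_set: LqrKmerSet,
    ref_seq: str,
    dbs: list[KmerDB] | KmerDB,
    reads: list[AlignedRead] | None = None,
    min_support: int = 1,
) -> tuple[str, str, dict[int, str] | None]:
    """Choose the correct K-mer for a residual LQR.

    Returns ``(chosen_kmer, rule, emissions)`` where ``emissions`` maps
    reference columns to replacement allele strings (``None`` means keep the
    draft sequence untouched).  A candidate carried by fewer than
    ``min_support`` reads is not trusted and the reference is kept instead.
    """
    if kmer_set.all_valid:
        k = len(next(iter(kmer_set.all_valid)))
    elif isinstance(dbs, KmerDB):
        k = dbs.k
    else:
        k = dbs[0].k
    db = db_for_k(dbs, k)

    if len(lqr) > k:
        return _resolve_long_lqr(lqr, ref_seq, db, reads or [])

    candidates = kmer_set.all_valid
    anchor = kmer_set.canonical_anchor
    ref_window = ref_seq[anchor : anchor + k] if anchor >= 0 else ""
    if not candidates:
        # no valid K-mer spans the region: keep the reference K-mer
        return ref_window, RULE_REFERENCE, None
    # the K-mer with the highest number wins: HiFi-read support first (the
    # reads surviving phasing are the locus's own haplotype, so their vote
    # outranks the diploid short-read pool), then the short-read count; ties
    # prefer the reference K-mer, then the lexicographically smallest
    best = max(
        sorted(candidates),
        key=lambda km: (
            kmer_set.support.get(km, 0),
            candidates[km],
            km == ref_window,
            _neg_lex(km),
        ),
    )
    if kmer_set.support.get(best, 0) < min_support:
        return ref_window, RULE_REFERENCE, None
    # reads carrying the same K-mer may align it over different column
    # ranges (indel shifts inside homopolymer runs); splice over the
    # best-supported span, as the K-mer string itself
    span_votes = kmer_set.spans[best]
    k_len = len(best)
    (lo, hi), _n = max(
        sorted(span_votes.items()),
        key=lambda item: (item[1], -abs(item[0][1] - item[0][0] + 1 - k_len)),
    )
    # map the K-mer string back onto its reference columns char by char
    # (left-aligned; surplus chars ride on the last column, missing columns
    # emit nothing), so overlapping windows of nearby LQRs stay consistent
    ncols = hi - lo + 1
    emissions: dict[int, str] = {}
    if k_len >= ncols:
        for i in range(ncols - 1):
            emissions[lo + i] = best[i]
        emissions[hi] = best[ncols - 1 :]
    else:
        for i in range(k_len):
            emissions[lo + i] = best[i]
        for c in range(lo + k_len, hi + 1):
            emissions[c] = ""
    return best, RULE_BEST_COUNT, emissions


def _neg_lex(km: str) -> tuple[int, ...]:
    """Key making ``max`` prefer the lexicographically *smallest* K-mer."""
    return tuple(-ord(c) for c in km)


def _resolve_long_lqr(
    lqr: LQR, ref_seq: str, db: KmerDB, reads: list[AlignedRead]
) -> tuple[str, str, dict[int, str] | None]:
    """Residual LQR longer than k: use the best-supported spanning read
    subsequence, validated K-mer by K-mer; fall back to the reference."""
    k = db.k
    wstart = max(0, lqr.start - (k - 1))
    wend = lqr.end + (k - 1)
    votes: Counter[tuple[tuple[int, str], ...]] = Counter()
    for read in sorted(reads, key=lambda r: r.read_id):
        if not read.covers(wstart, wend):
            continue
        emission = tuple(
            (c, read.alleles.get(c, "")) for c in range(wstart, min(wend, len(ref_seq)))
        )
        votes[emission] += 1
    for emission, _n in votes.most_common():
        seq = "".join(a for _c, a in emission if a != "-")
        if len(seq) < k:
            continue
        if all(db.is_valid(seq[i : i + k]) for i in range(len(seq) - k + 1)):
            emissions = {c: ("" if a == "-" else a) for c, a in emission}
            return seq[:k], RULE_MAJORITY, emissions
    return ref_seq[lqr.start : lqr.start + k], RULE_REFERENCE, None


def _splice_is_supported(
    emissions: list[str],
    repl: dict[int, str],
    ref_seq: str,
    db: KmerDB,
    k: int,
) -> bool:
    """Whether applying ``repl`` leaves only supported K-mers locally.

    Builds the spliced sequence over the replacement columns plus k-1
    flanking columns and checks every K-mer not already present in the
    corresponding draft window against the short-read database.  Junction
    K-mers straddle the splice boundary, so this is the only place a
    resolution could smuggle in sequence supported by neither the reads'
    consensus nor the short reads.
    """
    lo, hi = min(repl), max(repl)
    wlo, whi = max(0, lo - (k - 1)), min(len(emissions) - 1, hi + (k - 1))
    parts = []
    for c in range(wlo, whi + 1):
        parts.append(repl[c] if c in repl else emissions[c])
    spliced = "".join(parts)
    draft_window = ref_seq[wlo : whi + 1]
    for i in range(len(spliced) - k + 1):
        kmer = spliced[i : i + k]
        if kmer in draft_window:
            continue
        if not db.is_valid(kmer):
            return False
    return True


def polish_contig(
    contig_seq: str,
    reads: list[AlignedRead],
    dbs: list[KmerDB] | KmerDB,
    params: PhasingParams | None = None,
    contig: str = "contig",
) -> tuple[str, PolishReport]:
    """Polish one contig and report every change.

    Runs the phasing loop, regenerates the consensus from surviving reads,
    resolves remaining LQRs via the short-read K-mer rules, and emits the
    final sequence plus a :class:`PolishReport`.  A contig with zero coverage
    is returned unchanged with a warning.
    """
    params = params or PhasingParams()
    report = PolishReport(contig=contig)
    if not reads:
        msg = f"contig {contig!r}: no reads, returned unchanged"
        logger.warning(msg)
        report.warnings.append(msg)
        return contig_seq, report

    survivors, log, converged = iterate_phasing(contig_seq, reads, dbs, params)
    report.iteration_log = log
    report.n_iterations = len(log)
    report.n_reads_discarded = len(reads) - len(survivors)
    report.converged = converged
    if log:
        report.n_lqrs_initial = log[0].n_lqrs
    if not converged:
        report.warnings.append(
            f"conflicts unresolved after {params.max_iters} iterations"
        )
    if not survivors:
        msg = f"contig {contig!r}: all reads discarded, returned unchanged"
        logger.warning(msg)
        report.warnings.append(msg)
        return contig_seq, report

    pileup = build_pileup(contig_seq, survivors)
    _, trace = ksc_consensus(pileup, chain_k=params.chain_k)
    lqps = detect_lqps(trace, threshold=params.lqp_threshold)
    residual_lqrs = merge_lqrs(
        lqps,
        merge_gap=params.merge_gap,
        contig_len=len(contig_seq),
        pad=0,
        contig=contig,
    )

    # per-column emissions from the traceback.  Columns covered by fewer
    # than min_confirm_depth reads keep the draft base: a lone read's
    # sequencing error would otherwise be adopted with nominal full
    # support, the depth<=3 regime where residual assembly errors
    # concentrate.  Zero-coverage columns fall under the same rule.
    emissions: list[str] = []
    for node in trace:
        if int(pileup.valid_depth[node.position]) < params.min_confirm_depth:
            emissions.append(contig_seq[node.position])
        elif node.allele == "-":
            emissions.append("")
        else:
            emissions.append(node.allele)

    db = db_for_k(dbs, params.k)
    for lqr in residual_lqrs:
        kmer_set = extract_lqr_kmers(survivors, lqr, params.k, dbs)
        chosen, rule, repl = resolve_residual_lqr(
            lqr, kmer_set, contig_seq, dbs, reads=survivors,
            min_support=params.min_confirm_depth,
        )
        if rule != RULE_REFERENCE and repl is not None:
            if not _splice_is_supported(
                emissions, repl, contig_seq, db, params.k
            ):
                # the spliced window would create junction K-mers absent
                # from both the short reads and the draft: overcorrection
                # risk, keep the reference instead
                rule, repl = RULE_REFERENCE, None
                chosen = contig_seq[lqr.start : lqr.start + params.k]
        if rule == RULE_REFERENCE:
            for c in range(lqr.start, min(lqr.end, len(contig_seq))):
                emissions[c] = contig_seq[c]
        elif repl is not None:
            for c, allele in repl.items():
                if 0 <= c < len(emissions):
                    emissions[c] = allele
        report.residual_resolutions.append(ResidualResolution(lqr, rule, chosen))

    final_seq = "".join(emissions)
    report.edits = [
        (pos, contig_seq[pos], emissions[pos])
        for pos in range(len(contig_seq))
        if emissions[pos] != contig_seq[pos]
    ]
    return final_seq, report
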