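"""Short-read-validated read phasing over low-quality regions.

For every low-quality region (LQR) the phaser extracts, from each long read
that maps across the region, the K-mers spanning it; K-mers absent from the
short-read database are discarded as sequencing artifacts.  An LQR whose
surviving (valid) K-mer set still contains two or more distinct K-mers is
*heterozygous*: the disagreement is real sequence — two haplotypes or two
near-identical repeat copies — not noise.

Heterozygous LQRs induce a signed graph over reads: +1 per spanning K-mer two
reads share, -1 per position-equivalent valid K-mer on which they differ.
Louvain community detection on the positive-weight subgraph groups reads from
the same haplotype or repeat copy; community pairs whose total inter-community
weight is negative are *conflicts* — reads from the same locus but different
haplotype/copy.  For each conflict the phaser keeps, by default, the community
sharing the most K-mers with the reference (preserving the draft's haplotype)
or, optionally, the largest community, and discards the other side's reads.
The whole procedure repeats on the surviving reads until no conflict remains
or the iteration cap is reached.

Position equivalence is defined by anchoring: each K-mer is keyed by the
reference column of its first base, so K-mers from reads with different
indels remain comparable.  The heterozygosity test uses a single canonical
anchor (the spanning K-mer with the LQR closest to its centre); the weight
calculation uses every anchor whose K-mer covers the whole region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx
from networkx.algorithms.community import louvain_communities as _nx_louvain

from .alignment_io import AlignedRead, Pileup, build_pileup
from .kmer_db import KmerDB, db_for_k
from .ksc import LQR, detect_lqps, ksc_consensus, merge_lqrs

logger = logging.getLogger(__name__)


@dataclass
class LqrKmerSet:
    """Valid K-mers spanning one LQR, per read and pooled.

    ``all_valid`` maps each distinct valid K-mer observed at the canonical
    spanning anchor to its short-read database count; ``is_het`` is true when
    it holds at least two K-mers.  ``anchor_kmers[read_id]`` maps every
    spanning anchor column to that read's valid K-mer there (the weight
    substrate); ``per_read`` is the flattened per-read K-mer set.
    """

    lqr: LQR
    per_read: dict[str, set[str]] = field(default_factory=dict)
    all_valid: dict[str, int] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)  # spanning reads per K-mer
    is_het: bool = False
    canonical_anchor: int = -1
    anchor_kmers: dict[str, dict[int, str]] = field(default_factory=dict)
    spanning_reads: list[str] = field(default_factory=list)
    # reference span of each canonical-anchor K-mer, with read support.
    # Reads carrying the same K-mer string can align it over different
    # column ranges (an indel inside a homopolymer shifts the window), so
    # the span is part of the candidate: kmer -> {(first_col, last_col): n}
    spans: dict[str, dict[tuple[int, int], int]] = field(
        default_factory=dict, repr=False
    )


@dataclass
class ReadGraph:
    """Reads as nodes with signed weights from shared/conflicting K-mers."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    communities: dict[str, int] = field(default_factory=dict)
    community_pairs: dict[tuple[int, int], float] = field(default_factory=dict)
    read_kmers: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def weight(self, r1: str, r2: str) -> float:
        key = (r1, r2) if r1 <= r2 else (r2, r1)
        return self.edges.get(key, 0.0)

    def add_weight(self, r1: str, r2: str, w: float) -> None:
        key = (r1, r2) if r1 <= r2 else (r2, r1)
        self.edges[key] = self.edges.get(key, 0.0) + w

    def members(self, label: int) -> list[str]:
        return sorted(r for r, c in self.communities.items() if c == label)

    def conflict_pairs(self) -> list[tuple[int, int]]:
        """Community pairs with negative total inter-community weight."""
        return [pair for pair, w in self.community_pairs.items() if w < 0]


def _read_window_sequence(
    read: AlignedRead, wstart: int, wend: int
) -> tuple[str, list[int], list[bool]]:
    """Read bases over reference window [wstart, wend).

    Returns the concatenated read sequence, the source reference column of
    each base, and whether the base is the first base emitted at its column
    (K-mers are anchored only at first bases so insertions do not create
    spurious anchors).
    """
    chars: list[str] = []
    cols: list[int] = []
    first: list[bool] = []
    for c in range(wstart, wend):
        allele = read.alleles.get(c)
        if allele is None or allele == "-":
            continue
        for i, ch in enumerate(allele):
            chars.append(ch)
            cols.append(c)
            first.append(i == 0)
    return "".join(chars), cols, first


def extract_lqr_kmers(
    reads: Iterable[AlignedRead],
    lqr: LQR,
    k: int,
    dbs: list[KmerDB] | KmerDB,
) -> LqrKmerSet:
    """Collect valid K-mers from reads mapping across an LQR.

    Only reads whose alignment fully spans the padded window
    ``[lqr.start - (k-1), lqr.end + (k-1))`` (clipped to the contig)
    contribute.  An LQR spanned by no read yields an empty set, left for the
    residual-resolution stage.
    """
    db = db_for_k(dbs, k)
    wstart = max(0, lqr.start - (k - 1))
    wend = lqr.end + (k - 1)
    result = LqrKmerSet(lqr=lqr)
    span_len = len(lqr)
    if span_len <= k:
        # anchors at which a K-mer covers the whole LQR
        anchor_lo = max(wstart, lqr.end - k)
        anchor_hi = lqr.start  # inclusive
        result.canonical_anchor = max(anchor_lo, (lqr.end - k + lqr.start) // 2)
    else:
        # region longer than a K-mer: no single K-mer spans it; anchor K-mers
        # overlapping the region, with the canonical anchor at its start
        anchor_lo = wstart
        anchor_hi = lqr.end - 1
        result.canonical_anchor = lqr.start

    for read in sorted(reads, key=lambda r: r.read_id):
        if not read.covers(wstart, wend):
            continue
        seq, cols, first = _read_window_sequence(read, wstart, wend)
        result.spanning_reads.append(read.read_id)
        if len(seq) < k:
            continue
        anchors: dict[int, str] = {}
        kmers: set[str] = set()
        for i in range(len(seq) - k + 1):
            if not first[i]:
                continue
            anchor = cols[i]
            if anchor < anchor_lo or anchor > anchor_hi:
                continue
            if span_len <= k and cols[i + k - 1] < lqr.end - 1:
                continue  # does not reach the far edge of the LQR
            kmer = seq[i : i + k]
            if not db.is_valid(kmer):
                continue
            anchors[anchor] = kmer
            kmers.add(kmer)
            if anchor == result.canonical_anchor:
                result.support[kmer] = result.support.get(kmer, 0) + 1
                if kmer not in result.all_valid:
                    result.all_valid[kmer] = db.get(kmer)
                span = (cols[i], cols[i + k - 1])
                spans = result.spans.setdefault(kmer, {})
                spans[span] = spans.get(span, 0) + 1
        if anchors:
            result.anchor_kmers[read.read_id] = anchors
            result.per_read[read.read_id] = kmers
    result.is_het = len(result.all_valid) >= 2
    return result


def reference_window_kmers(ref_seq: str, lqr: LQR, k: int) -> set[str]:
    """K-mers of the draft/reference over the LQR's padded window."""
    wstart = max(0, lqr.start - (k - 1))
    wend = min(len(ref_seq), lqr.end + (k - 1))
    window = ref_seq[wstart:wend]
    return {window[i : i + k] for i in range(len(window) - k + 1)}


def compute_read_weights(kmer_sets: list[LqrKmerSet]) -> ReadGraph:
    """Accumulate signed pairwise weights over all heterozygous K-mer sets.

    For each heterozygous LQR and each pair of reads spanning it, the edge
    weight gains +1 per anchor at which both reads carry the same valid
    K-mer and -1 per anchor at which both carry a valid K-mer but disagree.
    Non-heterozygous sets contribute nothing.
    """
    graph = ReadGraph()
    for ks in kmer_sets:
        if not ks.is_het:
            continue
        graph.nodes.update(ks.spanning_reads)
        for rid, kmers in ks.per_read.items():
            graph.read_kmers.setdefault(rid, set()).update(kmers)
        # per anchor, group reads by their K-mer
        anchor_groups: dict[int, dict[str, list[str]]] = {}
        for rid, anchors in ks.anchor_kmers.items():
            for anchor, kmer in anchors.items():
                anchor_groups.setdefault(anchor, {}).setdefault(kmer, []).append(rid)
        for groups in anchor_groups.values():
            kmer_list = sorted(groups)
            for kmer in kmer_list:
                for r1, r2 in combinations(sorted(groups[kmer]), 2):
                    graph.add_weight(r1, r2, +1.0)
            for k1, k2 in combinations(kmer_list, 2):
                for r1 in groups[k1]:
                    for r2 in groups[k2]:
                        graph.add_weight(r1, r2, -1.0)
    return graph


def louvain_communities(graph: ReadGraph, seed: int = 0) -> ReadGraph:
    """Label communities by Louvain modularity on the positive subgraph.

    Modularity is undefined for negative weights, so only positive edges
    drive the grouping; the signed weights then define the inter-community
    totals, and a pair with negative total weight is a conflict.  Reads with
    no positive edge become singleton communities.  Labels are assigned in
    order of each community's smallest read id, making the output
    deterministic for a fixed seed.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    for (r1, r2), w in sorted(graph.edges.items()):
        if w > 0:
            g.add_edge(r1, r2, weight=w)
    if g.number_of_nodes() == 0:
        graph.communities = {}
        graph.community_pairs = {}
        return graph
    comms = _nx_louvain(g, weight="weight", resolution=1.0, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels: dict[str, int] = {}
    for idx, members in enumerate(comms):
        for rid in members:
            labels[rid] = idx
    graph.communities = labels
    pairs: dict[tuple[int, int], float] = {}
    for (r1, r2), w in graph.edges.items():
        c1, c2 = labels[r1], labels[r2]
        if c1 == c2:
            continue
        key = (c1, c2) if c1 < c2 else (c2, c1)
        pairs[key] = pairs.get(key, 0.0) + w
    graph.community_pairs = pairs
    return graph


def community_sides(graph: ReadGraph) -> dict[str, int]:
    """Coarsen communities into conflict *sides*.

    Louvain segments each haplotype's chain of overlapping reads along the
    contig into several communities; same-haplotype segments attract each
    other (positive inter-community weight) and are never conflicts.  For
    haplotype-recovery checks the meaningful partition is therefore the
    transitive closure of positive inter-community weight: communities so
    linked form one side, and only cross-side (negative) pairs are real
    haplotype/repeat-copy boundaries.  Returns read id -> side label.
    """
    labels = sorted(set(graph.communities.values()))
    parent = {lab: lab for lab in labels}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (c1, c2), w in sorted(graph.community_pairs.items()):
        if w > 0:
            r1, r2 = find(c1), find(c2)
            if r1 != r2:
                parent[max(r1, r2)] = min(r1, r2)
    return {rid: find(lab) for rid, lab in graph.communities.items()}


def resolve_conflicts(
    graph: ReadGraph,
    ref_kmers: set[str],
    mode: str = "reference",
) -> set[str]:
    """Decide which reads to discard for every conflicting community pair.

    Pairs are processed most-negative first.  In mode ``"reference"`` the
    community whose reads share the most K-mers with the reference wins
    (each shared K-mer counted once per read, so deeper communities are not
    penalised); in mode ``"largest"`` the community with more reads wins.
    Exact ties keep the community containing the lexicographically smallest
    read id.  All reads of each losing community are discarded.
    """
    if mode not in ("reference", "largest"):
        raise ValueError(f"unknown conflict mode {mode!r}")
    conflicts = sorted(
        ((w, pair) for pair, w in graph.community_pairs.items() if w < 0),
        key=lambda t: (t[0], t[1]),
    )
    discarded_comms: set[int] = set()
    discard_reads: set[str] = set()
    for _w, (c1, c2) in conflicts:
        if c1 in discarded_comms or c2 in discarded_comms:
            continue
        m1, m2 = graph.members(c1), graph.members(c2)
        if mode == "reference":
            s1 = sum(len(graph.read_kmers.get(r, set()) & ref_kmers) for r in m1)
            s2 = sum(len(graph.read_kmers.get(r, set()) & ref_kmers) for r in m2)
        else:
            s1, s2 = len(m1), len(m2)
        if s1 > s2:
            loser = c2
        elif s2 > s1:
            loser = c1
        else:  # tie: keep the community with the smallest read id
            loser = c2 if min(m1) < min(m2) else c1
        discarded_comms.add(loser)
        discard_reads.update(graph.members(loser))
    return discard_reads


@dataclass
class IterationRecord:
    """Bookkeeping for one phasing iteration."""

    iteration: int
    n_lqrs: int
    n_het_lqrs: int
    n_conflicts: int
    community_sizes: list[int]
    discarded: list[str]


@dataclass
class PhasingParams:
    """Tunable parameters of the phasing loop."""

    k: int = 21  # validation K-mer length; must match a database
    chain_k: int = 3  # chain-mer length of the KSC consensus
    lqp_threshold: float = 0.95  # inclusive low-quality support threshold
    merge_gap: int = 21  # LQPs closer than this merge into one LQR
    mode: str = "reference"  # conflict resolution: "reference" | "largest"
    max_iters: int = 5
    min_confirm_depth: int = 3  # below this depth the draft base is kept
    seed: int = 0


def iterate_phasing(
    contig_seq: str,
    reads: list[AlignedRead],
    dbs: list[KmerDB] | KmerDB,
    params: PhasingParams | None = None,
) -> tuple[list[AlignedRead], list[IterationRecord], bool]:
    """Run {KSC -> LQRs -> K-mer sets -> graph -> Louvain -> resolve} to a
    fixed point.

    Returns the surviving reads, the per-iteration log, and whether the loop
    converged (no conflict pair left).  Hitting ``max_iters`` with conflicts
    remaining logs a warning and returns ``converged = False``.
    """
    params = params or PhasingParams()
    if params.max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    current = list(reads)
    log: list[IterationRecord] = []
    converged = False
    for it in range(1, params.max_iters + 1):
        pileup = build_pileup(contig_seq, current)
        _, trace = ksc_consensus(pileup, chain_k=params.chain_k)
        lqps = detect_lqps(trace, threshold=params.lqp_threshold)
        lqrs = merge_lqrs(
            lqps, merge_gap=params.merge_gap, contig_len=len(contig_seq), pad=0
        )
        kmer_sets = [
            extract_lqr_kmers(current, lqr, params.k, dbs) for lqr in lqrs
        ]
        het_sets = [ks for ks in kmer_sets if ks.is_het]
        if not het_sets:
            log.append(IterationRecord(it, len(lqrs), 0, 0, [], []))
            converged = True
            break
        graph = compute_read_weights(het_sets)
        graph = louvain_communities(graph, seed=params.seed + it)
        conflicts = graph.conflict_pairs()
        sizes = sorted(
            (sum(1 for c in graph.communities.values() if c == lab)
             for lab in set(graph.communities.values())),
            reverse=True,
        )
        if not conflicts:
            log.append(IterationRecord(it, len(lqrs), len(het_sets), 0, sizes, []))
            converged = True
            break
        ref_kmers: set[str] = set()
        for ks in het_sets:
            ref_kmers |= reference_window_kmers(contig_seq, ks.lqr, params.k)
        discard = resolve_conflicts(graph, ref_kmers, mode=params.mode)
        log.append(
            IterationRecord(
                it, len(lqrs), len(het_sets), len(conflicts), sizes, sorted(discard)
            )
        )
        if not discard:
            converged = True
            break
        current = [r for r in current if r.read_id not in discard]
    else:
        logger.warning(
            "phasing stopped after %d iterations with conflicts unresolved",
            params.max_iters,
        )
    return current, log, converged
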