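"""K-mer score chain (KSC) consensus with low-quality-region detection.

The consensus is a dynamic program over pileup columns.  A node is a
(position, allele) pair; the score of allele *a* at column *P* is the best
predecessor score plus the number of reads carrying the *chain-mer* — the
tuple of the last ``chain_k`` alleles ending in *a* — minus the column's
valid depth.  With the default ``chain_k = 3`` and candidate predecessors
{C, -} at P-1, the chain-mers feeding allele C at P are CCC, -CC and --C.
Subtracting the valid depth makes the score of a fully supported path zero
and every disagreement strictly negative, so the traceback follows the
read-consistent path rather than a column-wise patchwork.

Positions on the traceback whose chosen allele is supported by at most 95%
of the covering reads (the default threshold, inclusive) are *low-quality
positions* (LQPs); adjacent LQPs are merged into *low-quality regions*
(LQRs), the unit the phasing and residual-resolution stages operate on.

Because a chain-mer of length g couples only g consecutive columns, the DP
state is the tuple of the last ``chain_k - 1`` alleles; the number of states
per column is the product of the (few) observed alleles, so the pass is
linear in contig length in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment_io import Pileup

@dataclass
class ChainNode:
    """One column of the traceback path."""

    position: int
    allele: str
    score: float
    best_pred: Optional["ChainNode"] = field(default=None, repr=False)
    support_fraction: float = 0.0


@dataclass
class LQR:
    """A half-open interval of merged low-quality positions on a contig."""

    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.positions:
            assert self.start <= min(self.positions) and self.end > max(self.positions)

    def __len__(self) -> int:
        return self.end - self.start


def _allele_rank(allele: str, ref_base: str) -> tuple[int, str]:
    """Deterministic preference key: reference-matching allele first, then
    lexicographic.  Used to break exact score ties, keeping the consensus
    conservative toward the input assembly."""
    return (0 if allele == ref_base else 1, allele)


def ksc_consensus(
    pileup: Pileup, chain_k: int = 3
) -> tuple[str, list[ChainNode]]:
    """Run the K-mer score chain over a pileup.

    Returns the consensus sequence and the per-column traceback.  Deletion
    alleles contribute no base; insertion alleles contribute their full
    string; zero-coverage columns emit the reference base (and are flagged as
    LQPs via ``support_fraction = 0``).

    Raises ``ValueError`` for an empty pileup or ``chain_k < 2``.
    """
    if chain_k < 2:
        raise ValueError(f"chain_k must be >= 2, got {chain_k}")
    n = len(pileup.ref_seq)
    if n == 0:
        raise ValueError("empty pileup")
    columns = pileup.columns
    depth = pileup.valid_depth

    chosen: list[str | None] = [None] * n  # traceback allele per covered column
    scores = np.zeros(n, dtype=float)

    # DP runs independently over maximal covered segments; zero-coverage
    # columns break the chain and emit the reference base.
    p = 0
    while p < n:
        if depth[p] == 0:
            p += 1
            continue
        seg_start = p
        while p < n and depth[p] > 0:
            p += 1
        seg_end = p
        _run_segment(pileup, seg_start, seg_end, chain_k, chosen, scores)

    trace: list[ChainNode] = []
    consensus_parts: list[str] = []
    prev_node: Optional[ChainNode] = None
    for pos in range(n):
        ref_base = pileup.ref_seq[pos]
        if depth[pos] == 0:
            node = ChainNode(pos, ref_base, 0.0, None, 0.0)
            consensus_parts.append(ref_base)
            prev_node = None
        else:
            allele = chosen[pos]
            assert allele is not None
            support = len(columns[pos][allele]) / int(depth[pos])
            node = ChainNode(pos, allele, float(scores[pos]), prev_node, support)
            if allele != "-":
                consensus_parts.append(allele)
            prev_node = node
        trace.append(node)
    return "".join(consensus_parts), trace


def _run_segment(
    pileup: Pileup,
    seg_start: int,
    seg_end: int,
    chain_k: int,
    chosen: list[str | None],
    scores: np.ndarray,
) -> None:
    """Viterbi over one covered segment; writes chosen alleles and scores."""
    columns = pileup.columns
    depth = pileup.valid_depth
    ref = pileup.ref_seq
    hist = chain_k - 1

    # state: tuple of the last min(hist, seen) alleles; value: (score, backref)
    # backref: (prev_state, prev_backpointers_index) chain reconstructed at end
    first_col = columns[seg_start]
    states: dict[tuple[str, ...], float] = {}
    backptrs: list[dict[tuple[str, ...], tuple[str, ...] | None]] = []
    bp0: dict[tuple[str, ...], tuple[str, ...] | None] = {}
    d0 = int(depth[seg_start])
    for allele, supporters in first_col.items():
        st = (allele,)
        states[st] = len(supporters) - d0
        bp0[st] = None
    backptrs.append(bp0)

    for pos in range(seg_start + 1, seg_end):
        col = columns[pos]
        dp = int(depth[pos])
        new_states: dict[tuple[str, ...], float] = {}
        bp: dict[tuple[str, ...], tuple[str, ...] | None] = {}
        ref_base = ref[pos]
        # alleles sorted by preference so that on exact ties the first
        # (reference-matching, then lexicographically smallest) wins
        for allele in sorted(col, key=lambda a: _allele_rank(a, ref_base)):
            supp_a = col[allele]
            for prev_state, prev_score in states.items():
                chain = (prev_state + (allele,))[-chain_k:]
                # count reads carrying the whole chain over its columns
                members = supp_a
                ok = True
                for back, ch_allele in enumerate(reversed(chain[:-1]), start=1):
                    cset = columns[pos - back].get(ch_allele)
                    if cset is None:
                        ok = False
                        break
                    members = members & cset
                    if not members:
                        ok = False
                        break
                cnt = len(members) if ok else 0
                cand = prev_score + cnt - dp
                new_state = (prev_state + (allele,))[-hist:]
                if new_state not in new_states or cand > new_states[new_state]:
                    new_states[new_state] = cand
                    bp[new_state] = prev_state
        states = new_states
        backptrs.append(bp)

    # pick the best final state (ties: preference order of its final allele)
    ref_last = ref[seg_end - 1]
    best_state = min(
        states,
        key=lambda st: (-states[st], _allele_rank(st[-1], ref_last)),
    )
    # reconstruct the allele path and per-column running scores
    path_states: list[tuple[str, ...]] = [best_state]
    st: tuple[str, ...] | None = best_state
    for bp in reversed(backptrs[1:]):
        st = bp[st]
        assert st is not None
        path_states.append(st)
    path_states.reverse()
    for i, pos in enumerate(range(seg_start, seg_end)):
        chosen[pos] = path_states[i][-1]
    # recompute per-position scores along the chosen path for the trace
    path_alleles = [st[-1] for st in path_states]
    d0 = int(depth[seg_start])
    score = len(columns[seg_start][path_alleles[0]]) - d0
    scores[seg_start] = score
    for i, pos in enumerate(range(seg_start + 1, seg_end), start=1):
        chain = tuple(path_alleles[max(0, i - chain_k + 1) : i + 1])
        members = columns[pos][chain[-1]]
        for back, ch_allele in enumerate(reversed(chain[:-1]), start=1):
            cset = columns[pos - back].get(ch_allele)
            if cset is None:
                members = set()
                break
            members = members & cset
            if not members:
                break
        score += len(members) - int(depth[pos])
        scores[pos] = score


def detect_lqps(trace: list[ChainNode], threshold: float = 0.95) -> list[int]:
    """Positions whose chosen allele accounts for <= ``threshold`` of reads.

    The rule is inclusive: a support fraction exactly at the threshold is
    low-quality.  Zero-coverage columns carry support 0 and are always LQPs.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [node.position for node in trace if node.support_fraction <= threshold]


def merge_lqrs(
    positions: list[int],
    merge_gap: int = 21,
    contig_len: int = 0,
    pad: int = 0,
    contig: str = "",
) -> list[LQR]:
    """Merge sorted low-quality positions into low-quality regions.

    Consecutive positions closer than ``merge_gap`` fall into one region;
    each region is padded by ``pad`` bases on both sides and clipped to
    ``[0, contig_len)`` (no clipping when ``contig_len`` is 0).
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    if not positions:
        return []
    lqrs: list[LQR] = []
    group: list[int] = [positions[0]]
    for pos in positions[1:]:
        if pos - group[-1] < merge_gap:
            group.append(pos)
        else:
            lqrs.append(_make_lqr(group, pad, contig_len, contig))
            group = [pos]
    lqrs.append(_make_lqr(group, pad, contig_len, contig))
    return lqrs


def _make_lqr(group: list[int], pad: int, contig_len: int, contig: str) -> LQR:
    start = max(0, group[0] - pad)
    end = group[-1] + 1 + pad
    if contig_len:
        end = min(contig_len, end)
    return LQR(contig=contig, start=start, end=end, positions=list(group))
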