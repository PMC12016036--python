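"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hifipolish.alignment_io import AlignedRead, Pileup, build_pileup


def mk_read(
    rid: str,
    start: int,
    alleles: dict[int, str],
    contig: str = "c",
    mapq: int = 60,
) -> AlignedRead:
    """Construct an AlignedRead directly from a column->allele map."""
    end = max(alleles) + 1 if alleles else start
    seq = "".join(a for _p, a in sorted(alleles.items()) if a != "-")
    return AlignedRead(rid, contig, start, end, mapq, dict(alleles), seq)


def pileup_from_strings(
    ref: str, rows: list[str]
) -> tuple[Pileup, list[AlignedRead]]:
    """Pileup from full-length read strings over ``ref``.

    ``'-'`` denotes a deletion; lowercase letters after a base are folded in
    as an insertion attached to that base (e.g. ``"Ag"`` emits allele "AG").
    """
    reads = []
    for i, row in enumerate(rows):
        assert len(row) == len(ref)
        alleles = {p: ch.upper() for p, ch in enumerate(row)}
        reads.append(mk_read(f"r{i:03d}", 0, alleles))
    return build_pileup(ref, reads), reads


def majority_consensus(pileup: Pileup) -> str:
    """Independent column-wise majority-vote oracle.

    Ties prefer the reference base, then the lexicographically smallest
    allele — the same deterministic preference the chain consensus uses, so
    the two are comparable wherever the majority is well defined.
    """
    out = []
    for p, col in enumerate(pileup.columns):
        ref_base = pileup.ref_seq[p]
        if not col:
            out.append(ref_base)
            continue
        allele = max(
            sorted(col),
            key=lambda a: (
                len(col[a]),
                a == ref_base,
                tuple(-ord(c) for c in a),
            ),
        )
        if allele != "-":
            out.append(allele)
    return "".join(out)


def random_unlinked_pileup(
    rng: np.random.Generator,
    length: int = 200,
    n_reads: int = 20,
    error_rate: float = 0.15,
) -> Pileup:
    """Pileup with independent per-column errors in <= ``error_rate`` of reads.

    Errors at different columns hit independently chosen reads, so there is
    no linkage between columns and the chain consensus should reduce to the
    column-wise majority vote.
    """
    bases = "ACGT"
    ref = "".join(rng.choice(list(bases), size=length))
    rows = [list(ref) for _ in range(n_reads)]
    for p in range(length):
        n_err = rng.binomial(n_reads, error_rate)
        n_err = min(n_err, int(n_reads * 0.2))
        victims = rng.choice(n_reads, size=n_err, replace=False)
        for v in victims:
            choices = [b for b in bases if b != ref[p]] + ["-"]
            rows[int(v)][p] = choices[int(rng.integers(0, len(choices)))]
    pileup, _ = pileup_from_strings(ref, ["".join(r) for r in rows])
    return pileup


def rand_index(labels_a: list, labels_b: list) -> float:
    """Plain Rand index between two labelings of the same items."""
    n = len(labels_a)
    assert n == len(labels_b)
    if n < 2:
        return 1.0
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            agree += same_a == same_b
            total += 1
    return agree / total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
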