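"""K-mer extraction at LQRs, signed read graph, Louvain, conflict resolution."""

import pytest

from hifipolish.kmer_db import build_kmer_db
from hifipolish.ksc import LQR
from hifipolish.phasing import (
    PhasingParams,
    ReadGraph,
    compute_read_weights,
    extract_lqr_kmers,
    iterate_phasing,
    louvain_communities,
    resolve_conflicts,
)
from tests.conftest import mk_read

K = 5  # small validation K so fixtures stay readable


def _full_read(rid: str, seq: str) -> "AlignedRead":
    return mk_read(rid, 0, {p: ch for p, ch in enumerate(seq)})


def _db_from(*seqs: str):
    return build_kmer_db(list(seqs), k=K, min_count=1)


# two 20-bp haplotypes differing at one site (position 9: A vs G)
HAP_A = "ACGTACGTACGTTACGGTCA"
HAP_B = HAP_A[:9] + "G" + HAP_A[10:]
SITE_LQR = LQR("c", 9, 10, [9])


def test_spanning_read_contributes_window_kmers():
    db = _db_from(HAP_A)
    reads = [_full_read("r1", HAP_A)]
    ks = extract_lqr_kmers(reads, SITE_LQR, K, db)
    assert ks.spanning_reads == ["r1"]
    assert "r1" in ks.per_read
    # every contributed K-mer covers the low-quality site
    assert all(HAP_A[9] in km or km in HAP_A for km in ks.per_read["r1"])
    assert len(ks.all_valid) == 1
    assert ks.is_het is False


def test_read_ending_inside_lqr_window_is_excluded():
    db = _db_from(HAP_A)
    short = mk_read("stub", 0, {p: HAP_A[p] for p in range(10)})  # ends at 10
    ks = extract_lqr_kmers([short], SITE_LQR, K, db)
    assert ks.spanning_reads == []
    assert ks.all_valid == {}


def test_two_haplotype_alleles_make_set_heterozygous():
    """Both variants present in short reads -> >= 2 valid K-mers -> het."""
    db = _db_from(HAP_A, HAP_B)
    reads = [_full_read("a1", HAP_A), _full_read("b1", HAP_B)]
    ks = extract_lqr_kmers(reads, SITE_LQR, K, db)
    assert len(ks.all_valid) == 2
    assert ks.is_het is True


def test_invalid_kmers_are_filtered_out():
    """A sequencing-error K-mer absent from short reads never reaches the set."""
    db = _db_from(HAP_A)  # only haplotype A is short-read supported
    err = HAP_A[:9] + "T" + HAP_A[10:]
    reads = [_full_read("a1", HAP_A), _full_read("e1", err)]
    ks = extract_lqr_kmers(reads, SITE_LQR, K, db)
    assert "e1" not in ks.per_read  # all its site K-mers are invalid
    assert ks.is_het is False


def test_weights_positive_for_identical_negative_for_disjoint():
    db = _db_from(HAP_A, HAP_B)
    reads = [
        _full_read("a1", HAP_A),
        _full_read("a2", HAP_A),
        _full_read("b1", HAP_B),
    ]
    ks = extract_lqr_kmers(reads, SITE_LQR, K, db)
    graph = compute_read_weights([ks])
    n_anchors = len(ks.anchor_kmers["a1"])
    assert n_anchors >= 2
    assert graph.weight("a1", "a2") == n_anchors  # +1 per shared anchor K-mer
    assert graph.weight("a1", "b1") == -n_anchors  # -1 per differing anchor
    # symmetry invariant
    assert graph.weight("b1", "a1") == graph.weight("a1", "b1")


def test_non_het_sets_contribute_nothing():
    db = _db_from(HAP_A)
    reads = [_full_read("a1", HAP_A), _full_read("a2", HAP_A)]
    ks = extract_lqr_kmers(reads, SITE_LQR, K, db)
    assert not ks.is_het
    graph = compute_read_weights([ks])
    assert graph.edges == {}


def _planted_graph(n_per_group: int = 6) -> ReadGraph:
    """Two internally positive, mutually negative read groups."""
    g = ReadGraph()
    a = [f"a{i}" for i in range(n_per_group)]
    b = [f"b{i}" for i in range(n_per_group)]
    g.nodes.update(a + b)
    for grp in (a, b):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                g.add_weight(grp[i], grp[j], +3.0)
    for r1 in a:
        for r2 in b:
            g.add_weight(r1, r2, -3.0)
    return g


def test_louvain_recovers_planted_partition_with_conflict():
    g = louvain_communities(_planted_graph(), seed=11)
    labels = {g.communities[r] for r in g.nodes}
    assert len(labels) == 2
    # the two groups are pure
    assert len({g.communities[f"a{i}"] for i in range(6)}) == 1
    assert len({g.communities[f"b{i}"] for i in range(6)}) == 1
    ((pair, w),) = list(g.community_pairs.items())
    assert w < 0
    assert g.conflict_pairs() == [pair]


def test_fully_consistent_reads_form_one_community():
    g = ReadGraph()
    reads = [f"r{i}" for i in range(5)]
    g.nodes.update(reads)
    for i in range(5):
        for j in range(i + 1, 5):
            g.add_weight(reads[i], reads[j], 2.0)
    g = louvain_communities(g, seed=1)
    assert len(set(g.communities.values())) == 1
    assert g.conflict_pairs() == []


def test_community_pair_weights_equal_edge_sums():
    g = louvain_communities(_planted_graph(4), seed=3)
    for (c1, c2), w in g.community_pairs.items():
        m1, m2 = set(g.members(c1)), set(g.members(c2))
        total = sum(
            wt for (r1, r2), wt in g.edges.items()
            if (r1 in m1 and r2 in m2) or (r1 in m2 and r2 in m1)
        )
        assert w == pytest.approx(total)


def test_resolve_conflicts_reference_mode():
    g = louvain_communities(_planted_graph(), seed=11)
    g.read_kmers = {f"a{i}": {"AAAAA", "CCCCC"} for i in range(6)}
    g.read_kmers.update({f"b{i}": {"GGGGG"} for i in range(6)})
    discard = resolve_conflicts(g, ref_kmers={"AAAAA", "CCCCC"}, mode="reference")
    assert discard == {f"b{i}" for i in range(6)}


def test_resolve_conflicts_largest_mode():
    g = ReadGraph()
    a = [f"a{i}" for i in range(8)]
    b = [f"b{i}" for i in range(3)]
    g.nodes.update(a + b)
    for grp in (a, b):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                g.add_weight(grp[i], grp[j], 1.0)
    for r1 in a:
        for r2 in b:
            g.add_weight(r1, r2, -1.0)
    g = louvain_communities(g, seed=5)
    discard = resolve_conflicts(g, ref_kmers=set(), mode="largest")
    assert discard == set(b)


def test_resolve_conflicts_tie_keeps_smallest_read_id():
    g = louvain_communities(_planted_graph(3), seed=2)
    g.read_kmers = {}
    discard = resolve_conflicts(g, ref_kmers=set(), mode="reference")
    # tie on reference sharing (0 == 0): community containing "a0" survives
    assert discard == {"b0", "b1", "b2"}


def test_resolve_conflicts_rejects_unknown_mode():
    with pytest.raises(ValueError):
        resolve_conflicts(ReadGraph(), set(), mode="biggest")


def test_iterate_phasing_homozygous_terminates_clean():
    db = _db_from(HAP_A)
    reads = [_full_read(f"r{i}", HAP_A) for i in range(6)]
    survivors, log, converged = iterate_phasing(
        HAP_A, reads, db, PhasingParams(k=K, merge_gap=K, seed=1)
    )
    assert converged
    assert len(survivors) == 6
    assert len(log) == 1 and log[0].discarded == []


def test_iterate_phasing_discards_non_reference_haplotype():
    db = _db_from(HAP_A, HAP_B)
    reads = [_full_read(f"a{i}", HAP_A) for i in range(6)]
    reads += [_full_read(f"b{i}", HAP_B) for i in range(6)]
    survivors, log, converged = iterate_phasing(
        HAP_A, reads, db, PhasingParams(k=K, merge_gap=K, seed=1)
    )
    assert converged
    assert {r.read_id for r in survivors} == {f"a{i}" for i in range(6)}


def test_iterate_phasing_max_iters_reports_unconverged():
    db = _db_from(HAP_A, HAP_B)
    reads = [_full_read(f"a{i}", HAP_A) for i in range(6)]
    reads += [_full_read(f"b{i}", HAP_B) for i in range(6)]
    params = PhasingParams(k=K, merge_gap=K, seed=1, max_iters=1)
    survivors, log, converged = iterate_phasing(HAP_A, reads, db, params)
    # one iteration discards the conflicting community but cannot confirm
    # convergence afterwards
    assert len(log) == 1
    assert len(survivors) == 6


def test_discarding_reads_never_adds_alleles():
    """Monotone safety: the allele set of every column only shrinks."""
    from hifipolish.alignment_io import build_pileup

    db = _db_from(HAP_A, HAP_B)
    reads = [_full_read(f"a{i}", HAP_A) for i in range(6)]
    reads += [_full_read(f"b{i}", HAP_B) for i in range(6)]
    before = build_pileup(HAP_A, reads)
    survivors, _, _ = iterate_phasing(
        HAP_A, reads, db, PhasingParams(k=K, merge_gap=K, seed=1)
    )
    after = build_pileup(HAP_A, survivors)
    for p in range(len(HAP_A)):
        assert set(after.columns[p]) <= set(before.columns[p])
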