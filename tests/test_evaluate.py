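"""Assessment metrics: K-mer changes, overcorrection, QV, switch error."""

import math

import numpy as np
import pytest

from hifipolish.evaluate import (
    PafRecord,
    alignment_qv,
    changed_kmers,
    kmer_qv,
    overcorrection_kmers,
    read_paf,
    switch_error,
)
from hifipolish.kmer_db import build_kmer_db


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_changed_kmers_identical_sequences_zero(rng):
    seq = _random_seq(rng, 500)
    assert changed_kmers(seq, seq, k=21) == 0


def test_single_substitution_bounded_by_2k_minus_1(rng):
    """One substitution introduces at most 2k-1 new K-mers (41 at k=21)."""
    k = 21
    seq = _random_seq(rng, 2000)
    pos = 1000
    edited = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
    n = changed_kmers(edited, seq, k=k)
    assert 0 < n <= 2 * k - 1


def test_substitution_at_position_zero_bounded_by_k(rng):
    k = 21
    seq = _random_seq(rng, 1000)
    edited = ("A" if seq[0] != "A" else "C") + seq[1:]
    assert 0 < changed_kmers(edited, seq, k=k) <= k


def test_overcorrection_subset_of_changed(rng):
    """overcorrection_kmers <= changed_kmers for arbitrary edits."""
    k = 11
    seq = _random_seq(rng, 800)
    db = build_kmer_db([seq], k=k, min_count=1)
    for _ in range(5):
        pos = int(rng.integers(50, 750))
        edited = seq[:pos] + _random_seq(rng, 3) + seq[pos + 3 :]
        ch = changed_kmers(edited, seq, k=k)
        oc = overcorrection_kmers(edited, seq, db)
        assert oc <= ch


def test_read_supported_edit_has_zero_overcorrection(rng):
    k = 11
    truth = _random_seq(rng, 600)
    draft = truth[:300] + ("A" if truth[300] != "A" else "C") + truth[301:]
    db = build_kmer_db([truth], k=k, min_count=1)
    # correcting the draft back to truth only introduces short-read K-mers
    assert overcorrection_kmers(truth, draft, db) == 0
    assert changed_kmers(truth, draft, k=k) > 0


def test_random_edit_is_flagged_as_overcorrection(rng):
    k = 11
    truth = _random_seq(rng, 600)
    db = build_kmer_db([truth], k=k, min_count=1)
    bogus = truth[:300] + "ACGTACGTT" + truth[309:]
    assert overcorrection_kmers(bogus, truth, db) > 0


def _paf(nmatch, blocklen, qlen=None):
    qlen = qlen or blocklen
    return PafRecord("q", qlen, 0, blocklen, "+", "t", blocklen, 0,
                     blocklen, nmatch, blocklen, 60)


def test_alignment_qv_closed_forms():
    qv, kept = alignment_qv([_paf(9900, 10000)])
    assert qv == pytest.approx(20.0)
    qv, _ = alignment_qv([_paf(9990, 10000)])
    assert qv == pytest.approx(30.0)
    assert kept == 1


def test_alignment_qv_filters_are_inclusive():
    low_cov = _paf(9990, 9000, qlen=10000)  # coverage exactly 0.90
    low_id = _paf(9800, 10000)  # identity exactly 0.98
    good = _paf(9990, 10000)
    qv, kept = alignment_qv([low_cov, low_id, good])
    assert kept == 1
    assert qv == pytest.approx(30.0)


def test_alignment_qv_perfect_capped():
    qv, _ = alignment_qv([_paf(10000, 10000)])
    assert qv == 99.0


def test_alignment_qv_monotone_in_mismatch_fraction():
    qvs = [alignment_qv([_paf(m, 10000)])[0] for m in (9999, 9990, 9900)]
    assert qvs[0] > qvs[1] > qvs[2]


def test_paf_round_trip_and_malformed_line(tmp_path):
    path = tmp_path / "a.paf"
    path.write_text("q\t100\t0\t100\t+\tt\t100\t0\t100\t99\t100\t60\tcg:Z:100M\n")
    (rec,) = read_paf(path)
    assert rec.nmatch == 99 and rec.identity == pytest.approx(0.99)
    bad = tmp_path / "bad.paf"
    bad.write_text("q\t100\t0\n")
    with pytest.raises(ValueError, match="bad.paf:1"):
        read_paf(bad)


def test_kmer_qv_all_shared_capped(rng):
    seq = _random_seq(rng, 500)
    db = build_kmer_db([seq], k=15, min_count=1)
    assert kmer_qv(seq, db) == 99.0


def test_kmer_qv_half_shared_closed_form_k2():
    # assembly AACC vs db from AACG: 2-mers AA,AC,CC; db has AA,AC,CG
    # shared instances 2 of 3 -> E = 1 - (2/3)^(1/2)
    db = build_kmer_db(["AACG"], k=2, min_count=1)
    expected = -10 * math.log10(1 - (2 / 3) ** 0.5)
    assert kmer_qv("AACC", db) == pytest.approx(expected)


def test_kmer_qv_monotone_in_sharing(rng):
    seq = _random_seq(rng, 1000)
    db = build_kmer_db([seq], k=15, min_count=1)
    one_edit = seq[:500] + ("A" if seq[500] != "A" else "C") + seq[501:]
    many_edits = list(seq)
    for p in range(100, 900, 100):
        many_edits[p] = "A" if seq[p] != "A" else "C"
    many_edits = "".join(many_edits)
    assert kmer_qv(one_edit, db) > kmer_qv(many_edits, db)
    assert kmer_qv(seq, db) > kmer_qv(one_edit, db)


def test_kmer_qv_empty_assembly_raises():
    db = build_kmer_db(["ACGTACGT"], k=5, min_count=1)
    with pytest.raises(ValueError):
        kmer_qv("", db)


def _diploid_pair(rng, n=3000, n_sites=12):
    hap1 = _random_seq(rng, n)
    sites = sorted(rng.choice(np.arange(50, n - 50), size=n_sites, replace=False).tolist())
    hap2 = list(hap1)
    for p in sites:
        hap2[p] = "ACGT"[("ACGT".index(hap1[p]) + 1) % 4]
    return hap1, "".join(hap2), sites


def test_switch_error_pure_haplotype_is_zero(rng):
    hap1, hap2, _ = _diploid_pair(rng)
    res = switch_error(hap1, hap1, hap2, k=21)
    assert res.switches == 0
    assert res.rate == 0.0
    assert res.het_sites > 0


def test_switch_error_alternating_assignment_rate_one(rng):
    hap1, hap2, sites = _diploid_pair(rng)
    # mosaic: alternate haplotype blocks between consecutive het sites
    mosaic = list(hap1)
    for idx, p in enumerate(sites):
        if idx % 2 == 1:
            mosaic[p] = hap2[p]
    res = switch_error("".join(mosaic), hap1, hap2, k=21)
    assert res.het_sites == len(sites)
    assert res.rate == pytest.approx(1.0)
    assert res.switches == len(sites) - 1


def test_switch_error_matches_brute_force_assignment(rng):
    hap1, hap2, sites = _diploid_pair(rng, n_sites=9)
    pattern = [1, 1, 2, 2, 2, 1, 2, 1, 1]
    mosaic = list(hap1)
    for p, h in zip(sites, pattern):
        if h == 2:
            mosaic[p] = hap2[p]
    res = switch_error("".join(mosaic), hap1, hap2, k=21)
    expected = sum(1 for a, b in zip(pattern, pattern[1:]) if a != b)
    assert res.switches == expected
    assert res.rate == pytest.approx(expected / (len(pattern) - 1))


def test_switch_error_single_site_degenerate(rng):
    hap1 = _random_seq(rng, 200)
    hap2 = hap1[:100] + "ACGT"[("ACGT".index(hap1[100]) + 1) % 4] + hap1[101:]
    res = switch_error(hap1, hap1, hap2, k=21)
    assert res.degenerate is True
    assert res.rate == 0.0
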