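"""Synthetic diploid genomes, HiFi-like reads, truth alignments."""

import numpy as np
import pytest

from hifipolish.alignment_io import load_alignments
from hifipolish.simulate import (
    SimConfig,
    homopolymer_mask,
    perturb_assembly,
    simulate_diploid,
    simulate_reads,
    write_fastq,
    write_truth_sam,
)

CFG_SMALL = dict(genome_length=20_000, hifi_read_length=3000, n_repeat_copies=0)


def test_het_rate_zero_identical_haplotypes():
    g = simulate_diploid(SimConfig(**CFG_SMALL, het_rate=0.0, seed=1))
    assert g.hap1 == g.hap2
    assert g.variants == []


def test_het_count_within_binomial_three_sigma():
    L, rate = 100_000, 0.01
    g = simulate_diploid(
        SimConfig(genome_length=L, het_rate=rate, n_repeat_copies=0, seed=7)
    )
    mean = L * rate
    sigma = (L * rate * (1 - rate)) ** 0.5
    # site collisions are dropped, so allow the 3-sigma band around the mean
    assert mean - 3 * sigma <= len(g.variants) <= mean + 3 * sigma


def test_variants_reconstruct_hap2():
    g = simulate_diploid(SimConfig(**CFG_SMALL, het_rate=0.01, seed=3))
    rebuilt = list(g.hap1)
    for v in sorted(g.variants, key=lambda v: v.pos1, reverse=True):
        if v.kind == "sub":
            rebuilt[v.pos1] = v.alt
        elif v.kind == "ins":
            rebuilt[v.pos1] = g.hap1[v.pos1] + v.alt
        else:
            for j in range(len(v.ref)):
                rebuilt[v.pos1 + j] = ""
    assert "".join(rebuilt) == g.hap2


def test_repeat_copies_differ_only_at_diagnostics():
    cfg = SimConfig(
        genome_length=30_000, het_rate=0.0, n_repeat_copies=2,
        repeat_length=5000, repeat_divergence=0.005, seed=5,
    )
    g = simulate_diploid(cfg)
    (a, b) = g.repeats
    seq_a = g.hap1[a.start : a.end]
    seq_b = g.hap1[b.start : b.end]
    diffs = {i for i in range(len(seq_a)) if seq_a[i] != seq_b[i]}
    recorded = {p - a.start for p, _ in a.diagnostics} | {
        p - b.start for p, _ in b.diagnostics
    }
    assert diffs == recorded
    for pos, base in a.diagnostics + b.diagnostics:
        assert g.hap1[pos] == base


def test_error_free_reads_are_exact_substrings():
    cfg = SimConfig(**CFG_SMALL, het_rate=0.0, hifi_error_rate=0.0,
                    sr_error_rate=0.0, seed=11)
    g = simulate_diploid(cfg)
    sim = simulate_reads(g, cfg)
    for read in sim.hifi[:50]:
        assert read.sequence in g.hap1
    for seq in sim.short_reads[:200]:
        assert seq in g.hap1


def test_hifi_coverage_arithmetic():
    cfg = SimConfig(**CFG_SMALL, het_rate=0.0, hifi_coverage=30, seed=13)
    g = simulate_diploid(cfg)
    sim = simulate_reads(g, cfg)
    total = sum(len(r.sequence) for r in sim.hifi)
    target = cfg.hifi_coverage * cfg.genome_length
    assert abs(total - target) / target < 0.10


def test_homopolymer_errors_dominate():
    """With multiplier 10 most injected errors sit in homopolymer runs."""
    cfg = SimConfig(genome_length=50_000, het_rate=0.0, n_repeat_copies=0,
                    hifi_read_length=5000, hifi_error_rate=0.002,
                    homopolymer_error_multiplier=10, seed=17)
    g = simulate_diploid(cfg)
    mask = homopolymer_mask(g.hap1)
    assert mask.mean() >= 0.15  # the genome model provides enough runs
    sim = simulate_reads(g, cfg)
    assert len(sim.error_log) > 100
    in_hp = sum(1 for e in sim.error_log if e.in_homopolymer)
    assert in_hp / len(sim.error_log) >= 0.60
    # homopolymer errors are indels, unique-sequence errors substitutions
    assert all(
        (e.kind in ("ins", "del")) == e.in_homopolymer for e in sim.error_log
    )


def test_full_determinism_byte_identical(tmp_path):
    cfg = SimConfig(**CFG_SMALL, het_rate=0.005, hifi_error_rate=0.001, seed=23)
    outs = []
    for run in ("a", "b"):
        g = simulate_diploid(cfg)
        draft = perturb_assembly(g.hap1, 5, 3, seed=99)
        sim = simulate_reads(g, cfg, draft=draft)
        sam = tmp_path / f"{run}.sam"
        fq = tmp_path / f"{run}.fq"
        write_truth_sam(sim, sam)
        write_fastq([(r.name, r.sequence) for r in sim.hifi], fq)
        outs.append((sam.read_bytes(), fq.read_bytes()))
    assert outs[0] == outs[1]


def test_truth_sam_validates_against_draft(tmp_path):
    """CIGAR-walking every truth record over the draft reconstructs the read:
    '=' columns match the draft base, lengths are consistent."""
    cfg = SimConfig(**CFG_SMALL, het_rate=0.01, hifi_error_rate=0.002, seed=29)
    g = simulate_diploid(cfg)
    draft = perturb_assembly(g.hap1, 8, 4, seed=31)
    sim = simulate_reads(g, cfg, draft=draft)
    sam = tmp_path / "t.sam"
    write_truth_sam(sim, sam)
    reads = load_alignments(sam, min_mapq=1)
    assert len(reads) == len(sim.hifi)
    by_name = {r.name: r for r in sim.hifi}
    for ar in reads:
        src = by_name[ar.read_id]
        assert ar.start == src.pos
        # reconstruct the read from its alleles: equals the emitted sequence
        rebuilt = "".join(
            a for _p, a in sorted(ar.alleles.items()) if a != "-"
        )
        assert rebuilt == src.sequence


def test_error_free_truth_pileup_single_allele_per_column(tmp_path):
    from hifipolish.alignment_io import build_pileup

    cfg = SimConfig(genome_length=5000, het_rate=0.0, n_repeat_copies=0,
                    hifi_read_length=1000, hifi_error_rate=0.0, seed=37)
    g = simulate_diploid(cfg)
    sim = simulate_reads(g, cfg)
    sam = tmp_path / "t.sam"
    write_truth_sam(sim, sam)
    pileup = build_pileup(g.hap1, load_alignments(sam))
    for p, col in enumerate(pileup.columns):
        if pileup.valid_depth[p] > 0:
            assert len(col) == 1
            assert next(iter(col)) == g.hap1[p]


def test_perturb_bookkeeping_and_identity():
    g = simulate_diploid(SimConfig(**CFG_SMALL, het_rate=0.0, seed=41))
    clean = perturb_assembly(g.hap1, 0, 0, seed=1)
    assert clean.seq == g.hap1 and clean.ledger == []
    draft = perturb_assembly(g.hap1, 12, 6, seed=2)
    kinds = [r.kind for r in draft.ledger]
    assert kinds.count("sub") == 12
    assert kinds.count("ins") + kinds.count("del") == 6
    assert draft.seq != g.hap1


def test_perturb_refuses_excessive_error_counts():
    g = simulate_diploid(SimConfig(genome_length=5000, het_rate=0.0,
                                   n_repeat_copies=0, seed=1))
    with pytest.raises(ValueError):
        perturb_assembly(g.hap1, 100, 0, seed=1)


def test_mismap_reports_reads_at_other_copy(tmp_path):
    cfg = SimConfig(genome_length=30_000, het_rate=0.0, n_repeat_copies=2,
                    repeat_length=5000, hifi_read_length=2000,
                    hifi_error_rate=0.0, repeat_mismap_rate=0.5, seed=43)
    g = simulate_diploid(cfg)
    sim = simulate_reads(g, cfg)
    mis = [r for r in sim.hifi if r.mismapped]
    assert mis, "expected some mismapped reads"
    spans = [(rc.start, rc.end) for rc in g.repeats]
    for r in mis:
        assert any(s <= r.pos < e for s, e in spans)
        # the read sequence is the true copy's sequence, not the target's
        assert r.sequence in g.hap1
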