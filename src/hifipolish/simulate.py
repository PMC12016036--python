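"""Synthetic diploid/repeat genomes, HiFi-like reads, and truth alignments.

The generator emulates, at desk scale, the data a HiFi polishing run sees:

* a genome with realistic low-complexity content (a base-repeat Markov chain
  puts a tunable fraction of bases in homopolymer runs, where HiFi errors
  concentrate);
* near-identical planted repeat copies, each with recorded copy-diagnostic
  substitutions;
* a second haplotype derived from the first by heterozygous substitutions
  and 1-3 bp indels at a configurable rate, with a full truth ledger;
* HiFi-like long reads drawn from both haplotypes whose errors are dominated
  by single-base indels inside homopolymer runs (rate x multiplier there),
  and accurate short reads for the K-mer databases;
* a draft assembly perturbed from haplotype 1 with errors biased into
  homopolymer/low-complexity tracts, the substrate the polisher must fix.

Everything is represented per haplotype-1 column: each column carries the
string a haplotype (or the perturbed draft) emits there — a base, an empty
string for a deletion, or base+insertion.  Reads are slices of these column
emissions, so a read's alignment against the (possibly perturbed) draft is
obtained by comparing emissions column by column; no external aligner is
needed and the emitted SAM is exact by construction.  An optional mismap
rate reports reads wholly contained in one repeat copy at the homologous
position of another copy, emulating the repeat-mapping ambiguity the
phasing stage exists to survive.

All randomness flows from ``SimConfig.seed``; outputs are byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions of a desk-scale simulation.

    Defaults model a 100-kb slice of a highly heterozygous diploid genome
    (1% heterozygosity) with two near-identical 5-kb repeat copies, 30x
    HiFi-like reads and 50x accurate short reads.
    """

    genome_length: int = 100_000
    het_rate: float = 0.01  # per-base heterozygous variant rate
    n_repeat_copies: int = 2
    repeat_length: int = 5_000
    repeat_divergence: float = 0.005  # per-base copy-diagnostic substitutions
    hifi_coverage: float = 30.0
    hifi_error_rate: float = 0.001  # per-base, outside homopolymer runs
    homopolymer_error_multiplier: float = 10.0  # rate factor inside runs >= 3
    hifi_read_length: int = 10_000
    sr_coverage: float = 50.0
    sr_error_rate: float = 0.001
    sr_read_length: int = 150
    homopolymer_bias: float = 0.2  # genome base-repeat probability
    repeat_mismap_rate: float = 0.0  # reads misplaced onto another copy
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("het_rate", "repeat_divergence", "hifi_error_rate",
                     "sr_error_rate", "homopolymer_bias", "repeat_mismap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0 or self.hifi_read_length <= 0:
            raise ValueError("lengths must be positive")
        if self.homopolymer_error_multiplier < 1:
            raise ValueError("homopolymer_error_multiplier must be >= 1")


@dataclass
class Variant:
    """One heterozygous difference between the two haplotypes."""

    pos1: int  # hap1 column of the site
    pos2: int  # corresponding hap2 coordinate
    kind: str  # "sub" | "ins" | "del"
    ref: str  # hap1 allele ("" for an insertion)
    alt: str  # hap2 allele ("" for a deletion)


@dataclass
class RepeatCopy:
    """One planted repeat copy with its diagnostic substitutions."""

    copy_id: int
    start: int
    end: int
    diagnostics: list[tuple[int, str]]  # absolute hap1 position, copy base


@dataclass
class DiploidGenome:
    hap1: str
    hap2: str
    variants: list[Variant]
    repeats: list[RepeatCopy]
    hap2_emissions: list[str] = field(repr=False)


@dataclass
class PerturbRecord:
    """One error injected into the draft assembly."""

    pos: int  # hap1 column
    kind: str  # "sub" | "ins" | "del"
    ref: str  # hap1 allele at the site
    alt: str  # draft allele


@dataclass
class PerturbedAssembly:
    seq: str
    ledger: list[PerturbRecord]
    emissions: list[str] = field(repr=False)  # per hap1 column


@dataclass
class SimRead:
    name: str
    sequence: str
    cigar: str
    pos: int  # 0-based position on the draft
    haplotype: int
    mismapped: bool = False


@dataclass
class ErrorRecord:
    read: str
    column: int  # hap1 column of the injected error
    kind: str  # "sub" | "ins" | "del"
    in_homopolymer: bool = False


@dataclass
class SimReads:
    hifi: list[SimRead]
    short_reads: list[str]
    error_log: list[ErrorRecord]
    draft_seq: str
    contig: str = "sim"


def homopolymer_mask(seq: str) -> np.ndarray:
    """Boolean mask of bases inside a homopolymer run of length >= 3."""
    n = len(seq)
    if n == 0:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    same_prev = np.concatenate(([False], arr[1:] == arr[:-1]))
    # run id and run length per position
    run_id = np.cumsum(~same_prev)
    lengths = np.bincount(run_id)
    return lengths[run_id] >= 3


def _random_genome(rng: np.random.Generator, length: int, bias: float) -> str:
    """Markov-chain genome: with probability ``bias`` repeat the last base."""
    fresh = rng.integers(0, 4, size=length)
    repeat = rng.random(length) < bias
    repeat[0] = False
    idx = np.where(repeat, 0, np.arange(length))
    last_fresh = np.maximum.accumulate(idx)
    codes = fresh[last_fresh]
    return "".join(BASES[c] for c in codes)


def simulate_diploid(config: SimConfig) -> DiploidGenome:
    """Generate both haplotypes, the truth variants, and repeat annotation."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    hap1_list = list(_random_genome(rng, L, config.homopolymer_bias))

    repeats: list[RepeatCopy] = []
    if config.n_repeat_copies > 0:
        if config.n_repeat_copies * config.repeat_length > L // 2:
            raise ValueError("repeat copies do not fit in the genome")
        template = _random_genome(rng, config.repeat_length, config.homopolymer_bias)
        n = config.n_repeat_copies
        for i in range(n):
            start = (i + 1) * L // (n + 1) - config.repeat_length // 2
            start = max(0, min(L - config.repeat_length, start))
            copy = list(template)
            diag: list[tuple[int, str]] = []
            n_div = rng.binomial(config.repeat_length, config.repeat_divergence)
            div_pos = rng.choice(config.repeat_length, size=n_div, replace=False)
            for p in sorted(div_pos.tolist()):
                old = copy[p]
                new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
                copy[p] = new
                diag.append((start + p, new))
            hap1_list[start : start + config.repeat_length] = copy
            repeats.append(
                RepeatCopy(i, start, start + config.repeat_length, diag)
            )
    hap1 = "".join(hap1_list)

    emissions = list(hap1)
    variants: list[Variant] = []
    positions = np.flatnonzero(rng.random(L) < config.het_rate)
    last = -10
    for pos in positions.tolist():
        if pos - last < 5 or pos >= L - 4:
            continue
        last = pos
        r = rng.random()
        ref_base = hap1[pos]
        if r < 0.9:
            alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            emissions[pos] = alt
            variants.append(Variant(pos, -1, "sub", ref_base, alt))
        elif r < 0.95:
            ins = "".join(BASES[c] for c in rng.integers(0, 4, int(rng.integers(1, 4))))
            emissions[pos] = ref_base + ins
            variants.append(Variant(pos, -1, "ins", "", ins))
        else:
            d = int(rng.integers(1, 4))
            d = min(d, L - pos - 1)
            for j in range(d):
                emissions[pos + j] = ""
            variants.append(Variant(pos, -1, "del", hap1[pos : pos + d], ""))
            last = pos + d

    # hap2 coordinate of each variant from the cumulative emission lengths
    lens = np.fromiter((len(e) for e in emissions), dtype=np.int64, count=L)
    offsets = np.concatenate(([0], np.cumsum(lens)))
    for v in variants:
        v.pos2 = max(0, int(offsets[v.pos1]) - (1 if v.kind == "del" else 0))
    hap2 = "".join(emissions)
    return DiploidGenome(hap1, hap2, variants, repeats, emissions)


def perturb_assembly(
    hap1: str,
    n_subs: int,
    n_indels: int,
    seed: int = 0,
    homopolymer_fraction: float = 0.7,
) -> PerturbedAssembly:
    """Inject base errors into haplotype 1 to form the draft assembly.

    ``homopolymer_fraction`` of the errors are placed inside homopolymer or
    low-complexity tracts, where HiFi assemblies actually err; indels there
    extend or shorten the run by 1-2 bases.  Error counts above one per
    kilobase are refused (the model is a *highly accurate* draft).
    """
    L = len(hap1)
    if n_subs + n_indels > L // 1000:
        raise ValueError("error counts exceed genome_length / 1000")
    rng = np.random.default_rng(seed)
    hp = homopolymer_mask(hap1)
    hp_pool = np.flatnonzero(hp)
    emissions = list(hap1)
    ledger: list[PerturbRecord] = []
    used: set[int] = set()

    def _pick(in_hp: bool) -> int:
        for _ in range(1000):
            if in_hp and hp_pool.size:
                pos = int(rng.choice(hp_pool))
            else:
                pos = int(rng.integers(0, L))
            if 3 < pos < L - 4 and all(abs(pos - u) > 8 for u in used):
                used.add(pos)
                return pos
        raise RuntimeError("could not place error away from previous ones")

    for kind_count, kind in ((n_subs, "sub"), (n_indels, "indel")):
        for _ in range(kind_count):
            in_hp = bool(rng.random() < homopolymer_fraction)
            pos = _pick(in_hp)
            ref_base = hap1[pos]
            if kind == "sub":
                alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
                emissions[pos] = alt
                ledger.append(PerturbRecord(pos, "sub", ref_base, alt))
            else:
                d = int(rng.integers(1, 3))  # 1-2 bp
                if rng.random() < 0.5:
                    ins = ref_base * d if in_hp else "".join(
                        BASES[c] for c in rng.integers(0, 4, d)
                    )
                    emissions[pos] = ref_base + ins
                    ledger.append(PerturbRecord(pos, "ins", ref_base, ref_base + ins))
                else:
                    for j in range(d):
                        emissions[pos + j] = ""
                        used.add(pos + j)
                    ledger.append(PerturbRecord(pos, "del", hap1[pos : pos + d], ""))
    ledger.sort(key=lambda r: r.pos)
    return PerturbedAssembly("".join(emissions), ledger, emissions)


def _emission_offsets(emissions: list[str]) -> np.ndarray:
    lens = np.fromiter((len(e) for e in emissions), dtype=np.int64,
                       count=len(emissions))
    return np.concatenate(([0], np.cumsum(lens)))


def simulate_reads(
    genome: DiploidGenome | str,
    config: SimConfig,
    draft: PerturbedAssembly | None = None,
    contig: str = "sim",
) -> SimReads:
    """Draw HiFi-like and short reads and derive their truth alignments.

    ``genome`` may be a :class:`DiploidGenome` (reads come uniformly from
    both haplotypes) or a plain sequence (haploid).  ``draft`` is the
    perturbed assembly the reads are reported against; by default reads are
    aligned to haplotype 1 itself.  Alignments are exact by construction:
    read and draft are compared column by column in the haplotype-1 frame.
    """
    if isinstance(genome, str):
        genome = DiploidGenome(genome, genome, [], [], list(genome))
    hap_emissions = {1: list(genome.hap1), 2: genome.hap2_emissions}
    L = len(genome.hap1)
    if draft is None:
        draft_emissions = list(genome.hap1)
        draft_seq = genome.hap1
    else:
        draft_emissions = draft.emissions
        draft_seq = draft.seq
    draft_offsets = _emission_offsets(draft_emissions)
    diploid = genome.hap2 != genome.hap1 or bool(genome.variants)

    rng = np.random.default_rng(config.seed + 1)
    hifi: list[SimRead] = []
    error_log: list[ErrorRecord] = []
    n_reads = int(round(config.hifi_coverage * L / config.hifi_read_length))
    hp_masks = {1: homopolymer_mask(genome.hap1), 2: homopolymer_mask(genome.hap2)}
    hap2_offsets = _emission_offsets(genome.hap2_emissions)

    for i in range(n_reads):
        hap = int(rng.integers(1, 3)) if diploid else 1
        c0 = int(rng.integers(0, L))
        c1 = min(L, c0 + config.hifi_read_length)
        tokens = [hap_emissions[hap][c] for c in range(c0, c1)]
        name = f"hifi_{i:05d}_hap{hap}"
        _inject_hifi_errors(
            tokens, c0, hap, genome, hp_masks, hap2_offsets, config, rng,
            name, error_log,
        )
        # optional mismap: read wholly inside one repeat copy reported at the
        # homologous position of another copy
        acol0 = c0
        mismapped = False
        if config.repeat_mismap_rate > 0 and len(genome.repeats) > 1:
            for rc in genome.repeats:
                if rc.start <= c0 and c1 <= rc.end:
                    if rng.random() < config.repeat_mismap_rate:
                        others = [r for r in genome.repeats if r.copy_id != rc.copy_id]
                        target = others[int(rng.integers(0, len(others)))]
                        acol0 = c0 + (target.start - rc.start)
                        mismapped = True
                    break
        read = _align_tokens(tokens, acol0, draft_emissions, draft_offsets,
                             name, hap, mismapped)
        if read is not None:
            hifi.append(read)

    short_reads: list[str] = []
    haps = (genome.hap1, genome.hap2)
    n_sr = int(round(config.sr_coverage * L / config.sr_read_length))
    for _ in range(n_sr):
        hs = haps[int(rng.integers(0, 2))] if diploid else haps[0]
        if len(hs) <= config.sr_read_length:
            s = 0
        else:
            s = int(rng.integers(0, len(hs) - config.sr_read_length))
        seq = hs[s : s + config.sr_read_length]
        if config.sr_error_rate > 0:
            errs = np.flatnonzero(rng.random(len(seq)) < config.sr_error_rate)
            if errs.size:
                chars = list(seq)
                for e in errs.tolist():
                    chars[e] = BASES[
                        (BASES.index(chars[e]) + int(rng.integers(1, 4))) % 4
                    ]
                seq = "".join(chars)
        short_reads.append(seq)

    return SimReads(hifi, short_reads, error_log, draft_seq, contig)


def _inject_hifi_errors(
    tokens: list[str],
    c0: int,
    hap: int,
    genome: DiploidGenome,
    hp_masks: dict[int, np.ndarray],
    hap2_offsets: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    read_name: str,
    error_log: list[ErrorRecord],
) -> None:
    """Mutate read tokens in place with homopolymer-biased errors."""
    if config.hifi_error_rate <= 0:
        return
    hp = hp_masks[hap]
    # per-character error probabilities, by haplotype-sequence position
    flat: list[tuple[int, int]] = []  # (token index, char index)
    probs: list[float] = []
    for ti, tok in enumerate(tokens):
        col = c0 + ti
        if hap == 1:
            hap_pos = col
        else:
            hap_pos = int(hap2_offsets[col])
        for ci in range(len(tok)):
            p = min(hap_pos + ci, len(hp) - 1)
            in_hp = bool(hp[p])
            rate = config.hifi_error_rate * (
                config.homopolymer_error_multiplier if in_hp else 1.0
            )
            flat.append((ti, ci))
            probs.append(min(rate, 0.5))
    if not flat:
        return
    draws = rng.random(len(flat))
    hits = [i for i in range(len(flat)) if draws[i] < probs[i]]
    # apply from the end so char indices stay valid
    for i in sorted(hits, reverse=True):
        ti, ci = flat[i]
        tok = tokens[ti]
        col = c0 + ti
        hap_pos = col if hap == 1 else int(hap2_offsets[col])
        in_hp = bool(hp[min(hap_pos + ci, len(hp) - 1)])
        if in_hp:
            # homopolymer indel: delete or duplicate the base
            if rng.random() < 0.5:
                tokens[ti] = tok[:ci] + tok[ci + 1 :]
                error_log.append(ErrorRecord(read_name, col, "del", True))
            else:
                tokens[ti] = tok[: ci + 1] + tok[ci] + tok[ci + 1 :]
                error_log.append(ErrorRecord(read_name, col, "ins", True))
        else:
            alt = BASES[(BASES.index(tok[ci]) + int(rng.integers(1, 4))) % 4]
            tokens[ti] = tok[:ci] + alt + tok[ci + 1 :]
            error_log.append(ErrorRecord(read_name, col, "sub", False))


def _align_tokens(
    tokens: list[str],
    acol0: int,
    draft_emissions: list[str],
    draft_offsets: np.ndarray,
    name: str,
    hap: int,
    mismapped: bool,
) -> SimRead | None:
    """Column-wise alignment of read tokens against the draft emissions."""
    L = len(draft_emissions)
    n = min(len(tokens), L - acol0)
    if n <= 0:
        return None
    tokens = tokens[:n]
    dcols = [draft_emissions[acol0 + j] for j in range(n)]
    # trim columns where either side is empty at the boundaries
    lo, hi = 0, n
    while lo < hi and (tokens[lo] == "" or dcols[lo] == ""):
        lo += 1
    while hi > lo and (tokens[hi - 1] == "" or dcols[hi - 1] == ""):
        hi -= 1
    if lo >= hi:
        return None
    ops: list[tuple[str, int]] = []

    def _push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    seq_parts: list[str] = []
    for j in range(lo, hi):
        r, d = tokens[j], dcols[j]
        seq_parts.append(r)
        m = min(len(r), len(d))
        for x in range(m):
            _push("=" if r[x] == d[x] else "X", 1)
        if len(r) > m:
            _push("I", len(r) - m)
        if len(d) > m:
            _push("D", len(d) - m)
    seq = "".join(seq_parts)
    if not seq or not any(op in "=X" for op, _ in ops):
        return None
    cigar = "".join(f"{ln}{op}" for op, ln in ops)
    pos = int(draft_offsets[acol0 + lo])
    return SimRead(name, seq, cigar, pos, hap, mismapped)


def write_truth_sam(
    sim: SimReads, path: str | Path, contig: str | None = None
) -> None:
    """Write the truth alignments as SAM (pysam), sorted by position."""
    contig = contig or sim.contig
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": len(sim.draft_seq)}],
    }
    reads = sorted(sim.hifi, key=lambda r: (r.pos, r.name))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_sequence = r.sequence
            a.set_tags([("HP", r.haplotype, "i"), ("XM", int(r.mismapped), "i")])
            out.write(a)


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA wrapped to ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(
    reads: list[tuple[str, str]] | list[str], path: str | Path, qual_char: str = "I"
) -> None:
    """Write reads as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for i, item in enumerate(reads):
            if isinstance(item, tuple):
                name, seq = item
            else:
                name, seq = f"read_{i:06d}", item
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
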