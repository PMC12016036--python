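# hifipolish

Repeat-aware, haplotype-preserving polishing of genome assemblies built from
PacBio HiFi long reads.

## The problem

Assemblies from HiFi reads are highly accurate (QV ≈ 50–60) but still carry
base-level errors, concentrated in homopolymer and low-complexity tracts
where HiFi reads themselves stumble. Correcting them is delicate: a polisher
that simply maximises agreement with the most abundant reads or K-mers will
(1) *overcorrect* near-identical repeat copies toward each other, and
(2) break local haplotype structure, replacing one parental allele with the
other and inflating the haplotype switch-error rate — both while nominally
*improving* the K-mer QV. `hifipolish` is for assembly and T2T-genome groups
who need the last residual errors fixed without paying either price.

## The algorithm

1. **K-mer score chain (KSC) consensus.** A dynamic program over the read
   pileup. For allele *a* at column *P*,

   `score(P, a) = max_b [ score(P−1, b) + count(chain-mer ending in a) ] − depth(P)`

   where the chain-mer is the tuple of the last *g* alleles (default *g* = 3)
   and `depth(P)` is the column's valid read depth. The traceback yields a
   read-consistent consensus rather than a column-wise patchwork. Columns
   whose chosen allele is supported by ≤ 95% of reads are **low-quality
   positions (LQPs)**; adjacent LQPs merge into **low-quality regions
   (LQRs)**.
2. **Short-read K-mer validation.** K-mers spanning each LQR, extracted from
   the reads that map across it, are filtered against canonical K-mer count
   databases built from accurate short reads (default *k* = 21, count ≥ 2).
   An LQR whose valid K-mer set still holds ≥ 2 distinct K-mers is
   **heterozygous**: the disagreement is real sequence — two haplotypes or
   two repeat copies — not noise.
3. **Read phasing by community detection.** Heterozygous LQRs induce a
   signed read graph (+1 per shared spanning K-mer, −1 per
   position-equivalent disagreement). Louvain community detection on the
   positive subgraph groups reads by haplotype/repeat copy; community pairs
   with negative total inter-community weight are **conflicts**. For each
   conflict the community sharing the most K-mers with the reference (or,
   optionally, the largest) is kept and the other side's reads are
   discarded. The loop repeats until no conflict remains.
4. **Residual resolution.** The consensus is regenerated from the surviving
   reads. Remaining LQRs are patched with the best-supported valid K-mer;
   regions spanned by no valid K-mer keep the reference sequence — the
   conservative choice that avoids overcorrection. Splices are verified to
   introduce no K-mer absent from both the short reads and the draft.

The package also implements the assessment metrics (changed K-mers,
potential overcorrection K-mers, K-mer QV, alignment-identity QV with
coverage ≤ 90% / identity ≤ 98% filters, haplotype switch error) and a
deterministic synthetic-data generator (diploid genomes with configurable
heterozygosity, near-identical repeat copies, homopolymer-biased HiFi-like
errors, truth alignments) so the whole pipeline is testable at desk scale.

## Worked example

Polishing a haplotype-1 draft of a 30-kb diploid genome (1% heterozygosity)
with reads from *both* haplotypes:

```bash
python examples/02_haplotype_preserving_polish.py
```

```
heterozygous truth variants : 272
phasing iterations          : 2
reads discarded (hap1/hap2) : 0/39
haplotype switches          : 0 over 275 sites
polished equals haplotype 1 : True
```

Every heterozygous locus starts as a 50/50 pileup conflict; the phaser
discards exactly the 39 haplotype-2 reads (and none from haplotype 1), and
the polished sequence is haplotype 1, base for base — zero switch errors.
The other examples cover draft-error recovery (`01`), repeat-copy
preservation under mismapping (`03`) and the assessment metrics (`04`).

A thin CLI mirrors the library:

```bash
hifipolish simulate --outdir sim --length 20000 --seed 7
hifipolish kmerdb sim/short.fq --k 21 --min-count 2 -o sim/sr.kc.tsv.gz
hifipolish polish -a sim/draft.fa -b sim/truth.sam -d sim/sr.kc.tsv.gz \
    -o polished.fa --report report.json --mode reference --seed 7
hifipolish eval --polished polished.fa --original sim/draft.fa -d sim/sr.kc.tsv.gz
```

## Layout

- `src/hifipolish/kmer_db.py` — canonical K-mer count databases
- `src/hifipolish/alignment_io.py` — SAM parsing, allele pileups
- `src/hifipolish/ksc.py` — chain consensus, LQP/LQR detection
- `src/hifipolish/phasing.py` — K-mer validation, read graph, Louvain,
  conflict resolution
- `src/hifipolish/polish.py` — per-contig orchestration, residual rules
- `src/hifipolish/evaluate.py` — assessment metrics
- `src/hifipolish/simulate.py` — synthetic data with truth ledgers
- `src/hifipolish/cli.py` — `hifipolish` subcommands
- `docs/methods.md` — models, parameters, design decisions, limitations
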