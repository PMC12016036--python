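# Methods

This note documents the models, parameter choices and numerical decisions
behind `hifipolish`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Consensus model

The K-mer score chain (KSC) consensus treats the read pileup over one
contig as a lattice of (column, allele) nodes. An allele is a single base,
a deletion (`-`), or a base followed by an inserted string; insertions are
anchored to the reference column of their left base so every column stays
indexable by draft coordinate (0-based half-open everywhere inside the
package; SAM's 1-based convention exists only at the pysam boundary).

The score recurrence is

    score(P, a) = max_b [ score(P-1, b) + n(chain ending in a) ] - depth(P)

where the chain is the tuple of the last `chain_k` alleles along the path
and `n(...)` counts reads carrying that exact allele tuple. Because a
chain couples only `chain_k` consecutive columns, the dynamic program runs
over states of the last `chain_k - 1` alleles; with the handful of alleles
a real column exhibits this is effectively linear in contig length. The
implementation runs independently over maximal covered segments;
zero-coverage columns break the chain and emit the draft base.

Subtracting the valid depth makes a fully supported path score 0 and any
disagreement strictly negative, so the traceback prefers paths supported
by whole reads over column-wise patchworks. When errors are independent
across columns the chain reduces to the column-wise majority vote — the
test suite checks this equivalence against a brute-force majority oracle
on 50 random pileups.

**Tie-breaking.** Exact score ties prefer the allele matching the draft
base, then the lexicographically smallest allele. This makes the consensus
deterministic and conservative toward the input assembly: a 50/50
heterozygous column resolves to the draft's own haplotype even before
phasing.

**Low-quality detection.** A traceback column whose chosen allele is
supported by at most `lqp_threshold` (default 0.95, *inclusive*) of its
valid depth is a low-quality position; zero-coverage columns always are.
Consecutive LQPs closer than `merge_gap` (default = the validation k, 21)
merge into one low-quality region. `merge_lqrs` accepts a `pad` parameter
(default 0); the pipeline leaves regions unpadded and applies the
±(k−1) window exactly once, at K-mer extraction — padding in both places
would make every region longer than k and no single K-mer could span it.

## Short-read K-mer validation

Databases map canonical K-mers (lexicographic minimum of the strand pair —
short reads are unstranded) to counts; K-mers are stored as 2-bit codes,
limiting k to 31. Defaults k = 21, `min_count` = 2: 21 is the standard
length at which K-mers in a ~100-Mb to gigabase genome are mostly unique,
and a count threshold of 2 drops singleton sequencing errors. Several
databases of different k may be supplied; a query is validated by the
database matching its length. Serialization is sorted `kmer TAB count`
text (optionally gzipped) with a header carrying k and `min_count`.

**Anchored K-mer sets per LQR.** Only reads whose alignment fully spans
the window `[start-(k-1), end+(k-1))` contribute. Each K-mer is keyed by
the reference column of its first base (its *anchor*), which keeps K-mers
comparable across reads with different indels. The heterozygosity test
uses one canonical anchor — the spanning position with the LQR closest to
the K-mer's centre — because pooling all window anchors would make any
locus "heterozygous" (different anchors necessarily give different
K-mers). A set with ≥ 2 distinct valid K-mers at that anchor is
heterozygous. For regions longer than k, where no single K-mer spans, the
anchor sits at the region start; such regions are rare at HiFi error rates
and are handled conservatively downstream.

## Read graph and phasing

For each heterozygous LQR and each pair of spanning reads, the edge weight
gains +1 per anchor where both carry the same valid K-mer and −1 per
anchor where both carry valid K-mers that differ. Unit weights (rather
than weights scaled by K-mer counts) keep the graph robust to coverage
fluctuations; database counts are reserved for residual resolution.

Louvain modularity is undefined for negative weights, so community
detection runs on the positive subgraph (seeded, resolution 1.0; community
labels are re-assigned in order of each community's smallest read id for
determinism). The signed weights then define inter-community totals;
a pair with negative total weight is a conflict. Conflicts are resolved
most-negative first: mode `"reference"` keeps the community whose reads
share the most K-mers with the draft (each shared K-mer counted once per
read, so deeper communities are not penalised), mode `"largest"` keeps the
bigger community; exact ties keep the community containing the smallest
read id. All reads of each losing community are discarded and the whole
loop (consensus → LQRs → K-mer sets → graph → Louvain → resolution)
repeats, up to `max_iters` (default 5) or until no conflict remains.

On a long contig Louvain cuts each haplotype's chain of overlapping reads
into several communities; adjacent same-haplotype segments attract each
other (positive inter-community weight) and are never conflicts. Where the
true partition matters — tests, diagnostics — communities linked by
positive weight are coarsened into *sides* (`community_sides`); only
cross-side negative pairs are haplotype or repeat-copy boundaries.

## Final consensus and residual resolution

After phasing, the consensus is regenerated from the surviving reads and
emitted per column. Two conservative guards apply:

* **Confirmation depth.** Columns covered by fewer than
  `min_confirm_depth` (default 3) reads keep the draft base. A lone read's
  sequencing error would otherwise be adopted with nominal 100% support;
  depth ≤ 3 is exactly the regime where residual assembly errors
  concentrate, and no confident call is possible there.
* **Residual rules.** Remaining LQRs are resolved by their valid K-mer
  set: none → keep the reference K-mer (`reference_kmer`); one or more →
  splice the best one (`best_count_kmer`), ranked by HiFi read support,
  then short-read count, then reference match, then lexicographic order.
  Read support outranks the database count because the reads surviving
  phasing represent the locus's own haplotype, while the short-read pool
  mixes both haplotypes and all repeat copies — ranking by database count
  alone would reintroduce exactly the switch errors the phaser removed.
  Regions longer than k use the most common spanning read subsequence,
  accepted only if every one of its K-mers validates (`majority`), else
  the reference.

Reads carrying the same K-mer string can align it over different column
ranges (an indel inside a homopolymer run shifts the window without
changing the 21-mer), so each candidate's reference span is voted on
separately and the K-mer string is spliced over the winning span,
left-aligned. Finally, every applied splice is re-checked locally: if the
spliced window would contain a K-mer absent from both the short reads and
the draft (a junction artifact), the splice is reverted to the reference.
Together these guards make "no unsupported sequence is ever introduced" a
structural property rather than a statistical tendency.

Edits are reported per draft column (position, draft allele, new allele);
splices map back onto columns char by char so overlapping windows of
nearby regions stay consistent.

## Assessment metrics

* `changed_kmers` — canonical K-mers present in the polished assembly but
  not the original; one substitution introduces at most 2k−1 of them.
* `overcorrection_kmers` — the subset also absent from the short-read
  database: new sequence supported by nothing. Haplotype switches inflate
  only the former; real damage inflates both.
* `kmer_qv` — per-base error rate `E = 1 − (shared/total)^(1/k)` over all
  assembly K-mer instances, reported as −10·log10(E), capped at QV 99 when
  everything is supported (finite reporting for the zero-error case).
* `alignment_qv` — pooled `−10·log10(1 − Σmatch/Σblock)` over PAF records
  after removing alignments with coverage ≤ 0.90 or identity ≤ 0.98
  (inclusive removal; coverage = block length / query length, matching
  pseudo-read evaluation where the query is a genome slice).
* `switch_error` — heterozygous sites are derived by global alignment of
  the two truth haplotypes (edlib) or supplied directly; each site is
  assigned to a haplotype by which distinguishing K-mer (the k-window
  centred on the site) the polished assembly contains, sites matching both
  or neither are excluded, and switches are counted over adjacent assigned
  sites (rate = switches per adjacent pair; fewer than two sites is
  flagged degenerate and reported as rate 0).

## Synthetic data

The generator produces, deterministically from one seed: a genome from a
base-repeat Markov chain (`homopolymer_bias` 0.2, putting ≳ 20% of bases
in runs ≥ 3 — enough low-complexity sequence to exercise the homopolymer
error model); optional near-identical repeat copies (two 5-kb copies at
0.5% divergence by default) with every copy-diagnostic substitution
recorded; a second haplotype at `het_rate` (default 1%; 90% substitutions,
10% 1–3-bp indels) with a full variant ledger; HiFi-like reads (30×,
10 kb) whose errors are substitutions at 0.1% outside homopolymer runs
and single-base indels at 10× that rate inside runs ≥ 3; accurate short
reads (50×, 150 bp, 0.1% substitutions); and a draft assembly perturbed
from haplotype 1 with errors biased 70% into homopolymer tracts.

Everything is represented per haplotype-1 column (each column emits a
string), so a read's alignment against any column-derived sequence — the
other haplotype, the perturbed draft — follows by comparing emissions
column by column. The emitted SAM is exact by construction and no external
aligner is needed; truth alignments against a genuine mapper's output can
be substituted at the `load_alignments` boundary.

`repeat_mismap_rate` optionally reports reads wholly contained in one
repeat copy at the homologous position of another, emulating the
repeat-mapping ambiguity the phasing stage exists to survive; in the
repeat scenario reads are scaled to 2 kb so a read can sit inside a 5-kb
copy, the same desk-scaling applied to the 100-kb genome itself.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: instrument-specific error profiles (chimeras,
adapter artifacts, quality-correlated errors), mapping ambiguity beyond
whole-read repeat mismapping (no soft-clipped, split or partially
misplaced alignments), structural variation, coverage biases (GC,
PCR), and repeat families larger or more divergent than the planted
copies. Results on real genomes additionally depend on the upstream
aligner's behaviour in repeats.

## Problem sizes

The test suite and the acceptance script run the pipeline on 100-kb
genomes at 30× HiFi / 50× short-read coverage (50 kb for the repeat
scenario, 2 × 5-kb copies), chosen so a full run takes minutes on one
CPU while keeping ≥ 10 reads per locus per haplotype — the same
reads-per-locus geometry as a production run.

## Limitations

* Phasing is local: reads are grouped per contig through shared LQRs, not
  into chromosome-scale haplotype blocks; trio or Hi-C integration is out
  of scope.
* Heterozygosity detection keys on a single canonical anchor per region;
  regions longer than k fall back to conservative handling rather than a
  full spanning analysis.
* Columns below the confirmation depth and regions with no valid spanning
  K-mer are left as the draft — the polisher deliberately prefers a known
  draft error over an unsupported correction.
* The K-mer databases are held in memory; counting is vectorised but not
  disk-backed, so inputs beyond a few hundred Mb of genome are outside the
  intended desk scale.
* Alignment QV depends on the upstream mapper's PAF; the package evaluates
  but does not produce those alignments.
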