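"""Assess an assembly: K-mer changes, overcorrection, QV, switch error.

Builds a small genome and a deliberately damaged copy, then walks through
the assessment metrics: changed K-mers (any new sequence), potential
overcorrection K-mers (new sequence unsupported by short reads), the
K-mer-based quality value, and the alignment-identity QV computed from PAF
records with the coverage/identity filters.
"""

import numpy as np

from hifipolish import build_kmer_db, changed_kmers, kmer_qv, overcorrection_kmers
from hifipolish.evaluate import PafRecord, alignment_qv

rng = np.random.default_rng(41)
genome = "".join(rng.choice(list("ACGT"), size=20_000))
# the sample is heterozygous at one site: short reads carry both alleles
pos = 10_000
other_hap = genome[:pos] + ("A" if genome[pos] != "A" else "C") + genome[pos + 1 :]
db = build_kmer_db([genome, other_hap], k=21, min_count=1)

# a haplotype switch (the other allele, present in the short reads) ...
hap_edit = other_hap
# ... versus a bogus edit (random sequence supported by nothing)
bogus = genome[:pos] + "".join(rng.choice(list("ACGT"), size=21)) + genome[pos + 21 :]

for name, asm in (("haplotype edit", hap_edit), ("random edit", bogus)):
    print(f"{name:15s} changed={changed_kmers(asm, genome, k=21):4d} "
          f"overcorrection={overcorrection_kmers(asm, genome, db):4d} "
          f"kmer_qv={kmer_qv(asm, db):5.1f}")
# Both edits change K-mers (up to 2k-1 = 41 from one substitution), but only
# the random edit produces overcorrection K-mers and drops the K-mer QV:
# this is how the two metrics separate haplotype switches from real damage.

def paf(nmatch, blocklen, qlen):
    return PafRecord("q", qlen, 0, blocklen, "+", "t", blocklen, 0,
                     blocklen, nmatch, blocklen, 60)

records = [
    paf(9990, 10000, 10000),   # identity 99.9%, full coverage: kept
    paf(9800, 10000, 10000),   # identity exactly 98%: removed (inclusive)
    paf(9990, 9000, 10000),    # coverage exactly 90%: removed (inclusive)
]
qv, kept = alignment_qv(records)
print(f"alignment QV over {kept} surviving record(s): {qv:.1f}")
# Only the first record survives the filters; its identity 0.999 gives
# QV = -10*log10(1 - 0.999) = 30.
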