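"""Canonical K-mer count databases built from accurate short reads.

The polisher validates every candidate K-mer extracted from HiFi long reads
against one or more short-read K-mer databases: a K-mer that is not supported
by the (essentially error-free) short-read data is treated as a sequencing or
assembly artifact and excluded downstream.  K-mers are canonicalised as the
lexicographic minimum of the forward and reverse-complement strand, the usual
convention for unstranded short-read data.

K-mers are stored internally as 2-bit integer codes (A=0, C=1, G=2, T=3),
which keeps counting a vectorised numpy operation; the public interface is
plain DNA strings.  ``k`` is limited to 31 so a code fits in a signed 64-bit
integer.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: numpy lookup table: ASCII byte -> 2-bit base code, 4 for anything else
_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

MAX_K = 31


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a K-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode_kmer(kmer: str) -> int:
    """2-bit integer code of a K-mer (forward strand, no canonicalisation)."""
    code = 0
    for ch in kmer:
        b = _BASE_CODE[ord(ch)]
        if b == 4:
            raise ValueError(f"non-ACGT base in K-mer {kmer!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every K-length window of ``seq`` without an N.

    Vectorised: one pass of k shifted adds for the forward codes and one for
    the reverse-complement codes, then an elementwise minimum.
    """
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64)
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    nwin = n - k + 1
    fwd = np.zeros(nwin, dtype=np.int64)
    rev = np.zeros(nwin, dtype=np.int64)
    bad = np.zeros(nwin, dtype=bool)
    for j in range(k):
        col = b[j : j + nwin]
        np.logical_or(bad, col == 4, out=bad)
        fwd += np.where(col == 4, 0, col) << (2 * (k - 1 - j))
        rev += np.where(col == 4, 0, 3 - col) << (2 * j)
    codes = np.minimum(fwd, rev)
    return codes[~bad]


@dataclass
class KmerDB:
    """A canonical K-mer -> count map for a single K length.

    Parameters
    ----------
    k
        K-mer length in bases (2..31).
    counts
        Mapping from canonical 2-bit K-mer code to a strictly positive count.
    min_count
        Validity threshold: a K-mer is *valid* when its stored count is at
        least ``min_count``.  K-mers below the threshold are dropped at build
        time, so membership in ``counts`` already implies validity.
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)
    min_count: int = 2

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.k > MAX_K:
            raise ValueError(f"k must be <= {MAX_K}, got {self.k}")

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def get(self, kmer: str) -> int:
        """Count of ``kmer`` (strand-insensitive); 0 if absent.

        Raises ``ValueError`` when ``len(kmer) != k``.
        """
        if len(kmer) != self.k:
            raise ValueError(
                f"query length {len(kmer)} does not match database k={self.k}"
            )
        code = min(encode_kmer(kmer), encode_kmer(revcomp(kmer)))
        return self.counts.get(code, 0)

    def get_code(self, code: int) -> int:
        """Count by canonical 2-bit code; 0 if absent."""
        return self.counts.get(code, 0)

    def is_valid(self, kmer: str) -> bool:
        """Whether the K-mer passes the short-read validity threshold."""
        return self.get(kmer) >= self.min_count

    def code_set(self) -> np.ndarray:
        """Sorted array of stored canonical codes (for vectorised set ops)."""
        return np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))

    def items(self) -> Iterator[tuple[str, int]]:
        """Iterate (kmer string, count) in sorted K-mer order."""
        for code in sorted(self.counts):
            yield decode_kmer(code, self.k), self.counts[code]


def build_kmer_db(
    sequences: Iterable[str], k: int, min_count: int = 2
) -> KmerDB:
    """Count canonical K-mers over ``sequences`` and keep those >= min_count.

    Windows containing a non-ACGT character are skipped.  Records whose
    alphabet is entirely invalid contribute nothing (logged at debug level).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}, got {k}")
    chunks: list[np.ndarray] = []
    n_skipped = 0
    for seq in sequences:
        codes = _window_codes(seq, k)
        if codes.size == 0 and len(seq) >= k:
            n_skipped += 1
            continue
        if codes.size:
            chunks.append(codes)
    if n_skipped:
        logger.warning("%d record(s) contributed no valid %d-mers", n_skipped, k)
    if not chunks:
        return KmerDB(k=k, counts={}, min_count=min_count)
    allcodes = np.concatenate(chunks)
    uniq, cnt = np.unique(allcodes, return_counts=True)
    keep = cnt >= min_count
    counts = dict(zip(uniq[keep].tolist(), cnt[keep].tolist()))
    return KmerDB(k=k, counts=counts, min_count=min_count)


def query_count(db: KmerDB, kmer: str) -> int:
    """Stored count of the canonical form of ``kmer``; 0 if absent."""
    return db.get(kmer)


def is_valid_kmer(dbs: list[KmerDB] | KmerDB, kmer: str) -> bool:
    """Validate a K-mer against the database whose k matches its length.

    Multiple databases of different k may be supplied; validity is decided by
    the one matching ``len(kmer)``.  Raises ``ValueError`` when no database
    has a matching k.
    """
    if isinstance(dbs, KmerDB):
        dbs = [dbs]
    for db in dbs:
        if db.k == len(kmer):
            return db.is_valid(kmer)
    raise ValueError(
        f"no K-mer database with k={len(kmer)} "
        f"(available: {sorted(db.k for db in dbs)})"
    )


def db_for_k(dbs: list[KmerDB] | KmerDB, k: int) -> KmerDB:
    """Return the database with the requested k, or raise ``ValueError``."""
    if isinstance(dbs, KmerDB):
        dbs = [dbs]
    for db in dbs:
        if db.k == k:
            return db
    raise ValueError(f"no K-mer database with k={k}")


def write_kmer_db(db: KmerDB, path: str | Path) -> None:
    """Write a database as sorted, gzipped two-column text (kmer TAB count).

    The single header line records k and min_count so a reloaded database
    applies the same validity threshold.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"#k={db.k}\tmin_count={db.min_count}\n")
        for kmer, count in db.items():
            fh.write(f"{kmer}\t{count}\n")


def read_kmer_db(path: str | Path) -> KmerDB:
    """Read a database written by :func:`write_kmer_db`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise ValueError(f"{path}: missing '#k=...' header line")
        fields = dict(part.split("=", 1) for part in header[1:].split("\t"))
        k = int(fields["k"])
        min_count = int(fields.get("min_count", 1))
        counts: dict[int, int] = {}
        for line in fh:
            kmer, cnt = line.rstrip("\n").split("\t")
            counts[encode_kmer(kmer)] = int(cnt)
    return KmerDB(k=k, counts=counts, min_count=min_count)
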