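"""Nucleotide-sequence primitives: validated DNA records, FASTA I/O,
longest-common-substring, and the k-mer membership index used by the
off-target screen.

Conventions
-----------
* Coordinates are 0-based, half-open throughout.
* Sequences are stored as DNA over the strict alphabet {A, C, G, T};
  ambiguity codes (including N) are rejected by default because guide
  sequences must be unambiguous.  :func:`as_rna` renders a sequence with
  T replaced by U for RNA-facing output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "NucSequence",
    "Transcriptome",
    "KmerIndex",
    "reverse_complement",
    "as_rna",
    "longest_common_substring",
    "build_kmer_index",
    "read_fasta",
    "write_fasta",
]

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains characters outside the allowed alphabet."""


def _validate_alphabet(seq: str, allow_n: bool = False) -> None:
    allowed = _DNA_N if allow_n else _DNA
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"invalid nucleotide(s) {sorted(bad)!r}; allowed: {sorted(allowed)}"
        )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def as_rna(seq: str) -> str:
    """Render a DNA string as RNA (T -> U)."""
    _validate_alphabet(seq)
    return seq.replace("T", "U")


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T} (N allowed only if
    ``allow_n=True`` was passed at construction, for hard-masking)."""

    id: str
    seq: str
    allow_n: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        _validate_alphabet(self.seq, allow_n=self.allow_n)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Transcriptome:
    """A background transcriptome with the target gene's isoforms flagged.

    Parameters
    ----------
    transcripts:
        All transcripts, target isoforms included.
    target_ids:
        Identifiers of the target gene's isoforms; these are excluded from
        off-target scanning (a guide is supposed to hit them).
    k:
        Seed length in nt for the k-mer index (default 16, i.e. one more
        than the 15-nt maximum tolerated off-target complementarity).
    """

    transcripts: list[NucSequence]
    target_ids: frozenset[str] = frozenset()
    k: int = 16

    def __post_init__(self) -> None:
        self.target_ids = frozenset(self.target_ids)
        ids = {t.id for t in self.transcripts}
        missing = self.target_ids - ids
        if missing:
            raise ValueError(f"target_ids not present in transcripts: {sorted(missing)}")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    def non_target_transcripts(self) -> list[NucSequence]:
        return [t for t in self.transcripts if t.id not in self.target_ids]

    def target_isoforms(self) -> list[NucSequence]:
        return [t for t in self.transcripts if t.id in self.target_ids]


class KmerIndex:
    """Exact-membership index over all length-k substrings of the
    non-target transcripts.

    ``query(s)`` answers "does any non-target transcript contain s?" and is
    defined only for ``len(s) == k``.  Behaviour is equivalent to
    brute-force substring search over the same transcripts.
    """

    def __init__(self, k: int, kmers: Iterable[str], transcripts: Sequence[NucSequence] = ()):
        self.k = k
        self._kmers = frozenset(kmers)
        # kept so callers can run the exact (LCS-based) scan on demand
        self.transcripts = list(transcripts)

    def __len__(self) -> int:
        return len(self._kmers)

    def query(self, s: str) -> bool:
        if len(s) != self.k:
            raise ValueError(f"query length {len(s)} != index k {self.k}")
        return s in self._kmers


def _iter_kmers(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def build_kmer_index(transcriptome: Transcriptome) -> KmerIndex:
    """Index every k-mer of every non-target transcript.

    Transcripts shorter than k contribute nothing; an empty transcriptome
    yields an empty index (all queries false).
    """
    k = transcriptome.k
    kmers: set[str] = set()
    decoys = transcriptome.non_target_transcripts()
    for t in decoys:
        kmers.update(_iter_kmers(t.seq, k))
    return KmerIndex(k, kmers, decoys)


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous substring shared by ``a`` and ``b``.

    This is the oracle defining "k nt complementarity" as a contiguous
    exact match: a guide window has LCS > 15 against a transcript iff it
    shares a 16-mer with it.  Symmetric in its arguments; 0 if nothing is
    shared.  Dynamic programming vectorised along ``b``.
    """
    if not a or not b:
        raise ValueError("both strings must be non-empty")
    if len(a) > len(b):
        a, b = b, a
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(len(bv), dtype=np.int32)
    cur = np.zeros(len(bv), dtype=np.int32)
    best = 0
    for ch in a.encode("ascii"):
        match = bv == ch
        cur[:] = 0
        cur[match] = 1
        ext = match[1:]
        cur[1:][ext] += prev[:-1][ext]
        m = int(cur.max())
        if m > best:
            best = m
        prev, cur = cur, prev
    return best


def read_fasta(path: str | os.PathLike, allow_n: bool = False) -> list[NucSequence]:
    """Read a multi-record FASTA file (wrapped or unwrapped lines).

    The identifier is the first whitespace-delimited token of the header.
    Lowercase residues are upper-cased; anything outside {A,C,G,T}
    (plus N when ``allow_n``) raises :class:`AlphabetError`.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        records.append(NucSequence(rec.id, str(rec.seq).upper(), allow_n=allow_n))
    return records


def write_fasta(records: Iterable[NucSequence], path: str | os.PathLike, width: int = 70) -> None:
    """Write records as wrapped FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def to_seqrecord(rec: NucSequence) -> SeqRecord:
    """Convert to a Biopython SeqRecord (for GenBank export etc.)."""
    return SeqRecord(Seq(rec.seq), id=rec.id, description="")
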