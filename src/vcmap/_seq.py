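"""Nucleotide-string helpers shared by the index, mapper and simulator.

All sequences are plain upper-case Python strings over {A,C,G,T,N,...}.
Only A/C/G/T are indexable; anything else splits a reference into contigs.
"""

from __future__ import annotations

import re
from typing import Iterator

_RC_TABLE = str.maketrans("ACGT", "TGCA")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

VALID_BASES = frozenset("ACGT")

_CONTIG_RE = re.compile(r"[ACGT]+")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_RC_TABLE)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_RC_TABLE)[::-1]
    return kmer if kmer <= rc else rc


def is_valid(seq: str) -> bool:
    return not (set(seq) - VALID_BASES)


def split_contigs(seq: str) -> Iterator[tuple[int, str]]:
    """Yield (offset, subsequence) for maximal runs of A/C/G/T.

    k-mers never span a non-ACGT character, so indexing operates on these
    contigs while all reported coordinates stay on the full reference.
    """
    for m in _CONTIG_RE.finditer(seq):
        yield m.start(), m.group()
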