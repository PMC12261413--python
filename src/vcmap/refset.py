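"""Reference sequence container and FASTA I/O.

A :class:`ReferenceSet` holds the named genomic sequences that form the
color universe of the index; the order of appearance defines the integer
reference ids 0..N-1 used everywhere downstream (mapping records, BED
sorting order).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file by suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class ReferenceSet:
    """Named nucleotide sequences; order defines reference ids.

    Attributes
    ----------
    names:
        Unique reference identifiers, in input order.
    seqs:
        Upper-case nucleotide strings (A/C/G/T/N and IUPAC codes allowed;
        only A/C/G/T is indexable).
    """

    names: list[str]
    seqs: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("reference names must be unique")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.seqs]

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.seqs))

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "ReferenceSet":
        return cls(list(d.keys()), list(d.values()))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        names: list[str] = []
        seqs: list[str] = []
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                names.append(rec.id)
                seqs.append(str(rec.seq).upper())
        if not names:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(names, seqs)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with _open_text(path, "wt") as fh:
            for name, seq in self:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read a (possibly gzipped) multi-record FASTA into a ReferenceSet."""
    return ReferenceSet.from_fasta(path)


def write_fasta(refs: ReferenceSet | Iterable[tuple[str, str]], path: str | Path) -> None:
    if not isinstance(refs, ReferenceSet):
        pairs = list(refs)
        refs = ReferenceSet([n for n, _ in pairs], [s for _, s in pairs])
    refs.to_fasta(path)
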