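"""File-level I/O: FASTQ triples (10x scATAC layout) and mapping streams.

The 10x single-cell ATAC layout ships three synchronized FASTQ files:
R1 = genomic mate 1, R2 = the 16-base cell barcode read, R3 = genomic
mate 2.  The mapper's intermediate output is a documented TSV stream
(one mapped fragment per line: pair name, raw barcode, reference id,
start, end, mate-1 orientation) headed by the reference-name table so
that downstream sorting knows the FASTA order; it stands in for a
binary reduced-alignment format, which is out of scope here.
"""

from __future__ import annotations

from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .fragments import FragmentRecord
from .refset import _open_text

_MAPPINGS_MAGIC = "#vcmap-mappings"
_MAPPINGS_VERSION = 1


def read_fastq_triple(
    r1_path: str | Path,
    r2_path: str | Path,
    r3_path: str | Path,
) -> Iterator[tuple[str, str, str, str]]:
    """Yield (name, mate1, barcode, mate2) from synchronized FASTQ files.

    Raises on length mismatch between the three files or on read-name
    disagreement (first whitespace-delimited token, ignoring a trailing
    /1 /2 /3 suffix).
    """
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2, _open_text(r3_path) as f3:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        it3 = FastqGeneralIterator(f3)
        for i, (rec1, rec2, rec3) in enumerate(zip_longest(it1, it2, it3)):
            if rec1 is None or rec2 is None or rec3 is None:
                raise ValueError(
                    f"FASTQ files out of sync at record {i}: unequal record counts"
                )
            names = []
            for title, _, _ in (rec1, rec2, rec3):
                name = title.split()[0]
                if name[-2:] in ("/1", "/2", "/3"):
                    name = name[:-2]
                names.append(name)
            if len(set(names)) != 1:
                raise ValueError(f"read-name mismatch at record {i}: {names}")
            yield names[0], rec1[1].upper(), rec2[1].upper(), rec3[1].upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    with _open_text(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_mappings(
    records: Iterable[FragmentRecord],
    ref_names: list[str],
    path: str | Path,
) -> int:
    """Write the intermediate mapped-fragment TSV stream; returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        fh.write(f"{_MAPPINGS_MAGIC}\tv{_MAPPINGS_VERSION}\n")
        fh.write("#refs\t" + "\t".join(ref_names) + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")
            n += 1
    return n


def read_mappings(path: str | Path) -> tuple[list[str], list[FragmentRecord]]:
    """Read an intermediate mapping stream; returns (ref names, records)."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != _MAPPINGS_MAGIC:
            raise ValueError(f"{path}: not a vcmap mapping stream")
        refline = fh.readline().rstrip("\n").split("\t")
        if refline[0] != "#refs":
            raise ValueError(f"{path}: missing reference table")
        ref_names = refline[1:]
        records = []
        for lineno, line in enumerate(fh, 3):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                records.append(FragmentRecord.from_line(line))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
    return ref_names, records
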