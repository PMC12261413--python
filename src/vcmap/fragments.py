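"""Fragment post-processing: barcode correction, sorting, dedup, BED.

The mapper emits barcode-tagged genomic intervals.  This module corrects
raw cell barcodes against a permit list (exact match, else a unique
Hamming-distance-1 neighbour; an opt-in frequency policy breaks
ambiguous cases by observed exact-match counts), sorts fragments by
(reference order, start, end, barcode) — spilling sorted runs to disk
and k-way merging them when the input exceeds a chunk size — collapses
consecutive identical fragments into one BED line carrying the total
duplicate count (including the fragment itself), and reads/writes the
5-column fragment BED with 0-based half-open intervals.
"""

from __future__ import annotations

import heapq
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional

from .refset import _open_text

_BASES = "ACGT"


@dataclass
class FragmentRecord:
    """A mapped, barcode-tagged genomic interval (pre-deduplication)."""

    barcode: str
    ref: int            # reference id (FASTA appearance order)
    start: int
    end: int
    forward: bool       # orientation of mate 1
    name: str = ""      # pair id, kept for truth joining / diagnostics

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate interval [{self.start}, {self.end})")

    def sort_key(self) -> tuple:
        return (self.ref, self.start, self.end, self.barcode)

    def to_line(self) -> str:
        ori = "f" if self.forward else "r"
        return f"{self.name}\t{self.barcode}\t{self.ref}\t{self.start}\t{self.end}\t{ori}"

    @classmethod
    def from_line(cls, line: str) -> "FragmentRecord":
        name, bc, ref, start, end, ori = line.rstrip("\n").split("\t")
        return cls(
            barcode=bc,
            ref=int(ref),
            start=int(start),
            end=int(end),
            forward=ori == "f",
            name=name,
        )


class BedRecord(NamedTuple):
    """One line of the deduplicated fragment file."""

    ref_name: str
    start: int
    end: int
    barcode: str
    count: int          # total duplicates, including the fragment itself


class PermitList:
    """Fixed-length cell-barcode whitelist."""

    def __init__(self, barcodes: Iterable[str]):
        self._set = {bc.strip().upper() for bc in barcodes if bc.strip()}
        if not self._set:
            raise ValueError("empty permit list")
        lengths = {len(bc) for bc in self._set}
        if len(lengths) != 1:
            raise ValueError(f"permit-list barcodes have mixed lengths: {sorted(lengths)}")
        (self.barcode_length,) = lengths

    @classmethod
    def from_file(cls, path: str | Path) -> "PermitList":
        with _open_text(path) as fh:
            return cls(fh)

    def __contains__(self, bc: str) -> bool:
        return bc in self._set

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(sorted(self._set))


def _hamming1_neighbors(bc: str) -> Iterator[str]:
    for i, ch in enumerate(bc):
        for b in _BASES:
            if b != ch:
                yield bc[:i] + b + bc[i + 1 :]


def correct_barcode(
    bc: str,
    permit: PermitList,
    policy: str = "unique",
    counts: Optional[dict[str, int]] = None,
) -> Optional[str]:
    """Correct a raw barcode against the permit list, or return None.

    An exact member is returned as-is.  Otherwise the Hamming-distance-1
    neighbourhood is searched: a unique candidate is accepted; with zero
    or several candidates the default ``unique`` policy drops the
    barcode.  The ``frequency`` policy instead resolves multi-candidate
    cases in favour of the candidate with the strictly highest
    exact-match count observed in the run (``counts``); ties still drop.
    """
    if policy not in ("unique", "frequency"):
        raise ValueError(f"unknown barcode policy {policy!r}")
    if len(bc) != permit.barcode_length:
        return None
    if bc in permit:
        return bc
    candidates = [nb for nb in _hamming1_neighbors(bc) if nb in permit]
    if len(candidates) == 1:
        return candidates[0]
    if len(candidates) >= 2 and policy == "frequency" and counts is not None:
        ranked = sorted(candidates, key=lambda c: counts.get(c, 0), reverse=True)
        if counts.get(ranked[0], 0) > counts.get(ranked[1], 0):
            return ranked[0]
    return None


def sort_fragments(
    records: Iterable[FragmentRecord],
    chunk_size: Optional[int] = None,
) -> Iterator[FragmentRecord]:
    """Sort fragments by (reference order, start, end, barcode).

    With ``chunk_size`` set, sorted runs of that many records are spilled
    to temporary files and k-way merged, so the result is identical to an
    in-memory sort while holding only one chunk in memory.
    """
    key = FragmentRecord.sort_key
    if chunk_size is None:
        yield from sorted(records, key=key)
        return
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    run_paths: list[str] = []
    chunk: list[FragmentRecord] = []

    def spill() -> None:
        chunk.sort(key=key)
        fd, path = tempfile.mkstemp(prefix="vcmap-sort-", suffix=".tsv")
        with os.fdopen(fd, "w") as fh:
            for r in chunk:
                fh.write(r.to_line() + "\n")
        run_paths.append(path)
        chunk.clear()

    for rec in records:
        chunk.append(rec)
        if len(chunk) >= chunk_size:
            spill()

    if not run_paths:  # everything fit in one chunk
        chunk.sort(key=key)
        yield from chunk
        return
    if chunk:
        spill()

    def read_run(path: str) -> Iterator[FragmentRecord]:
        with open(path) as fh:
            for line in fh:
                yield FragmentRecord.from_line(line)

    try:
        yield from heapq.merge(*(read_run(p) for p in run_paths), key=key)
    finally:
        for p in run_paths:
            try:
                os.unlink(p)
            except OSError:
                pass


def dedup_fragments(
    sorted_records: Iterable[FragmentRecord],
    ref_names: list[str],
) -> Iterator[BedRecord]:
    """Collapse consecutive identical fragments into counted BED records.

    Requires the input to be sorted by (ref, start, end, barcode);
    an out-of-order record raises.  The duplicate counts over the output
    sum to the number of input records.
    """
    prev_key: Optional[tuple] = None
    cur: Optional[FragmentRecord] = None
    count = 0
    for rec in sorted_records:
        k = rec.sort_key()
        if prev_key is not None and k < prev_key:
            raise ValueError(f"input not sorted: {k} after {prev_key}")
        if k == prev_key:
            count += 1
        else:
            if cur is not None:
                yield BedRecord(ref_names[cur.ref], cur.start, cur.end, cur.barcode, count)
            cur = rec
            count = 1
            prev_key = k
    if cur is not None:
        yield BedRecord(ref_names[cur.ref], cur.start, cur.end, cur.barcode, count)


def write_bed(records: Iterable[BedRecord], path: str | Path) -> int:
    """Write the 5-column fragment BED (0-based half-open); returns line count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.ref_name}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")
            n += 1
    return n


def read_bed(path: str | Path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            name, start, end, bc, count = fields
            try:
                start_i, end_i, count_i = int(start), int(end), int(count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate/count") from exc
            if start_i < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start_i}")
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: empty interval [{start_i}, {end_i})")
            if count_i < 1:
                raise ValueError(f"{path}:{lineno}: duplicate count must be >= 1")
            out.append(BedRecord(name, start_i, end_i, bc, count_i))
    return out


@dataclass
class ProcessStats:
    n_input: int = 0
    n_corrected: int = 0          # fragments whose barcode passed/was corrected
    n_dropped_barcode: int = 0    # dropped by ambiguous/failed correction
    n_length_mismatch: int = 0    # dropped: barcode length != permit length
    n_bed_records: int = 0
    n_dup_total: int = 0          # sum of BED counts (== n_corrected)

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def process_fragments(
    records: Iterable[FragmentRecord],
    permit: PermitList,
    ref_names: list[str],
    *,
    policy: str = "unique",
    chunk_size: Optional[int] = None,
    tn5_shift: bool = False,
) -> tuple[list[BedRecord], ProcessStats]:
    """Full post-processing: correct barcodes, sort, dedup.

    ``tn5_shift`` applies the conventional +4/-5 transposase-offset
    adjustment to fragment ends (off by default).  The conservation
    identity ``n_input == n_corrected + dropped`` and
    ``sum(counts) == n_corrected`` always holds.
    """
    stats = ProcessStats()
    counts: Optional[dict[str, int]] = None
    if policy == "frequency":
        records = list(records)
        counts = {}
        for r in records:
            if r.barcode in permit:
                counts[r.barcode] = counts.get(r.barcode, 0) + 1

    def corrected() -> Iterator[FragmentRecord]:
        for r in records:
            stats.n_input += 1
            if len(r.barcode) != permit.barcode_length:
                stats.n_length_mismatch += 1
                continue
            bc = correct_barcode(r.barcode, permit, policy, counts)
            if bc is None:
                stats.n_dropped_barcode += 1
                continue
            stats.n_corrected += 1
            start, end = r.start, r.end
            if tn5_shift:
                start, end = start + 4, end - 5
                if start >= end:
                    start, end = r.start, r.end  # too short to shift; keep as-is
            yield FragmentRecord(bc, r.ref, start, end, r.forward, r.name)

    bed = list(dedup_fragments(sort_fragments(corrected(), chunk_size), ref_names))
    stats.n_bed_records = len(bed)
    stats.n_dup_total = sum(b.count for b in bed)
    return bed, stats
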