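"""Compacted de Bruijn graph index over a reference set.

The index stores three things, mirroring the structure of modern
unitig-based genome indexes:

* the unitig set — maximal non-branching paths of the canonical k-mer
  graph, each distinct canonical k-mer occurring at exactly one
  (unitig, offset);
* the K→U map — canonical k-mer -> (unitig id, offset, orientation);
* the U→R tiling — for each unitig, the list of its oriented occurrences
  on the references, such that stitching the occurrences of a reference
  (overlapping by k-1) reconstructs the reference over its non-N
  stretches.

Composing K→U with U→R answers "where does this k-mer sit on the genome",
which is the primitive the virtual-color mapper is built on.

Coordinates are 0-based throughout; orientation is a boolean ``forward``
(True = the sequence as written matches the unitig/reference forward
strand), rendered as ``f``/``r`` only at text boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

from ._seq import VALID_BASES, canonical, revcomp, split_contigs
from .refset import ReferenceSet, _open_text

_BASES = "ACGT"

_INDEX_MAGIC = "#vcmap-index"
_INDEX_VERSION = 1


class KmerUnitigEntry(NamedTuple):
    """K→U record: where a k-mer sits inside its unitig.

    ``forward`` is relative to the k-mer the caller asked about (for the
    stored table, relative to the canonical form).
    """

    unitig: int
    offset: int
    forward: bool


class RefOccurrence(NamedTuple):
    """U→R record: one oriented occurrence of a unitig on a reference."""

    ref: int
    pos: int
    forward: bool


@dataclass
class DbgIndex:
    k: int
    names: list[str]
    lengths: list[int]
    unitigs: list[str] = field(repr=False)
    k2u: dict[str, KmerUnitigEntry] = field(repr=False)
    u2r: list[list[RefOccurrence]] = field(repr=False)

    @property
    def n_kmers(self) -> int:
        return len(self.k2u)

    @property
    def n_unitigs(self) -> int:
        return len(self.unitigs)

    @property
    def unitig_lengths(self) -> list[int]:
        return [len(u) for u in self.unitigs]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DbgIndex):
            return NotImplemented
        return (
            self.k == other.k
            and self.names == other.names
            and self.lengths == other.lengths
            and self.unitigs == other.unitigs
            and self.k2u == other.k2u
            and self.u2r == other.u2r
        )


def _oriented_succs(s: str, kmers: dict) -> list[str]:
    """Successor k-mers of an oriented k-mer present in the canonical set."""
    suf = s[1:]
    out = []
    for b in _BASES:
        t = suf + b
        if canonical(t) in kmers:
            out.append(t)
    return out


def _oriented_preds(s: str, kmers: dict) -> list[str]:
    pre = s[:-1]
    out = []
    for b in _BASES:
        t = b + pre
        if canonical(t) in kmers:
            out.append(t)
    return out


def _build_unitigs(kmers: dict, k: int) -> list[str]:
    """Compact the canonical k-mer set into maximal non-branching paths.

    A unitig extends from an oriented k-mer to its unique successor as
    long as that successor has a unique predecessor; ends of contigs,
    branch nodes and already-placed k-mers terminate the walk.  Isolated
    cycles (every node with in/out degree one) are swept up afterwards
    from an arbitrary, deterministic entry point.
    """
    visited: set[str] = set()
    unitigs: list[str] = []

    def walk(s0: str) -> str:
        chars = [s0]
        cur = s0
        while True:
            nxt = _oriented_succs(cur, kmers)
            if len(nxt) != 1:
                break
            nx = nxt[0]
            if len(_oriented_preds(nx, kmers)) != 1:
                break
            cn = canonical(nx)
            if cn in visited:
                break
            visited.add(cn)
            chars.append(nx[-1])
            cur = nx
        return "".join(chars)

    for c in kmers:
        if c in visited:
            continue
        for s0 in (c, revcomp(c)):
            preds = _oriented_preds(s0, kmers)
            extendable_back = (
                len(preds) == 1
                and len(_oriented_succs(preds[0], kmers)) == 1
                and canonical(preds[0]) != c
            )
            if extendable_back:
                continue
            visited.add(c)
            unitigs.append(walk(s0))
            break

    # isolated cycles: nothing qualified as a start
    for c in kmers:
        if c not in visited:
            visited.add(c)
            unitigs.append(walk(c))

    return unitigs


def build_index(
    refs: ReferenceSet | dict[str, str],
    k: int = 25,
    *,
    allow_small_k: bool = False,
    verify: bool = False,
) -> DbgIndex:
    """Build the compacted de Bruijn graph index for a reference set.

    Parameters
    ----------
    refs:
        Reference sequences (a :class:`ReferenceSet` or name->sequence dict).
    k:
        k-mer length.  Odd k >= 15 required; smaller or even values are
        refused unless ``allow_small_k`` is set (even k admits palindromic
        k-mers whose strand is ambiguous — acceptable for toy inputs only).
    verify:
        Re-check the tiling-reconstruction invariant after construction.
    """
    if isinstance(refs, dict):
        refs = ReferenceSet.from_dict(refs)
    if len(refs) == 0:
        raise ValueError("empty reference set")
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    if k % 2 == 0 or k < 15:
        if not allow_small_k:
            reason = "even k admits palindromes" if k % 2 == 0 else "k < 15"
            raise ValueError(
                f"refusing k={k} ({reason}); pass allow_small_k=True to override"
            )
        warnings.warn(f"k={k} is below the supported range; proceeding as requested")

    # ---- enumerate canonical k-mers (dict doubles as an ordered set)
    kmers: dict[str, None] = {}
    any_indexable = False
    for _, seq in refs:
        for _, contig in split_contigs(seq):
            n = len(contig)
            if n < k:
                continue
            any_indexable = True
            rc_contig = revcomp(contig)
            for i in range(n - k + 1):
                km = contig[i : i + k]
                rkm = rc_contig[n - k - i : n - i]
                canon = km if km <= rkm else rkm
                if canon not in kmers:
                    kmers[canon] = None
    if not any_indexable:
        raise ValueError(f"no reference contains a non-N stretch of length >= k={k}")

    # ---- compaction
    unitigs = _build_unitigs(kmers, k)

    # ---- K→U table (canonical-relative orientation)
    k2u: dict[str, KmerUnitigEntry] = {}
    for uid, u in enumerate(unitigs):
        lu = len(u)
        ru = revcomp(u)
        for p in range(lu - k + 1):
            km = u[p : p + k]
            rkm = ru[lu - k - p : lu - p]
            fwd = km <= rkm
            canon = km if fwd else rkm
            if canon in k2u:
                raise AssertionError(
                    f"k-mer {canon} placed twice during compaction (unitigs "
                    f"{k2u[canon].unitig} and {uid})"
                )
            k2u[canon] = KmerUnitigEntry(uid, p, fwd)
    if len(k2u) != len(kmers):
        raise AssertionError("unitig set does not cover the k-mer set exactly")

    # ---- U→R tiling
    u2r: list[list[RefOccurrence]] = [[] for _ in unitigs]
    for ref_id, (_, seq) in enumerate(refs):
        for coff, contig in split_contigs(seq):
            n = len(contig)
            if n < k:
                continue
            i = 0
            while i <= n - k:
                km = contig[i : i + k]
                canon = canonical(km)
                uid, p, cfwd = k2u[canon]
                qfwd = km == canon
                lu = len(unitigs[uid])
                if cfwd == qfwd:  # unitig occurs forward here
                    u2r[uid].append(RefOccurrence(ref_id, coff + i - p, True))
                    i += (lu - k - p) + 1
                else:  # unitig occurs reverse-complemented
                    pr = lu - k - p  # offset of km within revcomp(unitig)
                    u2r[uid].append(RefOccurrence(ref_id, coff + i - pr, False))
                    i += p + 1

    index = DbgIndex(
        k=k,
        names=list(refs.names),
        lengths=refs.lengths,
        unitigs=unitigs,
        k2u=k2u,
        u2r=u2r,
    )
    if verify:
        _verify_tiling(index, refs)
    return index


def _verify_tiling(index: DbgIndex, refs: ReferenceSet) -> None:
    """Assert that stitching each reference's unitig occurrences reproduces it."""
    k = index.k
    per_ref: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(refs))}
    for uid, occs in enumerate(index.u2r):
        u = index.unitigs[uid]
        for ref, pos, fwd in occs:
            per_ref[ref].append((pos, u if fwd else revcomp(u)))
    for ref_id, (_, seq) in enumerate(refs):
        for pos, useq in sorted(per_ref[ref_id]):
            if seq[pos : pos + len(useq)] != useq:
                raise AssertionError(
                    f"tiling mismatch on {refs.names[ref_id]} at {pos}"
                )
        # coverage of non-N stretches
        covered = bytearray(len(seq))
        for pos, useq in per_ref[ref_id]:
            for j in range(pos, pos + len(useq)):
                covered[j] = 1
        for coff, contig in split_contigs(seq):
            if len(contig) < k:
                continue
            if not all(covered[coff : coff + len(contig)]):
                raise AssertionError(
                    f"tiling gap on {refs.names[ref_id]} contig at {coff}"
                )


def lookup_kmer(index: DbgIndex, kmer: str) -> Optional[KmerUnitigEntry]:
    """K→U lookup; orientation reported relative to the queried k-mer.

    Non-ACGT or wrong-length queries return ``None``, never raise.
    """
    if len(kmer) != index.k or (set(kmer) - VALID_BASES):
        return None
    canon = canonical(kmer)
    e = index.k2u.get(canon)
    if e is None:
        return None
    qfwd = e.forward if kmer == canon else not e.forward
    return KmerUnitigEntry(e.unitig, e.offset, qfwd)


def kmer_positions(index: DbgIndex, kmer: str) -> list[tuple[int, int, bool]]:
    """All (ref id, 0-based position, orientation) occurrences of a k-mer.

    Composes K→U with U→R.  Orientation is the queried k-mer's strand
    relative to the reference forward strand.  Sorted by (ref, pos).
    """
    e = lookup_kmer(index, kmer)
    if e is None:
        return []
    uid, p, qfwd = e
    lu = len(index.unitigs[uid])
    k = index.k
    out = []
    for ref, rpos, ofwd in index.u2r[uid]:
        if ofwd:
            out.append((ref, rpos + p, qfwd))
        else:
            out.append((ref, rpos + lu - k - p, not qfwd))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# serialization: versioned plain-text container (gzip by suffix)
# ---------------------------------------------------------------------------

def save_index(index: DbgIndex, path: str | Path) -> None:
    """Serialize the index.

    Layout (tab-separated, text, optionally gzipped):
    a magic+version header, ``k``, the reference table, the unitig
    sequences and the U→R occurrence list.  The K→U table is not stored:
    it is a pure function of the unitig set and is rebuilt on load, which
    keeps the container small while save/load round trips compare equal.
    """
    with _open_text(path, "wt") as fh:
        fh.write(f"{_INDEX_MAGIC}\tv{_INDEX_VERSION}\n")
        fh.write(f"k\t{index.k}\n")
        fh.write(f"refs\t{len(index.names)}\n")
        for name, length in zip(index.names, index.lengths):
            fh.write(f"{name}\t{length}\n")
        fh.write(f"unitigs\t{len(index.unitigs)}\n")
        for u in index.unitigs:
            fh.write(u + "\n")
        n_occ = sum(len(o) for o in index.u2r)
        fh.write(f"occurrences\t{n_occ}\n")
        for uid, occs in enumerate(index.u2r):
            for ref, pos, fwd in occs:
                fh.write(f"{uid}\t{ref}\t{pos}\t{'f' if fwd else 'r'}\n")


def load_index(path: str | Path) -> DbgIndex:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != _INDEX_MAGIC or header[1] != f"v{_INDEX_VERSION}":
            raise ValueError(f"{path}: not a vcmap index (header {header!r})")
        tag, kval = fh.readline().split("\t")
        assert tag == "k"
        k = int(kval)
        tag, nref = fh.readline().split("\t")
        assert tag == "refs"
        names, lengths = [], []
        for _ in range(int(nref)):
            name, length = fh.readline().rstrip("\n").split("\t")
            names.append(name)
            lengths.append(int(length))
        tag, nuni = fh.readline().split("\t")
        assert tag == "unitigs"
        unitigs = [fh.readline().rstrip("\n") for _ in range(int(nuni))]
        tag, nocc = fh.readline().split("\t")
        assert tag == "occurrences"
        u2r: list[list[RefOccurrence]] = [[] for _ in unitigs]
        for _ in range(int(nocc)):
            uid, ref, pos, ori = fh.readline().rstrip("\n").split("\t")
            u2r[int(uid)].append(RefOccurrence(int(ref), int(pos), ori == "f"))

    k2u: dict[str, KmerUnitigEntry] = {}
    for uid, u in enumerate(unitigs):
        lu = len(u)
        ru = revcomp(u)
        for p in range(lu - k + 1):
            km = u[p : p + k]
            rkm = ru[lu - k - p : lu - p]
            fwd = km <= rkm
            k2u[km if fwd else rkm] = KmerUnitigEntry(uid, p, fwd)
    return DbgIndex(k=k, names=names, lengths=lengths, unitigs=unitigs, k2u=k2u, u2r=u2r)
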