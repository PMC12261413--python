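"""Threshold-union pseudoalignment over virtual colors.

A mate maps to a virtual color when at least τ·|K(Q)| of its
index-matched k-mers (K(Q)) support that color in a consistent
orientation.  The reported position is the reference position of the
leftmost-in-read supporting k-mer (smallest coordinate within the bin if
it occurs several times) minus that k-mer's offset in the read.  Mates
are then deduplicated (overlap regions assign two colors to one
position), merged under orientation/dovetail/insert-size constraints and
filtered down to the best-supported mapping(s); only pairs with a unique
survivor yield a fragment.

k-mer lookups go through a streaming query that walks along the current
unitig and only falls back to the index at unitig junctions, plus a
write-once cache of terminal k-mers.  Both are pure optimizations: output
is identical with them on or off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

from ._seq import COMPLEMENT, VALID_BASES, revcomp
from .dbg import DbgIndex, KmerUnitigEntry, lookup_kmer
from .fragments import FragmentRecord
from .vcolor import VirtualColorScheme


class MappingInvariantError(RuntimeError):
    """An internal guarantee of the mapping procedure was violated."""


class MappedHit(NamedTuple):
    """Candidate mapping of a single mate to one virtual color."""

    ref: int          # reference id
    pos: int          # inferred 0-based read start on the reference
    forward: bool     # read orientation relative to the reference
    vid: int          # virtual color id
    support: int      # k-mers supporting this (vid, orientation)
    kq: int           # |K(Q)| for this mate


class MergedMapping(NamedTuple):
    """Candidate fragment from merging one hit of each mate."""

    ref: int
    start: int
    end: int
    forward: bool     # orientation of mate 1
    fraction: float   # (support1 + support2) / (kq1 + kq2)


@dataclass
class MapParams:
    """Mapping parameters; the defaults are the best-accuracy setting
    (k=25, τ=0.7, ℓvcol=1000) with dovetail/insert bounds of 20/1000."""

    tau: float = 0.7
    k: int = 25
    bin_length: int = 1000
    ov_length: int = 150
    dovetail_max: int = 20
    insert_max: int = 1000
    cache_capacity: int = 5_000_000
    streaming: bool = True
    use_cache: bool = True
    premerge: bool = False  # optional pre-mapping mate merge (off by default)

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")


class TerminalKmerCache:
    """Write-once, fixed-capacity cache of terminal-k-mer lookups.

    Keys are canonical k-mers at unitig boundaries; values are the index's
    own K→U entries, so a hit is exactly a memoized index lookup and cache
    presence can never change mapping output.  An existing entry is never
    replaced, and nothing is inserted once ``capacity`` is reached.
    """

    def __init__(self, capacity: int = 5_000_000):
        if capacity < 0:
            raise ValueError("capacity must be non-negative")
        self.capacity = capacity
        self._map: dict[str, KmerUnitigEntry] = {}
        self.hits = 0
        self.misses = 0

    def get(self, key: str) -> Optional[KmerUnitigEntry]:
        e = self._map.get(key)
        if e is None:
            self.misses += 1
        else:
            self.hits += 1
        return e

    def insert(self, key: str, value: KmerUnitigEntry) -> None:
        if key not in self._map and len(self._map) < self.capacity:
            self._map[key] = value

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, key: str) -> bool:
        return key in self._map

    def items(self):
        return self._map.items()


def query_kmers(index: DbgIndex, seq: str) -> list[Optional[KmerUnitigEntry]]:
    """One independent K→U lookup per read k-mer (reference path)."""
    k = index.k
    if len(seq) < k:
        return []
    return [lookup_kmer(index, seq[i : i + k]) for i in range(len(seq) - k + 1)]


def query_kmers_streaming(
    index: DbgIndex,
    seq: str,
    cache: Optional[TerminalKmerCache] = None,
) -> list[Optional[KmerUnitigEntry]]:
    """Per-k-mer K→U entries via unitig extension, equal to naive lookups.

    While the previous k-mer sits inside a unitig with distance > 0 to its
    end, the next entry is produced by comparing the read's next base with
    the next base of the unitig — no index access.  When the previous
    k-mer was terminal (distance 0), the current k-mer starts a new unitig:
    the terminal-k-mer cache is consulted first and populated on a
    successful index lookup.  Mismatching extensions and k-mers containing
    non-ACGT characters fall back to a full query / an empty slot and
    reset the state.
    """
    k = index.k
    n = len(seq)
    if n < k:
        return []
    m = n - k + 1
    slots: list[Optional[KmerUnitigEntry]] = [None] * m
    k2u = index.k2u
    unitigs = index.unitigs

    bad = [j for j, ch in enumerate(seq) if ch not in VALID_BASES]
    bad_idx = 0  # index into `bad` of the first invalid position >= window start

    rseq = revcomp(seq) if not bad else None

    state: Optional[tuple[int, int, bool, int]] = None  # uid, off, fwd, dist_to_end
    prev_at_end = False

    for i in range(m):
        # --- validity of window [i, i+k)
        while bad_idx < len(bad) and bad[bad_idx] < i:
            bad_idx += 1
        if bad_idx < len(bad) and bad[bad_idx] < i + k:
            state = None
            prev_at_end = False
            continue

        entry: Optional[KmerUnitigEntry] = None
        if state is not None:
            uid, off, fwd, dist = state
            u = unitigs[uid]
            if fwd:
                if seq[i + k - 1] == u[off + k]:
                    entry = KmerUnitigEntry(uid, off + 1, True)
            else:
                if seq[i + k - 1] == COMPLEMENT[u[off - 1]]:
                    entry = KmerUnitigEntry(uid, off - 1, False)

        if entry is None:
            # full query (cache-assisted when crossing a unitig boundary)
            km = seq[i : i + k]
            if rseq is not None:
                rkm = rseq[m - 1 - i : m - 1 - i + k]
            else:
                rkm = revcomp(km)
            canon = km if km <= rkm else rkm
            ce: Optional[KmerUnitigEntry] = None
            if prev_at_end and cache is not None:
                ce = cache.get(canon)
                if ce is None:
                    ce = k2u.get(canon)
                    if ce is not None:
                        cache.insert(canon, ce)
            else:
                ce = k2u.get(canon)
            if ce is not None:
                qfwd = ce.forward if km == canon else not ce.forward
                entry = KmerUnitigEntry(ce.unitig, ce.offset, qfwd)

        if entry is None:
            slots[i] = None
            state = None
            prev_at_end = False
            continue

        slots[i] = entry
        uid, off, fwd = entry
        dist = (len(unitigs[uid]) - k - off) if fwd else off
        state = (uid, off, fwd, dist) if dist > 0 else None
        prev_at_end = dist == 0

    return slots


def pseudoalign_mate(
    index: DbgIndex,
    scheme: VirtualColorScheme,
    seq: str,
    params: MapParams,
    cache: Optional[TerminalKmerCache] = None,
) -> list[MappedHit]:
    """Threshold-union pseudoalignment of a single mate.

    Returns the hits whose (virtual color, orientation) support reaches
    τ·|K(Q)|, with inferred read-start positions.  An empty list means the
    mate is unmapped (including reads shorter than k or with K(Q) = ∅).
    """
    k = index.k
    if len(seq) < k:
        return []
    if params.streaming:
        slots = query_kmers_streaming(index, seq, cache if params.use_cache else None)
    else:
        slots = query_kmers(index, seq)

    u2r = index.u2r
    ulen = [len(u) for u in index.unitigs]
    lv = scheme.bin_length
    ov = scheme.ov_length
    cb = scheme.cb
    nbins = scheme.bins
    edge = lv - ov

    # (vid, ori) -> [support, last_kmer_counted, anchor_kmer, anchor_pos, ref]
    acc: dict[tuple[int, bool], list] = {}
    kq = 0
    for i, e in enumerate(slots):
        if e is None:
            continue
        kq += 1
        uid, off, fwd = e
        back = ulen[uid] - k - off
        for ref, rpos, ofwd in u2r[uid]:
            if ofwd:
                p = rpos + off
                ori = fwd
            else:
                p = rpos + back
                ori = not fwd
            b = p // lv
            vid = cb[ref] + b
            rec = acc.get((vid, ori))
            if rec is None:
                acc[(vid, ori)] = [1, i, i, p, ref]
            else:
                if rec[1] != i:
                    rec[0] += 1
                    rec[1] = i
                if rec[2] == i and p < rec[3]:
                    rec[3] = p
            if p % lv >= edge and b + 1 < nbins[ref]:
                vid2 = vid + 1
                rec = acc.get((vid2, ori))
                if rec is None:
                    acc[(vid2, ori)] = [1, i, i, p, ref]
                else:
                    if rec[1] != i:
                        rec[0] += 1
                        rec[1] = i
                    if rec[2] == i and p < rec[3]:
                        rec[3] = p

    if kq == 0:
        return []
    thr = params.tau * kq
    rl = len(seq)
    hits = []
    for (vid, ori), (s, _, ai, ap, ref) in acc.items():
        if s >= thr:
            # infer the read's start on the reference forward strand from the
            # leftmost-in-read supporting k-mer: that k-mer begins at read
            # offset ai, i.e. at reference offset ai (forward) or
            # rl - k - ai (reverse-complemented read) from the read start
            pos = (ap - ai) if ori else (ap + k + ai - rl)
            if pos < 0:
                pos = 0
            hits.append(MappedHit(ref, pos, ori, vid, s, kq))
    hits.sort(key=lambda h: (h.vid, not h.forward))
    return hits


def dedup_hits(hits: list[MappedHit]) -> list[MappedHit]:
    """Remove duplicate hits induced by the bin overlap.

    Hits equal on (orientation, reference, position) are duplicates; the
    one with the smaller virtual color id is kept.  The construction
    guarantees at most one duplicate per hit; larger groups indicate a
    broken invariant and raise.
    """
    best: dict[tuple[bool, int, int], MappedHit] = {}
    counts: dict[tuple[bool, int, int], int] = {}
    order: list[tuple[bool, int, int]] = []
    for h in hits:
        key = (h.forward, h.ref, h.pos)
        c = counts.get(key, 0) + 1
        counts[key] = c
        if c > 2:
            raise MappingInvariantError(
                f"duplicate group of size {c} at {key}; at most 2 expected"
            )
        cur = best.get(key)
        if cur is None:
            best[key] = h
            order.append(key)
        elif h.vid < cur.vid:
            best[key] = h
    return [best[key] for key in order]


def merge_mates(
    hits1: list[MappedHit],
    hits2: list[MappedHit],
    rl1: int,
    rl2: int,
    params: MapParams,
) -> list[MergedMapping]:
    """Merge deduplicated per-mate hits into candidate fragments.

    Mates must hit the same reference in adjacent-or-equal virtual colors
    with opposite orientations, and the forward mate must start no more
    than ``dovetail_max`` after and no more than ``insert_max`` before the
    reverse mate.  The fragment interval runs from the smaller start to
    the larger start plus that mate's read length.
    """
    dt = params.dovetail_max
    ins = params.insert_max
    out: list[MergedMapping] = []
    for a in hits1:
        for b in hits2:
            if a.ref != b.ref or a.forward == b.forward:
                continue
            if abs(a.vid - b.vid) > 1:
                continue
            d = (b.pos - a.pos) if a.forward else (a.pos - b.pos)
            if d < -dt or d > ins:
                continue
            if a.pos < b.pos:
                start, end = a.pos, b.pos + rl2
            elif b.pos < a.pos:
                start, end = b.pos, a.pos + rl1
            else:
                start, end = a.pos, a.pos + max(rl1, rl2)
            frac = (a.support + b.support) / (a.kq + b.kq)
            out.append(MergedMapping(a.ref, start, end, a.forward, frac))
    return out


def filter_best_support(merged: list[MergedMapping]) -> list[MergedMapping]:
    """Keep only the mapping(s) with the largest supporting k-mer fraction τ'."""
    if not merged:
        return []
    best = max(m.fraction for m in merged)
    return [m for m in merged if m.fraction == best]


# ---------------------------------------------------------------------------
# optional pre-mapping mate merge ("unified fragment"); off by default
# ---------------------------------------------------------------------------

def merge_read_pair(
    r1: str,
    r2: str,
    min_overlap: int = 20,
    max_mismatch: int = 2,
) -> Optional[str]:
    """Attempt a 3'-overlap merge of a read pair into a single fragment.

    Scans overlap lengths from the longest possible down to
    ``min_overlap`` and accepts the first with at most ``max_mismatch``
    mismatches between the end of mate 1 and the (reverse-complemented)
    start of mate 2.  Returns the merged sequence, or None.
    """
    rc2 = revcomp(r2)
    for olen in range(min(len(r1), len(rc2)), min_overlap - 1, -1):
        tail = r1[len(r1) - olen :]
        head = rc2[:olen]
        mism = sum(1 for x, y in zip(tail, head) if x != y)
        if mism <= max_mismatch:
            return r1 + rc2[olen:]
    return None


def _map_single_fragment(
    index: DbgIndex,
    scheme: VirtualColorScheme,
    seq: str,
    barcode: str,
    params: MapParams,
    cache: Optional[TerminalKmerCache],
) -> tuple[str, Optional[FragmentRecord]]:
    hits = dedup_hits(pseudoalign_mate(index, scheme, seq, params, cache))
    if not hits:
        return "unmapped", None
    best = max(h.support for h in hits)
    hits = [h for h in hits if h.support == best]
    if len(hits) != 1:
        return "multimapped", None
    h = hits[0]
    return "mapped", FragmentRecord(
        barcode=barcode, ref=h.ref, start=h.pos, end=h.pos + len(seq), forward=h.forward
    )


def map_pair(
    index: DbgIndex,
    scheme: VirtualColorScheme,
    r1: str,
    r2: str,
    barcode: str,
    params: MapParams,
    cache: Optional[TerminalKmerCache] = None,
) -> tuple[str, Optional[FragmentRecord]]:
    """Map a genomic read pair; returns (status, fragment-or-None).

    Status is one of ``mapped`` (exactly one merged mapping survived the
    best-support filter), ``multimapped`` (several equally supported
    survivors — discarded) or ``unmapped``.
    """
    if params.premerge:
        merged_seq = merge_read_pair(r1, r2)
        if merged_seq is not None:
            return _map_single_fragment(index, scheme, merged_seq, barcode, params, cache)
    h1 = dedup_hits(pseudoalign_mate(index, scheme, r1, params, cache))
    h2 = dedup_hits(pseudoalign_mate(index, scheme, r2, params, cache))
    if not h1 or not h2:
        return "unmapped", None
    merged = merge_mates(h1, h2, len(r1), len(r2), params)
    best = filter_best_support(merged)
    if not best:
        return "unmapped", None
    if len(best) > 1:
        return "multimapped", None
    m = best[0]
    return "mapped", FragmentRecord(
        barcode=barcode, ref=m.ref, start=m.start, end=m.end, forward=m.forward
    )


@dataclass
class MapStats:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0

    @property
    def mapping_rate(self) -> float:
        return self.mapped / self.total if self.total else 0.0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "mapped": self.mapped,
            "unmapped": self.unmapped,
            "multimapped": self.multimapped,
            "mapping_rate": self.mapping_rate,
        }


def map_pairs(
    index: DbgIndex,
    scheme: VirtualColorScheme,
    pairs: Iterable[tuple[str, str, str, str]],
    params: MapParams,
    cache: Optional[TerminalKmerCache] = None,
) -> tuple[list[FragmentRecord], MapStats]:
    """Map an iterable of (name, r1, barcode, r2) tuples.

    Returns the fragment records of uniquely mapped pairs (each carrying
    its pair name for downstream truth joining) and the run statistics.
    """
    if cache is None and params.use_cache and params.streaming:
        cache = TerminalKmerCache(params.cache_capacity)
    stats = MapStats()
    records: list[FragmentRecord] = []
    for name, r1, bc, r2 in pairs:
        stats.total += 1
        status, rec = map_pair(index, scheme, r1, r2, bc, params, cache)
        if status == "mapped":
            stats.mapped += 1
            rec.name = name
            records.append(rec)
        elif status == "multimapped":
            stats.multimapped += 1
        else:
            stats.unmapped += 1
    return records, stats
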