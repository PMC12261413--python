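"""Independent brute-force reference implementations used as test oracles.

Nothing here touches the de Bruijn graph: k-mer positions come from a
naive full-text scan of the genome, bin ids from first-principles
arithmetic on the reference lengths.  These deliberately re-derive the
threshold-union definition so the package's index-based path can be
checked against a literal reading of it.
"""

from __future__ import annotations

import math
from collections import defaultdict

_RC = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def scan_kmer_table(refs, k):
    """canonical k-mer -> [(ref, pos, canonical-is-forward)] by full scan."""
    table = defaultdict(list)
    for ref_id, (_, seq) in enumerate(refs):
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if set(km) - _VALID:
                continue
            r = rc(km)
            if km <= r:
                table[km].append((ref_id, i, True))
            else:
                table[r].append((ref_id, i, False))
    return table


def oracle_positions(table, kmer):
    """(ref, pos, orientation-relative-to-query), sorted by (ref, pos)."""
    if set(kmer) - _VALID:
        return []
    r = rc(kmer)
    canon = kmer if kmer <= r else r
    out = []
    for ref, p, cfwd in table.get(canon, []):
        out.append((ref, p, cfwd if kmer == canon else not cfwd))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


class OracleScheme:
    """Bin bookkeeping recomputed from scratch (no package imports)."""

    def __init__(self, lengths, bin_length, ov_length):
        self.lv = bin_length
        self.ov = ov_length
        self.lengths = list(lengths)
        self.bins = [math.ceil(L / bin_length) for L in lengths]
        self.cb = [0]
        for b in self.bins[:-1]:
            self.cb.append(self.cb[-1] + b)

    def vids(self, ref, pos):
        b = pos // self.lv
        vid = self.cb[ref] + b
        out = [vid]
        if pos % self.lv >= self.lv - self.ov and b + 1 < self.bins[ref]:
            out.append(vid + 1)
        return out


def oracle_pseudoalign(table, scheme: OracleScheme, seq, k, tau):
    """Literal threshold-union pseudoalignment over virtual colors.

    Returns the same (ref, pos, forward, vid, support, kq) tuples as
    ``pseudoalign_mate``, computed from the scan table.
    """
    n = len(seq)
    if n < k:
        return []
    supporters = defaultdict(set)      # (vid, ori) -> {kmer indices}
    anchor = {}                        # (vid, ori) -> (min kmer idx, min pos there)
    refs_of = {}
    kq = 0
    for i in range(n - k + 1):
        hits = oracle_positions(table, seq[i : i + k])
        if not hits:
            continue
        kq += 1
        for ref, p, ori in hits:
            for vid in scheme.vids(ref, p):
                key = (vid, ori)
                supporters[key].add(i)
                refs_of[key] = ref
                if key not in anchor or (i, p) < anchor[key]:
                    cur = anchor.get(key)
                    if cur is None or i < cur[0] or (i == cur[0] and p < cur[1]):
                        anchor[key] = (i, p)
    if kq == 0:
        return []
    out = []
    for key, idxs in supporters.items():
        support = len(idxs)
        if support >= tau * kq:
            vid, ori = key
            ai, ap = anchor[key]
            pos = (ap - ai) if ori else (ap + k + ai - n)
            out.append((refs_of[key], max(0, pos), ori, vid, support, kq))
    out.sort(key=lambda h: (h[3], not h[2]))
    return out
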