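"""Mapper: streaming query, threshold-union pseudoalignment, merging."""

from __future__ import annotations

import numpy as np
import pytest

from _oracle import OracleScheme, oracle_pseudoalign, scan_kmer_table
from conftest import random_refs

from vcmap import (
    MapParams,
    MappedHit,
    TerminalKmerCache,
    build_index,
    build_scheme,
    dedup_hits,
    filter_best_support,
    map_pair,
    map_pairs,
    merge_mates,
    merge_read_pair,
    pseudoalign_mate,
    query_kmers,
    query_kmers_streaming,
)
from vcmap.mapping import MappingInvariantError, MergedMapping
from vcmap._seq import revcomp
from vcmap.simulate import SimParams, make_genome, simulate_pairs


class CountingDict(dict):
    """Index table wrapper that counts full lookups."""

    lookups = 0

    def get(self, *a, **kw):
        CountingDict.lookups += 1
        return super().get(*a, **kw)


@pytest.fixture(scope="module")
def mapping_index():
    rng = np.random.default_rng(5)
    refs = random_refs(rng, [8000])
    return refs, build_index(refs, 25)


class TestStreamingQuery:
    def test_within_unitig_uses_one_index_query(self, mapping_index):
        refs, idx = mapping_index
        # pick a read fully inside one long unitig
        long_uid = max(range(idx.n_unitigs), key=lambda u: len(idx.unitigs[u]))
        u = idx.unitigs[long_uid]
        assert len(u) >= 60
        read = u[5:55]
        counted = CountingDict(idx.k2u)
        idx.k2u = counted
        try:
            CountingDict.lookups = 0
            slots = query_kmers_streaming(idx, read)
            assert CountingDict.lookups == 1  # 1 query + 25 extensions
        finally:
            idx.k2u = dict(counted)
        assert slots == query_kmers(idx, read)

    def test_junction_falls_back_to_full_query(self, mapping_index):
        refs, idx = mapping_index
        # a genomic read spanning >=2 unitigs still matches naive lookups
        seq = refs.seqs[0]
        occs = sorted(
            (occ.pos, uid) for uid, l in enumerate(idx.u2r) for occ in l
        )
        # read straddling the second unitig boundary on the reference
        if len(occs) > 1:
            boundary = occs[1][0]
            read = seq[max(0, boundary - 30) : boundary + 30]
        else:
            read = seq[:60]
        assert query_kmers_streaming(idx, read) == query_kmers(idx, read)

    def test_substitution_resets_state(self, mapping_index):
        refs, idx = mapping_index
        read = list(refs.seqs[0][1000:1080])
        read[40] = {"A": "C"}.get(read[40], "A")
        read = "".join(read)
        slots_s = query_kmers_streaming(idx, read)
        slots_n = query_kmers(idx, read)
        assert slots_s == slots_n
        assert any(s is None for s in slots_s)  # the error destroys k-mers

    def test_non_acgt_yields_empty_slots(self, mapping_index):
        refs, idx = mapping_index
        read = refs.seqs[0][:30] + "N" + refs.seqs[0][31:80]
        slots = query_kmers_streaming(idx, read)
        assert slots == query_kmers(idx, read)
        k = idx.k
        for i in range(len(read) - k + 1):
            if i <= 30 < i + k:
                assert slots[i] is None


class TestPseudoalign:
    def test_partial_duplicate_below_threshold(self):
        """5 k-mers hit one bin; 3 of them also hit a duplicated locus in an
        earlier bin; at tau=0.7 only the fully supported bin survives."""
        rng = np.random.default_rng(9)
        refs = random_refs(rng, [8000])
        s = list(refs.seqs[0])
        k = 15
        # copy the first 3 k-mers' span (k+2 bases) of the read at 5400 to 1400
        s[1400 : 1400 + k + 2] = s[5400 : 5400 + k + 2]
        refs = type(refs)(refs.names, ["".join(s)])
        idx = build_index(refs, k)
        scheme = build_scheme(idx.lengths, 1000, 100)
        read = refs.seqs[0][5400 : 5400 + k + 4]  # 5 k-mers
        hits = pseudoalign_mate(idx, scheme, read, MapParams(tau=0.7, k=k))
        assert [(h.vid, h.support, h.kq) for h in hits] == [(5, 5, 5)]
        # lowering tau exposes the duplicate as a second candidate
        hits_low = pseudoalign_mate(idx, scheme, read, MapParams(tau=0.5, k=k))
        assert {(h.vid, h.support) for h in hits_low} == {(5, 5), (1, 3)}

    def test_tau_one_survives_substitution(self, mapping_index):
        """|K(Q)| counts only index-matched k-mers, so tau=1 still maps a
        read whose middle k-mers were destroyed by an error."""
        refs, idx = mapping_index
        read = list(refs.seqs[0][2000:2050])
        read[25] = {"A": "G"}.get(read[25], "A")
        read = "".join(read)
        scheme = build_scheme(idx.lengths, 1000, 100)
        hits = pseudoalign_mate(idx, scheme, read, MapParams(tau=1.0))
        assert len(hits) == 1
        h = hits[0]
        assert h.support == h.kq < 26
        assert (h.ref, h.pos, h.forward) == (0, 2000, True)

    def test_all_n_read_unmapped(self, mapping_index):
        _, idx = mapping_index
        scheme = build_scheme(idx.lengths, 1000, 100)
        assert pseudoalign_mate(idx, scheme, "N" * 50, MapParams()) == []

    def test_short_read_unmapped(self, mapping_index):
        _, idx = mapping_index
        scheme = build_scheme(idx.lengths, 1000, 100)
        assert pseudoalign_mate(idx, scheme, "ACGT", MapParams()) == []

    @pytest.mark.parametrize("tau", [0.6, 0.7, 0.8, 1.0])
    def test_matches_brute_force(self, tau):
        """Index-based pseudoalignment equals the literal threshold-union
        oracle on a small genome with duplications, both strands."""
        rng = np.random.default_rng(13)
        refs = random_refs(rng, [6000, 4000])
        s1 = list(refs.seqs[1])
        s1[1000:1400] = refs.seqs[0][2000:2400]  # 400 bp duplication
        refs = type(refs)(refs.names, [refs.seqs[0], "".join(s1)])
        idx = build_index(refs, 25)
        table = scan_kmer_table(refs, 25)
        scheme = build_scheme(idx.lengths, 500, 150)
        oscheme = OracleScheme(idx.lengths, 500, 150)
        params = MapParams(tau=tau, bin_length=500, ov_length=150)
        for _ in range(60):
            ref = int(rng.integers(0, 2))
            L = idx.lengths[ref]
            i = int(rng.integers(0, L - 80))
            read = refs.seqs[ref][i : i + 80]
            if rng.random() < 0.5:
                read = revcomp(read)
            if rng.random() < 0.5:  # inject an error
                j = int(rng.integers(0, len(read)))
                read = read[:j] + {"A": "C"}.get(read[j], "A") + read[j + 1 :]
            got = [tuple(h) for h in pseudoalign_mate(idx, scheme, read, params)]
            assert got == oracle_pseudoalign(table, oscheme, read, 25, tau)

    def test_tau_monotonicity(self, mapping_index):
        """Lowering tau never removes a pre-filter candidate color."""
        refs, idx = mapping_index
        scheme = build_scheme(idx.lengths, 1000, 100)
        rng = np.random.default_rng(3)
        for _ in range(30):
            i = int(rng.integers(0, idx.lengths[0] - 60))
            read = refs.seqs[0][i : i + 60]
            prev: set | None = None
            for tau in (1.0, 0.8, 0.6):
                cur = {
                    (h.vid, h.forward)
                    for h in pseudoalign_mate(idx, scheme, read, MapParams(tau=tau))
                }
                if prev is not None:
                    assert prev <= cur
                prev = cur


class TestDedup:
    def _hit(self, fwd, ref, pos, vid):
        return MappedHit(ref, pos, fwd, vid, 5, 5)

    def test_keeps_smaller_vid(self):
        hits = [self._hit(True, 0, 950, 0), self._hit(True, 0, 950, 1)]
        assert dedup_hits(hits) == [hits[0]]

    def test_distinct_positions_unchanged(self):
        hits = [self._hit(True, 0, 100, 0), self._hit(True, 0, 200, 0)]
        assert dedup_hits(hits) == hits

    def test_opposite_orientations_both_kept(self):
        hits = [self._hit(True, 0, 950, 0), self._hit(False, 0, 950, 0)]
        assert dedup_hits(hits) == hits

    def test_oversized_group_raises(self):
        hits = [self._hit(True, 0, 950, v) for v in range(3)]
        with pytest.raises(MappingInvariantError):
            dedup_hits(hits)


class TestMergeMates:
    P = MapParams()

    def _hit(self, fwd, ref, pos, vid=0):
        return MappedHit(ref, pos, fwd, vid, 10, 10)

    def test_fr_pair_merges(self):
        a = self._hit(True, 0, 100)
        b = self._hit(False, 0, 380)
        (m,) = merge_mates([a], [b], 50, 50, self.P)
        assert (m.ref, m.start, m.end, m.forward) == (0, 100, 430, True)
        assert m.fraction == 1.0

    def test_dovetail_within_bound(self):
        a = self._hit(True, 0, 100)
        b = self._hit(False, 0, 90)
        assert len(merge_mates([a], [b], 50, 50, self.P)) == 1

    def test_insert_too_large(self):
        a = self._hit(True, 0, 100)
        b = self._hit(False, 0, 1200)
        assert merge_mates([a], [b], 50, 50, self.P) == []

    def test_reverse_first_mate_symmetric(self):
        a = self._hit(False, 0, 380)
        b = self._hit(True, 0, 100)
        (m,) = merge_mates([a], [b], 50, 50, self.P)
        assert (m.start, m.end, m.forward) == (100, 430, False)

    @pytest.mark.parametrize(
        "a,b",
        [
            (("f", 0, 100, 0), ("f", 0, 380, 0)),   # same orientation
            (("f", 0, 100, 0), ("r", 1, 380, 5)),   # different reference
            (("f", 0, 100, 0), ("r", 0, 380, 2)),   # vid gap > 1
        ],
    )
    def test_rejection_criteria(self, a, b):
        ha = MappedHit(a[1], a[2], a[0] == "f", a[3], 10, 10)
        hb = MappedHit(b[1], b[2], b[0] == "f", b[3], 10, 10)
        assert merge_mates([ha], [hb], 50, 50, self.P) == []


class TestFilterBestSupport:
    def test_keeps_only_max_fraction(self):
        ms = [
            MergedMapping(0, 100, 430, True, 1.0),
            MergedMapping(0, 900, 1230, True, 0.8),
        ]
        assert filter_best_support(ms) == [ms[0]]

    def test_single_unchanged(self):
        ms = [MergedMapping(0, 100, 430, True, 0.9)]
        assert filter_best_support(ms) == ms

    def test_ties_all_survive(self):
        ms = [
            MergedMapping(0, 100, 430, True, 1.0),
            MergedMapping(0, 5100, 5430, True, 1.0),
        ]
        assert filter_best_support(ms) == ms

    def test_empty(self):
        assert filter_best_support([]) == []


class TestMapPair:
    def test_unique_pair_maps_to_truth(self):
        p = SimParams(genome_length=20_000, n_pairs=20, sub_rate=0.0, seed=2)
        refs, _ = make_genome(p)
        idx = build_index(refs, 25)
        scheme = build_scheme(idx.lengths, 1000, 200)
        pairs, truth, _ = simulate_pairs(refs, p)
        params = MapParams(ov_length=200)
        for (name, r1, bc, r2), t in zip(pairs, truth):
            status, rec = map_pair(idx, scheme, r1, r2, bc, params)
            assert status == "mapped"
            assert (rec.ref, rec.start, rec.end) == (t.ref, t.start, t.end)
            assert rec.forward == t.forward

    def test_exact_duplicate_multimaps(self):
        rng = np.random.default_rng(21)
        refs = random_refs(rng, [12_000])
        s = list(refs.seqs[0])
        s[9000:9500] = s[2000:2500]  # exact distant duplication
        refs = type(refs)(refs.names, ["".join(s)])
        idx = build_index(refs, 25)
        scheme = build_scheme(idx.lengths, 1000, 200)
        r1 = refs.seqs[0][2100:2200]
        r2 = revcomp(refs.seqs[0][2250:2350])
        status, rec = map_pair(idx, scheme, r1, r2, "AAAA", MapParams(ov_length=200))
        assert status == "multimapped" and rec is None

    def test_mates_on_different_references_unmapped(self):
        rng = np.random.default_rng(22)
        refs = random_refs(rng, [5000, 5000])
        idx = build_index(refs, 25)
        scheme = build_scheme(idx.lengths, 1000, 200)
        r1 = refs.seqs[0][1000:1100]
        r2 = revcomp(refs.seqs[1][1000:1100])
        status, rec = map_pair(idx, scheme, r1, r2, "AAAA", MapParams(ov_length=200))
        assert status == "unmapped" and rec is None


class TestOptimizations:
    def test_streaming_and_cache_transparent(self):
        """All four streaming x cache switch settings give identical output."""
        p = SimParams(genome_length=30_000, n_pairs=300, sub_rate=0.01, seed=6,
                      repeat_count=3, repeat_length=600, repeat_divergence=0.05)
        refs, _ = make_genome(p)
        idx = build_index(refs, 25)
        scheme = build_scheme(idx.lengths, 1000, 200)
        pairs, _, _ = simulate_pairs(refs, p)
        outputs = []
        for streaming in (True, False):
            for use_cache in (True, False):
                params = MapParams(ov_length=200, streaming=streaming,
                                   use_cache=use_cache)
                recs, stats = map_pairs(idx, scheme, pairs, params)
                outputs.append(
                    ([r.to_line() for r in recs], stats.as_dict())
                )
        assert all(o == outputs[0] for o in outputs[1:])

    def test_cache_write_once_and_consistent(self):
        # diverged repeat copies create unitig junctions for reads to cross
        p = SimParams(genome_length=30_000, n_pairs=400, sub_rate=0.0, seed=8,
                      repeat_count=6, repeat_length=800, repeat_divergence=0.03)
        refs, _ = make_genome(p)
        idx = build_index(refs, 25)
        assert idx.n_unitigs > 1
        scheme = build_scheme(idx.lengths, 1000, 200)
        pairs, _, _ = simulate_pairs(refs, p)
        cache = TerminalKmerCache(capacity=64)
        map_pairs(idx, scheme, pairs, MapParams(ov_length=200), cache)
        assert 0 < len(cache) <= 64
        for key, entry in cache.items():
            assert idx.k2u[key] == entry  # cached value == fresh index lookup
        # write-once: re-inserting a different value is ignored
        key = next(iter(dict(cache.items())))
        old = dict(cache.items())[key]
        cache.insert(key, old._replace(offset=old.offset + 1))
        assert dict(cache.items())[key] == old


class TestPreMerge:
    def test_overlapping_pair_merges(self):
        rng = np.random.default_rng(31)
        refs = random_refs(rng, [2000])
        frag = refs.seqs[0][500:640]  # 140 bp fragment, 100 bp mates: 60 overlap
        r1, r2 = frag[:100], revcomp(frag[-100:])
        assert merge_read_pair(r1, r2) == frag

    def test_disjoint_pair_does_not_merge(self):
        rng = np.random.default_rng(32)
        refs = random_refs(rng, [2000])
        r1 = refs.seqs[0][100:200]
        r2 = revcomp(refs.seqs[0][500:600])
        assert merge_read_pair(r1, r2) is None

    def test_premerge_pipeline_maps_fragment(self):
        p = SimParams(genome_length=20_000, n_pairs=10, sub_rate=0.0,
                      fragment_mean=150, fragment_sd=5, read_length=100,
                      random_orientation=False, seed=4)
        refs, _ = make_genome(p)
        idx = build_index(refs, 25)
        scheme = build_scheme(idx.lengths, 1000, 200)
        pairs, truth, _ = simulate_pairs(refs, p)
        params = MapParams(ov_length=200, premerge=True)
        for (name, r1, bc, r2), t in zip(pairs, truth):
            status, rec = map_pair(idx, scheme, r1, r2, bc, params)
            assert status == "mapped"
            assert (rec.start, rec.end) == (t.start, t.end)
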