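"""Path spelling, bounded DFS, and the three per-category recovery rules."""

from collections import deque

import numpy as np
import pytest

import pefrag as pf
from pefrag.classify import FragmentLengthRange, PECategory
from pefrag.recover import (RecoverConfig, find_paths, path_mean_coverage,
                            recover_bridging, recover_regular, recover_single,
                            spell_path)

from conftest import random_seq


def chain_graph(rng, lens, ovs, orients=None, depths=None):
    """A sequence-consistent oriented chain; returns (graph, steps, spelled)."""
    total = sum(lens) - sum(ovs)
    S = random_seq(rng, total)
    g = pf.ContigGraph()
    steps, prev, pos = [], None, 0
    for i, ln in enumerate(lens):
        seg = S[pos : pos + ln]
        o = orients[i] if orients else "+"
        d = depths[i] if depths else 10.0
        g.add_contig(pf.Contig(id=f"n{i}", sequence=seg if o == "+" else pf.revcomp(seg),
                               depth=[d] * ln))
        steps.append((f"n{i}", o))
        if prev is not None:
            g.add_edge(*prev, f"n{i}", o, ovs[i - 1])
        prev = (f"n{i}", o)
        if i < len(ovs):
            pos += ln - ovs[i]
    return g, steps, S


def enumerate_paths_bfs(graph, source, target, max_len):
    """Independent oracle: breadth-first enumeration of oriented paths under
    the same length bound."""
    a, ao, off = source
    queue = deque([([(a, ao)], 0)])
    found = []
    while queue:
        steps, start_pos = queue.popleft()
        if steps[-1] == target:
            found.append(steps)
        cur = steps[-1]
        for to, to_o, ov in graph.neighbors(*cur):
            ns = start_pos + len(graph.contigs[cur[0]]) - ov
            if ns - off < max_len:
                queue.append((steps + [(to, to_o)], ns))
    return sorted(found)


class TestSpellPath:
    def test_single_step_identity(self, rng):
        g, steps, S = chain_graph(rng, [120], [])
        assert spell_path(g, steps[:1]) == S

    def test_forced_overlap_semantics(self):
        g = pf.ContigGraph()
        g.add_contig(pf.Contig(id="c1", sequence="ACGTAC", depth=[1] * 6))
        g.add_contig(pf.Contig(id="c2", sequence="TACGG", depth=[1] * 5))
        g.add_edge("c1", "+", "c2", "+", 3)
        assert spell_path(g, [("c1", "+"), ("c2", "+")]) == "ACGTACGG"

    def test_five_contig_chain_matches_naive_merge(self, rng):
        lens = [100, 80, 90, 70, 110]
        ovs = [20, 15, 25, 30]
        orients = ["+", "-", "+", "-", "-"]
        g, steps, S = chain_graph(rng, lens, ovs, orients)
        spelled = spell_path(g, steps)
        assert spelled == S
        assert len(spelled) == sum(lens) - sum(ovs)  # length identity

    def test_missing_edge_rejected(self, rng):
        g, steps, _ = chain_graph(rng, [60, 60], [10])
        with pytest.raises(ValueError, match="no edge"):
            spell_path(g, [steps[0], (steps[1][0], "-")])


class TestPathMeanCoverage:
    def test_single_contig(self, rng):
        g, steps, _ = chain_graph(rng, [100], [], depths=[40.0])
        assert path_mean_coverage(g, steps) == pytest.approx(40.0)

    def test_length_weighted(self, rng):
        # contigs contribute 100 and 300 bases at depths 10 and 30 -> 25
        g, steps, _ = chain_graph(rng, [100, 350], [50], depths=[10.0, 30.0])
        assert path_mean_coverage(g, steps) == pytest.approx(25.0)


class TestFindPaths:
    def test_linear_chain_unique_path(self, rng):
        g, steps, S = chain_graph(rng, [100, 80, 90], [20, 20])
        paths = find_paths(g, (*steps[0], 0), steps[-1], max_len=len(S) + 50)
        assert [p.steps for p in paths] == [steps]
        assert paths[0].spelled_length == len(S)

    def test_tight_bound_admits_only_short_route(self, rng):
        g, steps, S = chain_graph(rng, [100, 80, 90], [20, 20])
        # long detour: n0 -> d -> n2 with a larger spelled extent
        d = random_seq(rng, 200)
        g.add_contig(pf.Contig(id="d", sequence=d, depth=[5.0] * 200))
        g.add_edge("n0", "+", "d", "+", 10)
        g.add_edge("d", "+", "n2", "+", 10)
        short_only = find_paths(g, (*steps[0], 0), steps[-1], max_len=len(S))
        assert [p.steps for p in short_only] == [steps]
        both = find_paths(g, (*steps[0], 0), steps[-1], max_len=len(S) + 300)
        assert len(both) == 2

    def test_cycle_terminates(self, rng):
        g, steps, _ = chain_graph(rng, [60, 60], [10])
        g.add_edge("n1", "+", "n0", "+", 10)  # short cycle
        paths = find_paths(g, ("n0", "+", 0), ("n1", "+"), max_len=500)
        assert len(paths) >= 2  # one loop or more, but finite
        assert all(p.steps[-1] == ("n1", "+") for p in paths)

    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        for trial in range(60):
            n = int(rng.integers(2, 13))
            g = pf.ContigGraph()
            for i in range(n):
                ln = int(rng.integers(40, 120))
                g.add_contig(pf.Contig(id=f"c{i}", sequence=random_seq(rng, ln),
                                       depth=[1.0] * ln))
            for _ in range(int(rng.integers(1, 2 * n))):
                i, j = rng.integers(0, n, size=2)
                g.add_edge(f"c{i}", "+-"[rng.integers(0, 2)],
                           f"c{j}", "+-"[rng.integers(0, 2)],
                           int(rng.integers(5, 30)))
            src = (f"c{rng.integers(0, n)}", "+-"[rng.integers(0, 2)],
                   int(rng.integers(0, 30)))
            dst = (f"c{rng.integers(0, n)}", "+-"[rng.integers(0, 2)])
            max_len = int(rng.integers(100, 400))
            got = find_paths(g, src, dst, max_len, max_paths=100_000)
            assert not got.truncated
            assert sorted(p.steps for p in got) == \
                enumerate_paths_bfs(g, src, dst, max_len)

    def test_truncation_flagged(self, rng):
        g, steps, _ = chain_graph(rng, [60, 60], [10])
        g.add_edge("n1", "+", "n0", "+", 10)
        paths = find_paths(g, ("n0", "+", 0), ("n1", "+"), max_len=5000,
                           max_paths=3)
        assert paths.truncated and len(paths) <= 3


def _hit(cid, start, strand, length=76, mm=0):
    return pf.MappingHit(read_id="r", contig_id=cid, start=start, strand=strand,
                         mismatches=mm, length=length)


def _pe(pe_id="pe1", s1="A" * 76, s2="A" * 76):
    return pf.PairedEnd(pe_id=pe_id,
                        read1=pf.SeqRecord(id=f"{pe_id}/1", sequence=s1),
                        read2=pf.SeqRecord(id=f"{pe_id}/2", sequence=s2))


class TestRecoverRegular:
    def _one_contig(self, rng, depth=20.0):
        g = pf.ContigGraph()
        seq = random_seq(rng, 500)
        g.add_contig(pf.Contig(id="c1", sequence=seq, depth=[depth] * 500))
        return g, seq

    def test_in_range_extraction(self, rng):
        g, seq = self._one_contig(rng)
        rng_ = FragmentLengthRange(250, 350)
        frag = recover_regular(_pe(), [_hit("c1", 100, "+")],
                               [_hit("c1", 324, "-")], g, rng_)
        assert frag is not None
        assert frag.length == 300
        assert frag.sequence == seq[100:400]
        assert frag.category is PECategory.REGULAR

    def test_out_of_range_rejected(self, rng):
        g, _ = self._one_contig(rng)
        rng_ = FragmentLengthRange(250, 350)
        assert recover_regular(_pe(), [_hit("c1", 0, "+")],
                               [_hit("c1", 324, "-")], g, rng_) is None

    def test_highest_depth_contig_wins(self, rng):
        g = pf.ContigGraph()
        s1, s2 = random_seq(rng, 500), random_seq(rng, 500)
        g.add_contig(pf.Contig(id="lo", sequence=s1, depth=[12.0] * 500))
        g.add_contig(pf.Contig(id="hi", sequence=s2, depth=[55.0] * 500))
        rng_ = FragmentLengthRange(250, 350)
        frag = recover_regular(
            _pe(),
            [_hit("lo", 100, "+"), _hit("hi", 100, "+")],
            [_hit("lo", 324, "-"), _hit("hi", 324, "-")], g, rng_)
        assert frag.path[0][0] == "hi"
        assert frag.sequence == s2[100:400]

    def test_minus_anchor_orients_fragment_to_read1(self, rng):
        g, seq = self._one_contig(rng)
        rng_ = FragmentLengthRange(250, 350)
        frag = recover_regular(_pe(), [_hit("c1", 324, "-")],
                               [_hit("c1", 100, "+")], g, rng_)
        assert frag.sequence == pf.revcomp(seq[100:400])


class TestRecoverBridging:
    def test_unique_path_extraction(self, rng):
        g, steps, S = chain_graph(rng, [200, 150, 180], [30, 30])
        rng_ = FragmentLengthRange(300, 400)
        h1 = _hit("n0", 50, "+")
        h2 = _hit("n2", 34, "-")  # frame end at 290 + 34 + 76 = 400
        frag = recover_bridging(_pe(), [h1], [h2], g, rng_)
        assert frag is not None
        assert frag.sequence == S[50:400]
        assert [s for s in frag.path] == steps

    def test_no_orientation_consistent_path(self, rng):
        g, steps, S = chain_graph(rng, [200, 150, 180], [30, 30])
        rng_ = FragmentLengthRange(300, 400)
        h2_wrong = _hit("n2", 34, "+")  # same strand as mate 1: outward
        assert recover_bridging(_pe(), [_hit("n0", 50, "+")], [h2_wrong],
                                g, rng_) is None

    def test_highest_coverage_path_wins(self, rng):
        # diamond: n0 -> {b_lo, b_hi} -> n3, same spelled length both ways
        A, C = random_seq(rng, 200), random_seq(rng, 200)
        mid = random_seq(rng, 100)
        b1 = A[-30:] + mid + C[:30]
        g = pf.ContigGraph()
        g.add_contig(pf.Contig(id="a", sequence=A, depth=[20.0] * 200))
        g.add_contig(pf.Contig(id="blo", sequence=b1, depth=[18.0] * len(b1)))
        b2 = A[-30:] + random_seq(rng, 100) + C[:30]
        g.add_contig(pf.Contig(id="bhi", sequence=b2, depth=[44.0] * len(b2)))
        g.add_contig(pf.Contig(id="z", sequence=C, depth=[20.0] * 200))
        for b in ("blo", "bhi"):
            g.add_edge("a", "+", b, "+", 30)
            g.add_edge(b, "+", "z", "+", 30)
        rng_ = FragmentLengthRange(350, 500)
        h1, h2 = _hit("a", 50, "+"), _hit("z", 100, "-")
        frag = recover_bridging(_pe(), [h1], [h2], g, rng_)
        assert frag is not None
        assert ("bhi", "+") in frag.path
        spelled = spell_path(g, [("a", "+"), ("bhi", "+"), ("z", "+")])
        assert frag.sequence == spelled[50 : 50 + frag.length]
        assert frag.length == 426  # frame start of z (300) + mate end (176) - 50


class TestRecoverSingle:
    def test_head_match_places_unmapped_mate(self, rng):
        g, steps, S = chain_graph(rng, [200, 250], [30])
        rng_ = FragmentLengthRange(250, 350)
        off, e = 40, 350
        r2 = pf.revcomp(S[e - 76 : e])
        pe = _pe(s2=r2)
        frag = recover_single(pe, _hit("n0", off, "+"), pe.read2, g, rng_)
        assert frag is not None
        assert frag.length == e - off
        assert frag.sequence == S[off:e]

    def test_head_absent_returns_none(self, rng):
        g, steps, S = chain_graph(rng, [200, 250], [30])
        rng_ = FragmentLengthRange(250, 350)
        pe = _pe(s2=random_seq(rng, 76))
        assert recover_single(pe, _hit("n0", 40, "+"), pe.read2, g, rng_) is None

    def test_highest_coverage_extension_wins(self, rng):
        A = random_seq(rng, 200)
        ext = random_seq(rng, 250)
        b_seq = A[-30:] + ext
        g = pf.ContigGraph()
        g.add_contig(pf.Contig(id="a", sequence=A, depth=[20.0] * 200))
        g.add_contig(pf.Contig(id="blo", sequence=b_seq, depth=[9.0] * len(b_seq)))
        g.add_contig(pf.Contig(id="bhi", sequence=b_seq, depth=[33.0] * len(b_seq)))
        g.add_edge("a", "+", "blo", "+", 30)
        g.add_edge("a", "+", "bhi", "+", 30)
        S = A + ext  # spelled along either branch
        rng_ = FragmentLengthRange(250, 350)
        off, e = 40, 350
        pe = _pe(s2=pf.revcomp(S[e - 76 : e]))
        frag = recover_single(pe, _hit("a", off, "+"), pe.read2, g, rng_)
        assert frag is not None
        assert ("bhi", "+") in frag.path
        assert frag.sequence == S[off:e]

    def test_junction_straddling_head_found(self, rng):
        # pattern spans the n0/n1 junction
        g, steps, S = chain_graph(rng, [200, 250], [30])
        rng_ = FragmentLengthRange(150, 350)
        e = 205  # head occupies S[195:205], across the junction at 200
        pe = _pe(s2=pf.revcomp(S[e - 76 : e]))
        frag = recover_single(pe, _hit("n0", 0, "+"), pe.read2, g, rng_)
        assert frag is not None and frag.sequence == S[0:e]


class TestRecoverAll:
    def test_partition_identity(self, clean_library, clean_graph):
        pairs, _ = clean_library
        res = pf.recover_all(pairs, clean_graph)
        assert len(res.fragments) + len(res.remaining) == len(pairs)
        recovered_ids = {f.pe_id for f in res.fragments}
        remaining_ids = {pe.pe_id for pe in res.remaining}
        assert not recovered_ids & remaining_ids
        n_by_cat = {c: 0 for c in PECategory}
        for f in res.fragments:
            n_by_cat[f.category] += 1
        for cat in PECategory:
            assert n_by_cat[cat] <= res.report[cat.value]["n_pes"]

    def test_error_free_fragments_are_genome_substrings(
        self, clean_library, clean_graph, small_genome
    ):
        pairs, truth = clean_library
        res = pf.recover_all(pairs, clean_graph)
        genome = small_genome.sequence
        rc = pf.revcomp(genome)
        for f in res.fragments[::37]:
            assert f.sequence in genome or f.sequence in rc
        # every regular fragment lies within the estimated range
        for f in res.fragments:
            if f.category is PECategory.REGULAR:
                assert f.length in res.range
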