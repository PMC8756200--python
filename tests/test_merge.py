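"""Greedy color-guided path cover: classification, traversal and emission."""

import numpy as np
import pytest

from nrsmerge.cdbg import build_ccdbg, spell
from nrsmerge.dna import revcomp
from nrsmerge.merge import (
    TraversalState,
    classify_vertices,
    merge,
    merge_graph,
    traverse_from_source,
    write_nrs_fasta,
)

from oracles import (
    coverable_vertices,
    enumerate_source_sink_paths,
    min_cover_weight,
    phi,
)

CLEAN = "GCTGAGACAAAGCACGCCAT"  # single unitig at k=5


def random_sets(rng, n_sets, n_seq=2, lo=20, hi=80):
    return [
        [
            "".join(rng.choice(list("ACGT"), size=rng.integers(lo, hi)))
            for _ in range(n_seq)
        ]
        for _ in range(n_sets)
    ]


class TestClassify:
    def test_isolated_unitig_is_singleton(self):
        g = build_ccdbg([[CLEAN]], 5)
        singles, sources, others = classify_vertices(g)
        assert singles == [0] and sources == [] and others == []

    def test_linear_chain_sources(self):
        # branch point makes a chain: verify source classification per
        # orientation against raw degree counts
        g = build_ccdbg([["AAACGTTCAAGG", "CAACGTTCATGG"]], 5)
        singles, sources, others = classify_vertices(g)
        assert not singles
        for uid, ori in sources:
            assert g.successors(uid, ori)
            assert not g.predecessors(uid, ori)
        # every forward sink is a reverse source in a bidirected graph
        for u in g.unitigs:
            for ori in "+-":
                if g.successors(u.id, ori) and not g.predecessors(u.id, ori):
                    assert (u.id, ori) in sources

    def test_cycle_has_no_sources_or_singletons(self):
        # a circular k-mer structure: repeat of period > k
        cyc = "ACGGATGGCACGGATGGCACGGATGGC"
        g = build_ccdbg([[cyc]], 5)
        singles, sources, others = classify_vertices(g)
        assert singles == [] and sources == []
        assert set(others) == {u.id for u in g.unitigs}


class TestTraversal:
    def test_chain_emits_full_path(self):
        inA = "GCTGAGACAAAGCACGCCAT"
        inB = "ATATTTCAAGAGGACTCAGT"
        mid = "CGGTTTTGTCCTGTAAAGCC"
        g = build_ccdbg([[inA + mid], [inB + mid]], 7)
        _, sources, _ = classify_vertices(g)
        state = TraversalState(tau=0)
        path = traverse_from_source(g, sources[0], state)
        assert path is not None
        # emitted path is valid: consecutive steps are edges, ids distinct
        ids = path.ids()
        assert len(set(ids)) == len(ids)
        for a, b in zip(path.steps, path.steps[1:]):
            assert b in g.successors(*a)
        assert set(ids) <= state.covered

    def test_bubble_prefers_color_consistent_branch(self):
        # two colors share flanks; each color has its own middle -> the
        # traversal from a flank should follow its color. Verify the emitted
        # path has the minimum phi among all source-sink paths.
        s1 = "GCTGAGACAAAGCACGCCATGGTC"
        mid1, mid2 = "TTACGATCGGA", "CGGATTAACGT"
        right = "GACCTTAGTTCAATCTCATC"
        sets = [[s1 + mid1 + right], [s1 + mid2 + right]]
        g = build_ccdbg(sets, 7)
        _, sources, _ = classify_vertices(g)
        state = TraversalState(tau=0)
        path = traverse_from_source(g, sources[0], state)
        assert path is not None
        best = min(phi(g, p) for p in enumerate_source_sink_paths(g))
        assert phi(g, path.steps) == pytest.approx(best)

    def test_tau_gate_is_strict(self):
        inA = "GCTGAGACAAAGCACGCCAT"
        inB = "ATATTTCAAGAGGACTCAGT"
        mid = "CGGTTTTGTCCTGTAAAGCC"
        g = build_ccdbg([[inA + mid], [inB + mid]], 7)
        _, sources, _ = classify_vertices(g)
        assert sources
        state = TraversalState(tau=0)
        first = traverse_from_source(g, sources[0], state)
        assert first is not None
        # re-traversing the same source: zero novel k-mers, 0 > 0 is false
        again = traverse_from_source(g, sources[0], state)
        assert again is None


class TestMergeExamples:
    def test_identical_contigs_one_nrs(self):
        recs = merge([[CLEAN]] * 4, k=5, tau=0)
        assert len(recs) == 1
        assert recs[0].sequence in (CLEAN, revcomp(CLEAN))

    def test_x_shaped_graph_pairs_same_color_flanks(self):
        # two colors share a middle segment with distinct flanks; the
        # zero-phi cover pairs same-colored in/out flanks and re-uses the
        # shared middle in both paths
        inA = "GCTGAGACAAAGCACGCCAT"
        inB = "ATATTTCAAGAGGACTCAGT"
        mid = "CGGTTTTGTCCTGTAAAGCC"
        outA = "CTCTGCTTATCTATGTGTTG"
        outB = "GACCTTAGTTCAATCTCATC"
        sets = [[inA + mid + outA], [inB + mid + outB]]
        recs = merge(sets, k=7, tau=0)
        seqs = {r.sequence for r in recs} | {revcomp(r.sequence) for r in recs}
        assert sets[0][0] in seqs
        assert sets[1][0] in seqs
        # the bidirected graph also exposes reverse-orientation sources; a
        # greedy pass from one of them may emit one extra (mixed-color) path
        assert 2 <= len(recs) <= 3
        g = build_ccdbg(sets, 7)
        covered = set().union(*[set(r.source_path.ids()) for r in recs])
        assert covered == {u.id for u in g.unitigs}

    def test_huge_tau_only_singletons(self):
        sets = [["AAACGTTCAAGG", "CAACGTTCATGG"]]
        g = build_ccdbg(sets, 5)
        total = sum(u.n_kmers for u in g.unitigs)
        recs = merge(sets, k=5, tau=total)
        singles, _, _ = classify_vertices(g)
        assert len(recs) == len(singles)


class TestMergeProperties:
    def test_validity_and_omega_length_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            sets = random_sets(rng, int(rng.integers(1, 4)))
            g = build_ccdbg(sets, 7)
            recs = merge_graph(g, tau=0)
            for r in recs:
                ids = r.source_path.ids()
                assert len(set(ids)) == len(ids)
                m = len(ids)
                total = sum(len(g.unitigs[u].sequence) for u in ids)
                assert len(r.sequence) == total - (m - 1) * (7 - 1)
                assert r.sequence == spell(r.source_path, g)

    def test_cover_property_with_tau_zero(self):
        # on graphs where every unitig lies on some source-sink path (or is
        # a singleton), tau=0 merging covers every unitig
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(25):
            sets = random_sets(rng, int(rng.integers(1, 4)))
            g = build_ccdbg(sets, 7)
            on_path = set().union(
                *[
                    {uid for uid, _ in p}
                    for p in enumerate_source_sink_paths(g)
                ],
                set(classify_vertices(g)[0]),
            )
            if on_path != {u.id for u in g.unitigs}:
                continue
            checked += 1
            recs = merge_graph(g, tau=0)
            covered = set().union(*[set(r.source_path.ids()) for r in recs])
            assert covered == {u.id for u in g.unitigs}
        assert checked >= 5

    def test_tau_monotonicity(self):
        """Emitted non-singleton NRS can only disappear as tau grows.

        Tested in the regime the threshold is meant for: candidate paths in
        separate components (one per insertion-like family), where the
        covered set D does not couple distinct sources. With entangled
        sources, suppressing one path under a higher tau shrinks D and can
        legitimately enable another, so strict set-shrinkage is only
        guaranteed for component-disjoint paths.
        """
        rng = np.random.default_rng(9)
        # several shared-core families, each its own component
        sets = [[], [], []]
        for fam in range(6):
            core = "".join(rng.choice(list("ACGT"), size=60))
            for color in range(3):
                if rng.random() < 0.7:
                    flank = "".join(rng.choice(list("ACGT"), size=12))
                    sets[color].append(core + flank)
        prev = None
        for tau in (0, 5, 10, 20, 40, 10**6):
            recs = merge(sets, k=7, tau=tau)
            non_single = {
                r.sequence for r in recs if len(r.source_path.steps) > 1
            }
            if prev is not None:
                assert non_single <= prev
            prev = non_single

    def test_determinism_byte_identical_fasta(self, tmp_path):
        rng = np.random.default_rng(13)
        sets = random_sets(rng, 4, n_seq=3)
        p1, p2 = str(tmp_path / "a.fa"), str(tmp_path / "b.fa")
        write_nrs_fasta(merge(sets, k=7, tau=6), p1)
        write_nrs_fasta(merge(sets, k=7, tau=6), p2)
        assert open(p1, "rb").read() == open(p2, "rb").read()


class TestGreedyVsOracle:
    def test_zero_weight_cover_found_and_never_beats_optimum(self):
        """On small graphs the heuristic's emitted cover weight is 0
        whenever a zero-weight source-sink cover exists, and never falls
        below the exhaustive minimum."""
        rng = np.random.default_rng(20240915)
        n_small = 0
        trials = 0
        while n_small < 30 and trials < 2000:
            trials += 1
            n_sets = int(rng.integers(1, 4))
            sets = random_sets(rng, n_sets, n_seq=int(rng.integers(1, 3)), lo=12, hi=35)
            g = build_ccdbg(sets, 5)
            if not 2 <= len(g) <= 7:
                continue
            opt, n_coverable = min_cover_weight(g)
            if opt is None:
                continue
            n_small += 1
            recs = merge_graph(g, tau=0)
            singles = set(classify_vertices(g)[0])
            family = [
                r
                for r in recs
                if len(r.source_path.steps) > 1
                or r.source_path.ids()[0] in singles
            ]
            heur = sum(phi(g, r.source_path.steps) for r in family)
            covered = set().union(
                *[set(r.source_path.ids()) for r in family], set()
            )
            opt_same, _ = min_cover_weight(g, targets=covered)
            assert heur >= opt_same - 1e-12
            if opt == 0.0 and covered >= coverable_vertices(g):
                # the heuristic also achieves a zero-weight cover
                assert heur == pytest.approx(0.0)
        assert n_small >= 20
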