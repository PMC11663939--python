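"""Discovery engine: stable skeleton, retention, majority rule, R0-R10."""

import itertools

import numpy as np
import pytest

from anchorfci.citest import CITestResult, oracle_ci
from anchorfci.engine import (
    DiscoveryConfig,
    SepsetStore,
    TripleStatus,
    TripleTable,
    TripleRecord,
    apply_orientation_rules,
    classify_triples_majority,
    orient_v_structures,
    rfci_triple_retention,
    run_discovery,
    stable_skeleton,
)
from anchorfci.graph import (
    ARROWHEAD,
    CIRCLE,
    PAG,
    TAIL,
    m_separated,
)
from .conftest import random_mag


class DictTester:
    """CI tester scripted from a {(pair, S): p} table; dependent by default."""

    def __init__(self, table, default=0.0):
        self.table = {
            (frozenset(pair), frozenset(S)): p for (pair, S), p in table.items()
        }
        self.default = default
        self.n_tests = 0
        self.queries = []

    def test(self, i, j, S=()):
        self.n_tests += 1
        key = (frozenset((i, j)), frozenset(S))
        self.queries.append(key)
        p = self.table.get(key, self.default)
        return CITestResult(p, p, p, 1, 1, "mock", "mock")

    __call__ = test


class TestStableSkeleton:
    def test_oracle_chain(self, chain_mag):
        g, sepsets = stable_skeleton(
            oracle_ci(chain_mag), chain_mag.nodes, DiscoveryConfig()
        )
        assert g.has_edge("A", "B") and g.has_edge("B", "C")
        assert not g.has_edge("A", "C")
        assert sepsets.get_set("A", "C") == {"B"}

    def test_order_independence(self, fig_mag, rng):
        cfg = DiscoveryConfig()
        ref, _ = stable_skeleton(oracle_ci(fig_mag), fig_mag.nodes, cfg)
        for _ in range(3):
            perm = list(rng.permutation(fig_mag.nodes))
            g, _ = stable_skeleton(oracle_ci(fig_mag), perm, cfg)
            for a, b in itertools.combinations(fig_mag.nodes, 2):
                assert g.has_edge(a, b) == ref.has_edge(a, b)

    def test_max_cond_size_zero_only_marginal_tests(self, chain_mag):
        tester = oracle_ci(chain_mag)
        g, _ = stable_skeleton(
            tester, chain_mag.nodes, DiscoveryConfig(max_cond_size=0)
        )
        # A-C requires conditioning on B, so the edge survives at m=0
        assert g.has_edge("A", "C")

    def test_filter_vetoes_combinations(self, fig_mag):
        anchors = {"G1", "G2", "G3"}
        interest = {"A", "B", "C", "D", "E"}

        def forbid(i, j, S):
            return i in anchors and j in anchors and bool(set(S) & interest)

        free = oracle_ci(fig_mag)
        stable_skeleton(free, fig_mag.nodes, DiscoveryConfig())
        filt = oracle_ci(fig_mag)
        stable_skeleton(filt, fig_mag.nodes, DiscoveryConfig(), forbid)
        # no forbidden query was ever executed
        for pair, S in filt._cache.keys():
            i, j = sorted(pair)
            assert not forbid(i, j, S)


class TestRetention:
    def test_faithful_oracle_removes_nothing(self, rng):
        for _ in range(5):
            mag = random_mag(rng, n=6)
            tester = oracle_ci(mag)
            cfg = DiscoveryConfig()
            g, sepsets = stable_skeleton(tester, mag.nodes, cfg)
            before = set(g.edges())
            g2 = rfci_triple_retention(g, sepsets, tester, cfg)
            assert set(g2.edges()) == before

    def test_unfaithful_edge_removed_and_sepset_shrunk(self):
        # x leaves j's and k's adjacency at level 0, so the skeleton never
        # tests (j, k | {x}); the retention check of triple <i, k, j> does,
        # finds independence, and removes k-j with minimal sepset {x}.
        nodes = ["i", "j", "k", "x"]
        table = {
            (("j", "x"), ()): 0.9,
            (("k", "x"), ()): 0.9,
            (("i", "j"), ("x",)): 0.9,  # i-j removed at level 1, sepset {x}
            (("j", "k"), ("x",)): 0.8,  # only retention can discover this
        }
        tester = DictTester(table)
        cfg = DiscoveryConfig()
        g, sepsets = stable_skeleton(tester, nodes, cfg)
        assert g.has_edge("j", "k")
        assert sepsets.get_set("i", "j") == {"x"}
        g2 = rfci_triple_retention(g, sepsets, tester, cfg)
        assert not g2.has_edge("j", "k")
        assert sepsets.get_set("j", "k") == {"x"}

    def test_oracle_sepsets_are_minimal(self, rng):
        for _ in range(10):
            mag = random_mag(rng, n=6)
            tester = oracle_ci(mag)
            cfg = DiscoveryConfig()
            g, sepsets = stable_skeleton(tester, mag.nodes, cfg)
            rfci_triple_retention(g, sepsets, tester, cfg)
            for pair, (S, _p) in sepsets.items():
                x, y = sorted(pair)
                assert m_separated(mag, x, y, S)
                for v in S:
                    assert not m_separated(mag, x, y, S - {v})


class TestMajorityRule:
    def _tie_tester(self):
        # adj(i) = adj(j) = {k, a, b}; separating sets for (i, j):
        # {a}, {b}, {k,a}, {k,b}  -> exactly half contain k
        sep = [("a",), ("b",), ("k", "a"), ("k", "b")]
        table = {(("i", "j"), S): 0.9 for S in sep}
        return DictTester(table)

    def test_two_of_four_vote_is_ambiguous(self):
        nodes = ["a", "b", "i", "j", "k"]
        tester = self._tie_tester()
        cfg = DiscoveryConfig()
        g, sepsets = stable_skeleton(tester, nodes, cfg)
        assert not g.has_edge("i", "j")
        g = rfci_triple_retention(g, sepsets, tester, cfg)
        triples = classify_triples_majority(g, sepsets, tester, cfg)
        rec = triples[("i", "k", "j")]
        assert rec.status == TripleStatus.AMBIGUOUS
        assert rec.vote_fraction == 0.5
        assert rec.n_sepsets == 4

    def test_oracle_collider_has_zero_vote(self, collider_mag):
        tester = oracle_ci(collider_mag)
        cfg = DiscoveryConfig()
        g, sepsets = stable_skeleton(tester, collider_mag.nodes, cfg)
        g = rfci_triple_retention(g, sepsets, tester, cfg)
        triples = classify_triples_majority(g, sepsets, tester, cfg)
        rec = triples[("A", "C", "B")]
        assert rec.status == TripleStatus.COLLIDER
        assert rec.vote_fraction == 0.0

    def test_majority_rule_off_uses_stored_sepset(self, collider_mag):
        tester = oracle_ci(collider_mag)
        cfg = DiscoveryConfig(majority_rule=False)
        g, sepsets = stable_skeleton(tester, collider_mag.nodes, cfg)
        triples = classify_triples_majority(g, sepsets, tester, cfg)
        assert triples[("A", "C", "B")].status == TripleStatus.COLLIDER


class TestOrientation:
    def test_r0_orients_collider_and_leaves_ambiguous(self):
        g = PAG(["A", "B", "C"])
        g.set_edge("A", "C", CIRCLE, CIRCLE)
        g.set_edge("B", "C", CIRCLE, CIRCLE)
        triples = TripleTable()
        triples.put("A", "C", "B", TripleRecord(TripleStatus.COLLIDER, 0.0, 1))
        pag = orient_v_structures(g, triples)
        assert pag.mark("A", "C") == ARROWHEAD
        assert pag.mark("B", "C") == ARROWHEAD
        assert pag.mark("C", "A") == CIRCLE  # endpoint marks untouched

        triples2 = TripleTable()
        triples2.put("A", "C", "B", TripleRecord(TripleStatus.AMBIGUOUS, 0.5, 2))
        pag2 = orient_v_structures(g, triples2)
        assert pag2.mark("A", "C") == CIRCLE

    def test_r1_orients_definite_noncollider(self):
        g = PAG(["A", "B", "C"])
        g.set_edge("A", "B", CIRCLE, ARROWHEAD)  # A *-> B
        g.set_edge("B", "C", CIRCLE, CIRCLE)
        triples = TripleTable()
        triples.put("A", "B", "C", TripleRecord(TripleStatus.NONCOLLIDER, 1.0, 1))
        pag, log, conflicts = apply_orientation_rules(
            g, triples, SepsetStore(), DiscoveryConfig()
        )
        assert pag.mark("B", "C") == ARROWHEAD
        assert pag.mark("C", "B") == TAIL
        assert conflicts == []

    def test_r1_blocked_by_ambiguity(self):
        g = PAG(["A", "B", "C"])
        g.set_edge("A", "B", CIRCLE, ARROWHEAD)
        g.set_edge("B", "C", CIRCLE, CIRCLE)
        triples = TripleTable()
        triples.put("A", "B", "C", TripleRecord(TripleStatus.AMBIGUOUS, 0.5, 2))
        pag, _, _ = apply_orientation_rules(
            g, triples, SepsetStore(), DiscoveryConfig()
        )
        assert pag.mark("B", "C") == CIRCLE

    def test_idempotence(self, fig_mag):
        res = run_discovery(oracle_ci(fig_mag), fig_mag.nodes)
        pag2, log2, _ = apply_orientation_rules(
            res.pag, res.triples, res.sepsets, DiscoveryConfig()
        )
        assert pag2 == res.pag
        assert log2 == []

    def test_r4_noncollider_branch(self):
        # discriminating path <d, a, b, c>: d*->a<->b o-o c, a --> c
        g = PAG(["a", "b", "c", "d"])
        g.set_edge("d", "a", CIRCLE, ARROWHEAD)
        g.set_edge("a", "b", ARROWHEAD, ARROWHEAD)
        g.set_edge("a", "c", TAIL, ARROWHEAD)
        g.set_edge("b", "c", CIRCLE, CIRCLE)
        sepsets = SepsetStore()
        sepsets.put("d", "c", {"b"}, 0.9)
        pag, log, _ = apply_orientation_rules(
            g, sepsets=sepsets, triples=TripleTable(), config=DiscoveryConfig()
        )
        assert pag.mark("b", "c") == ARROWHEAD
        assert pag.mark("c", "b") == TAIL
        assert any(r[0] == "R4" for r in log)

    def test_r4_collider_branch(self):
        g = PAG(["a", "b", "c", "d"])
        g.set_edge("d", "a", CIRCLE, ARROWHEAD)
        g.set_edge("a", "b", ARROWHEAD, ARROWHEAD)
        g.set_edge("a", "c", TAIL, ARROWHEAD)
        g.set_edge("b", "c", CIRCLE, CIRCLE)
        sepsets = SepsetStore()
        sepsets.put("d", "c", set(), 0.9)  # b not in the separating set
        pag, log, _ = apply_orientation_rules(
            g, sepsets=sepsets, triples=TripleTable(), config=DiscoveryConfig()
        )
        assert pag.mark("c", "b") == ARROWHEAD  # collider at b
        assert pag.mark("b", "a") == ARROWHEAD  # a <-> b

    def test_conflicting_demand_keeps_earlier_mark_and_logs(self):
        # A *-> B o-t C: R1 wants an arrowhead at C, but a definite tail is
        # already there; the earlier mark must win and the conflict be logged
        g = PAG(["A", "B", "C"])
        g.set_edge("A", "B", CIRCLE, ARROWHEAD)
        g.set_edge("B", "C", CIRCLE, TAIL)  # circle at B, tail at C
        triples = TripleTable()
        triples.put("A", "B", "C", TripleRecord(TripleStatus.NONCOLLIDER, 1.0, 1))
        pag, _, conflicts = apply_orientation_rules(
            g, triples, SepsetStore(), DiscoveryConfig()
        )
        assert conflicts
        assert pag.mark("B", "C") == TAIL  # earlier mark kept


class TestOracleSoundness:
    def test_invariant_marks_match_generating_mag(self, rng):
        """Definite marks of the oracle-run PAG never contradict the MAG."""
        checked_arrow = checked_tail = 0
        for _ in range(12):
            mag = random_mag(rng, n=6)
            res = run_discovery(oracle_ci(mag), mag.nodes)
            pag = res.pag
            assert res.conflicts == []
            for a, b in itertools.combinations(mag.nodes, 2):
                assert pag.has_edge(a, b) == mag.has_edge(a, b)
                if not pag.has_edge(a, b):
                    continue
                for x, y in ((a, b), (b, a)):
                    m = pag.mark(x, y)
                    if m == ARROWHEAD:
                        assert mag.mark(x, y) == ARROWHEAD, (mag, pag, x, y)
                        checked_arrow += 1
                    elif m == TAIL:
                        assert mag.mark(x, y) == TAIL, (mag, pag, x, y)
                        checked_tail += 1
        assert checked_arrow > 10 and checked_tail > 0

    def test_monotone_caution_in_cap(self, rng):
        """Raising the conditioning cap under the oracle never yields
        contradictory definite marks, only more or fewer circles."""
        for _ in range(5):
            mag = random_mag(rng, n=6)
            pags = [
                run_discovery(
                    oracle_ci(mag), mag.nodes, DiscoveryConfig(max_cond_size=m)
                ).pag
                for m in (0, 1, None)
            ]
            for p in pags:
                for a, b in itertools.combinations(mag.nodes, 2):
                    if not p.has_edge(a, b):
                        continue
                    for x, y in ((a, b), (b, a)):
                        m = p.mark(x, y)
                        if m in (ARROWHEAD, TAIL) and mag.has_edge(x, y):
                            assert mag.mark(x, y) == m
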