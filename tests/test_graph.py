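"""Graph core: marks, ancestral validity, m-separation, projection, SHD."""

import itertools

import numpy as np
import pytest

from anchorfci.graph import (
    ARROWHEAD,
    CIRCLE,
    MAG,
    TAIL,
    GraphError,
    MarkedGraph,
    definite_status_open,
    is_valid_ancestral,
    latent_project,
    m_separated,
    possible_descendants,
    shd,
)
from .conftest import (
    all_queries,
    bidirected,
    brute_force_m_separated,
    directed,
    random_dag,
    random_mag,
)


class TestMarkedGraph:
    def test_no_half_edges(self):
        g = MarkedGraph(["A", "B"])
        with pytest.raises(GraphError):
            g.set_edge("A", "B", TAIL, 0)

    def test_unknown_label(self, chain_mag):
        with pytest.raises(GraphError, match="X"):
            chain_mag.mark("A", "X")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(GraphError):
            MarkedGraph(["A", "A"])

    def test_edge_roundtrip_and_types(self, chain_mag):
        assert chain_mag.edge_type("A", "B") == "-->"
        assert chain_mag.edge_type("B", "A") == "<--"
        assert chain_mag.mark("A", "B") == ARROWHEAD
        assert chain_mag.mark("B", "A") == TAIL

    def test_copy_is_independent(self, chain_mag):
        g2 = chain_mag.copy()
        g2.remove_edge("A", "B")
        assert chain_mag.has_edge("A", "B")
        assert not g2.has_edge("A", "B")

    def test_ancestors(self, chain_mag):
        assert chain_mag.ancestors(["C"]) == {"A", "B", "C"}
        assert chain_mag.ancestors(["A"]) == {"A"}

    def test_dot_export_mentions_all_edges(self, fig_mag):
        dot = fig_mag.to_dot()
        assert dot.count("--") == len(list(fig_mag.edges()))
        assert "arrowhead=normal" in dot


class TestAncestralValidity:
    def test_dag_is_valid(self, chain_mag):
        ok, viol = is_valid_ancestral(chain_mag)
        assert ok and viol == []

    def test_almost_directed_cycle(self):
        g = MarkedGraph(["A", "B"])
        # A --> B and A <-> B cannot coexist on one edge pair, so use 3 nodes:
        # A --> B, B <-> A is the same edge; instead A --> B --> C with A <-> C
        g = MarkedGraph(["A", "B", "C"])
        directed(g, "A", "B")
        directed(g, "B", "C")
        bidirected(g, "A", "C")
        ok, viol = is_valid_ancestral(g)
        assert not ok
        assert any(set(v) == {"A", "B", "C"} for v in viol)

    def test_directed_cycle_reported(self):
        g = MarkedGraph(["A", "B", "C"])
        directed(g, "A", "B")
        directed(g, "B", "C")
        directed(g, "C", "A")
        ok, viol = is_valid_ancestral(g)
        assert not ok
        assert any(len(v) == 4 and v[0] == v[-1] for v in viol)


class TestMSeparation:
    def test_chain_blocked_by_middle(self, chain_mag):
        assert m_separated(chain_mag, "A", "C", {"B"})
        assert not m_separated(chain_mag, "A", "C", set())

    def test_collider_semantics(self, collider_mag):
        assert m_separated(collider_mag, "A", "B", set())
        assert not m_separated(collider_mag, "A", "B", {"C"})

    def test_collider_descendant_opens(self):
        g = MAG(["A", "B", "C", "D"])
        directed(g, "A", "C")
        directed(g, "B", "C")
        directed(g, "C", "D")
        assert not m_separated(g, "A", "B", {"D"})

    def test_errors(self, chain_mag):
        with pytest.raises(GraphError):
            m_separated(chain_mag, "A", "A", set())
        with pytest.raises(GraphError):
            m_separated(chain_mag, "A", "C", {"A"})
        with pytest.raises(GraphError, match="Q"):
            m_separated(chain_mag, "A", "Q", set())

    def test_symmetry_and_oracle_agreement(self, rng):
        """BFS reachability must match path enumeration on random 6-node MAGs."""
        for _ in range(20):
            g = random_mag(rng, n=6)
            for x, y, Z in all_queries(g.nodes, max_z=3):
                got = m_separated(g, x, y, Z)
                assert got == m_separated(g, y, x, Z)
                assert got == brute_force_m_separated(g, x, y, Z), (g, x, y, Z)


class TestLatentProject:
    def test_classic_confounder(self):
        g = MarkedGraph(["L", "A", "B"])
        directed(g, "L", "A")
        directed(g, "L", "B")
        mag = latent_project(g, {"L"})
        assert mag.nodes == ("A", "B")
        assert mag.edge_type("A", "B") == "<->"

    def test_no_latents_identity(self, rng):
        for _ in range(5):
            dag = random_dag(rng, n=6)
            mag = latent_project(dag, set())
            assert set(mag.edges()) == set(dag.edges())
            for i, j in dag.edges():
                assert mag.mark(i, j) == dag.mark(i, j)

    def test_cyclic_input_rejected(self):
        g = MarkedGraph(["A", "B"])
        directed(g, "A", "B")
        g.marks[:] = 0
        g.set_edge("A", "B", CIRCLE, CIRCLE)
        with pytest.raises(GraphError):
            latent_project(g, set())

    def test_projection_preserves_observed_independencies(self, rng):
        """MAG m-separations equal DAG d-separations among observed nodes."""
        import networkx as nx

        for _ in range(10):
            dag = random_dag(rng, n=7)
            latents = set(rng.choice(dag.nodes, size=2, replace=False))
            mag = latent_project(dag, latents)
            ok, _ = is_valid_ancestral(mag)
            assert ok
            D = nx.DiGraph()
            D.add_nodes_from(dag.nodes)
            for i, j in dag.edges():
                (D.add_edge(i, j) if dag.mark(i, j) == ARROWHEAD else D.add_edge(j, i))
            for x, y, Z in all_queries(mag.nodes, max_z=3):
                assert m_separated(mag, x, y, Z) == nx.is_d_separator(D, {x}, {y}, Z)


class TestSHD:
    def test_identity(self, fig_mag):
        assert shd(fig_mag, fig_mag) == 0

    def test_single_mark_difference(self):
        g1 = MarkedGraph(["A", "B"])
        g1.set_edge("A", "B", CIRCLE, CIRCLE)
        g2 = MarkedGraph(["A", "B"])
        g2.set_edge("A", "B", CIRCLE, ARROWHEAD)
        assert shd(g1, g2) == 1

    def test_adjacency_difference_counts_one(self):
        g1 = MarkedGraph(["A", "B"])
        g1.set_edge("A", "B", TAIL, ARROWHEAD)
        g2 = MarkedGraph(["A", "B"])
        assert shd(g1, g2) == 1

    def test_subset_restriction(self, fig_mag):
        empty = MAG(fig_mag.nodes)
        # restricted to interest variables: count only their pairwise edges
        interest = ["A", "B", "C", "D", "E"]
        expected = sum(
            1
            for a, b in itertools.combinations(interest, 2)
            if fig_mag.has_edge(a, b)
        )
        assert shd(fig_mag, empty, interest) == expected

    def test_label_mismatch(self):
        with pytest.raises(GraphError):
            shd(MarkedGraph(["A"]), MarkedGraph(["B"]))

    def test_metric_properties(self, rng):
        """Symmetry, identity and triangle inequality on random mark matrices."""
        nodes = ["A", "B", "C", "D"]
        for _ in range(25):
            gs = []
            for _k in range(3):
                g = MarkedGraph(nodes)
                for a, b in itertools.combinations(nodes, 2):
                    if rng.random() < 0.6:
                        g.set_edge(a, b, rng.integers(1, 4), rng.integers(1, 4))
                gs.append(g)
            g1, g2, g3 = gs
            assert shd(g1, g2) == shd(g2, g1)
            assert shd(g1, g1) == 0
            assert shd(g1, g3) <= shd(g1, g2) + shd(g2, g3)


class TestPossibleDescendants:
    def test_chain(self, chain_mag):
        assert possible_descendants(chain_mag, "A") == {"A", "B", "C"}
        assert possible_descendants(chain_mag, "C") == {"C"}

    def test_arrow_blocks(self):
        g = MarkedGraph(["A", "B"])
        directed(g, "B", "A")
        assert possible_descendants(g, "A") == {"A"}

    def test_circle_paths_count(self):
        g = MarkedGraph(["A", "B", "C"])
        g.set_edge("A", "B", CIRCLE, CIRCLE)
        g.set_edge("B", "C", CIRCLE, ARROWHEAD)
        assert possible_descendants(g, "A") == {"A", "B", "C"}

    def test_matches_path_enumeration(self, rng):
        for _ in range(20):
            nodes = [f"V{i}" for i in range(5)]
            g = MarkedGraph(nodes)
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.45:
                    g.set_edge(a, b, rng.integers(1, 4), rng.integers(1, 4))
            for x in nodes:
                # brute force: enumerate all simple paths, keep those where
                # every step leaves with a non-arrowhead and enters with a
                # non-tail mark
                reach = {x}
                def extend(path):
                    u = path[-1]
                    for v in g.adjacent(u):
                        if v in path:
                            continue
                        if g.mark(v, u) != ARROWHEAD and g.mark(u, v) != TAIL:
                            reach.add(v)
                            extend(path + [v])
                extend([x])
                assert possible_descendants(g, x) == reach


class TestDefiniteStatusOpen:
    def test_confounder_open(self):
        g = MarkedGraph(["X", "C", "Y"])
        directed(g, "C", "X")
        directed(g, "C", "Y")
        definite, open_ = definite_status_open(g, ["X", "C", "Y"], set())
        assert definite and open_
        definite, open_ = definite_status_open(g, ["X", "C", "Y"], {"C"})
        assert definite and not open_

    def test_collider_blocked_without_descendant_in_z(self):
        g = MarkedGraph(["X", "C", "Y"])
        directed(g, "X", "C")
        directed(g, "Y", "C")
        definite, open_ = definite_status_open(g, ["X", "C", "Y"], set())
        assert definite and not open_
        definite, open_ = definite_status_open(g, ["X", "C", "Y"], {"C"})
        assert definite and open_

    def test_shielded_circle_interior_not_definite(self):
        g = MarkedGraph(["X", "B", "Y", "W"])
        g.set_edge("X", "B", CIRCLE, CIRCLE)
        g.set_edge("B", "Y", CIRCLE, CIRCLE)
        g.set_edge("X", "Y", CIRCLE, CIRCLE)  # shields the triple
        definite, open_ = definite_status_open(g, ["X", "B", "Y"], set())
        assert not definite and not open_

    def test_unshielded_circle_interior_is_definite_noncollider(self):
        g = MarkedGraph(["X", "B", "Y"])
        g.set_edge("X", "B", CIRCLE, CIRCLE)
        g.set_edge("B", "Y", CIRCLE, CIRCLE)
        definite, open_ = definite_status_open(g, ["X", "B", "Y"], set())
        assert definite and open_

    def test_non_path_rejected(self, chain_mag):
        with pytest.raises(GraphError):
            definite_status_open(chain_mag, ["A", "C"], set())
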