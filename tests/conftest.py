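"""Shared fixtures: small hand-built graphs and random-structure helpers."""

import itertools

import numpy as np
import pytest

from anchorfci.graph import (
    ABSENT,
    ARROWHEAD,
    CIRCLE,
    MAG,
    TAIL,
    MarkedGraph,
)


def directed(g, i, j):
    g.set_edge(i, j, TAIL, ARROWHEAD)


def bidirected(g, i, j):
    g.set_edge(i, j, ARROWHEAD, ARROWHEAD)


@pytest.fixture
def chain_mag():
    """A --> B --> C."""
    g = MAG(["A", "B", "C"])
    directed(g, "A", "B")
    directed(g, "B", "C")
    return g


@pytest.fixture
def collider_mag():
    """A --> C <-- B."""
    g = MAG(["A", "B", "C"])
    directed(g, "A", "C")
    directed(g, "B", "C")
    return g


def fig_example_mag():
    """The 8-node worked-example MAG with anchors G1-G3 and interest A-E.

    G1-->A, G2-->D, G3-->B, A-->C, B-->C, C<->E, B<->E, B<->D.
    """
    g = MAG(["G1", "G2", "G3", "A", "B", "C", "D", "E"])
    directed(g, "G1", "A")
    directed(g, "G2", "D")
    directed(g, "G3", "B")
    directed(g, "A", "C")
    directed(g, "B", "C")
    bidirected(g, "C", "E")
    bidirected(g, "B", "E")
    bidirected(g, "B", "D")
    return g


@pytest.fixture
def fig_mag():
    return fig_example_mag()


def random_mag(rng, n=6, p_edge=0.35, p_bidirected=0.3):
    """Random ancestral graph: directed edges respect a random order, plus
    bidirected edges between some non-ancestrally-related pairs."""
    nodes = [f"V{i}" for i in range(n)]
    order = list(rng.permutation(n))
    g = MAG(nodes)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p_edge:
                u, v = (a, b) if order.index(a) < order.index(b) else (b, a)
                if rng.random() < p_bidirected:
                    bidirected(g, nodes[u], nodes[v])
                else:
                    directed(g, nodes[u], nodes[v])
    # bidirected edges drawn this way cannot form almost-directed cycles with
    # the order-respecting directed edges unless a directed path u->..->v
    # exists; drop offending bidirected edges.
    from anchorfci.graph import is_valid_ancestral

    ok, viol = is_valid_ancestral(g)
    while not ok:
        seq = viol[0]
        g.remove_edge(seq[0], seq[1])
        ok, viol = is_valid_ancestral(g)
    return g


def random_dag(rng, n=7, p_edge=0.35):
    nodes = [f"V{i}" for i in range(n)]
    order = rng.permutation(n)
    g = MarkedGraph(nodes)
    pos = {v: k for k, v in enumerate(order)}
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p_edge:
                u, v = (a, b) if pos[a] < pos[b] else (b, a)
                directed(g, nodes[u], nodes[v])
    return g


# ---------------------------------------------------------------------------
# brute-force m-separation oracle (simple-path enumeration)


def _all_simple_paths(g, x, y):
    out = []

    def extend(path):
        u = path[-1]
        if u == y:
            out.append(list(path))
            return
        for v in g.adjacent(u):
            if v not in path:
                path.append(v)
                extend(path)
                path.pop()

    extend([x])
    return out


def brute_force_m_separated(g, x, y, Z):
    """Path-enumeration oracle for m-separation in an ancestral graph."""
    Z = set(Z)
    anZ = g.ancestors(Z) if Z else set()
    for path in _all_simple_paths(g, x, y):
        open_path = True
        for a, b, c in zip(path, path[1:], path[2:]):
            collider = g.mark(a, b) == ARROWHEAD and g.mark(c, b) == ARROWHEAD
            if collider:
                if b not in anZ:
                    open_path = False
                    break
            else:
                if b in Z:
                    open_path = False
                    break
        if open_path:
            return False
    return True


def all_queries(nodes, max_z=3):
    """All (x, y, Z) m-separation queries with |Z| <= max_z."""
    for x, y in itertools.combinations(nodes, 2):
        rest = [v for v in nodes if v not in (x, y)]
        for r in range(min(max_z, len(rest)) + 1):
            for Z in itertools.combinations(rest, r):
                yield x, y, set(Z)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
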