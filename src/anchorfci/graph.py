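"""Mixed-mark graphs: MAGs, PAGs, m-separation, latent projection, SHD.

Graphs are stored as an ``n x n`` integer mark matrix ``M`` where ``M[i, j]``
is the edge mark at the *j* endpoint of the edge between ``i`` and ``j``:

======  =========  =======================================
code    mark       meaning at that endpoint
======  =========  =======================================
0       ABSENT     no edge between i and j
1       CIRCLE     non-invariant mark (varies within MEC)
2       ARROWHEAD  j is *not* an ancestor of i
3       TAIL       j is an ancestor of i
======  =========  =======================================

so ``i --> j`` is ``M[i, j] = ARROWHEAD`` and ``M[j, i] = TAIL``, while
``i <-> j`` has arrowheads on both sides.  A maximal ancestral graph (MAG)
uses only arrowheads and tails and has no directed or almost-directed
cycle; a partial ancestral graph (PAG) additionally uses circles.
Selection bias (tail-tail edges) is not modelled.
"""

from __future__ import annotations

import itertools
from enum import IntEnum
from typing import Iterable, Iterator, Sequence

import numpy as np


class Mark(IntEnum):
    """Edge-endpoint mark.  Integer codes match the CSV serialization."""

    ABSENT = 0
    CIRCLE = 1
    ARROWHEAD = 2
    TAIL = 3


ABSENT = Mark.ABSENT
CIRCLE = Mark.CIRCLE
ARROWHEAD = Mark.ARROWHEAD
TAIL = Mark.TAIL

_MARK_GLYPH_LEFT = {CIRCLE: "o", ARROWHEAD: "<", TAIL: "-"}
_MARK_GLYPH_RIGHT = {CIRCLE: "o", ARROWHEAD: ">", TAIL: "-"}


class GraphError(ValueError):
    """Malformed graph structure or unknown node label."""


class MarkedGraph:
    """Graph over labelled nodes with per-endpoint edge marks.

    Parameters
    ----------
    nodes
        Ordered, unique node labels.
    marks
        Optional ``(n, n)`` integer matrix of `Mark` codes; defaults to the
        empty graph.  ``marks[i, j]`` is the mark at ``nodes[j]`` on the
        edge ``nodes[i] - nodes[j]``.
    """

    def __init__(self, nodes: Sequence[str], marks: np.ndarray | None = None):
        self.nodes: tuple[str, ...] = tuple(str(v) for v in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphError("node labels must be unique")
        self._ix = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        if marks is None:
            self.marks = np.zeros((n, n), dtype=np.int8)
        else:
            self.marks = np.asarray(marks, dtype=np.int8).copy()
            if self.marks.shape != (n, n):
                raise GraphError(f"mark matrix must be {n}x{n}")
            self._check_wellformed()

    # -- basic structure ---------------------------------------------------

    def _check_wellformed(self) -> None:
        M = self.marks
        if np.any(np.diag(M) != ABSENT):
            raise GraphError("self-loops are not allowed")
        if np.any((M == ABSENT) != (M.T == ABSENT)):
            raise GraphError("half-edges: ABSENT must be symmetric")
        if M.max() > 3 or M.min() < 0:
            raise GraphError("invalid mark code")

    def index(self, v: str) -> int:
        try:
            return self._ix[v]
        except KeyError:
            raise GraphError(f"unknown node label: {v!r}") from None

    def __contains__(self, v: str) -> bool:
        return v in self._ix

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def copy(self) -> "MarkedGraph":
        g = object.__new__(type(self))
        g.nodes = self.nodes
        g._ix = self._ix
        g.marks = self.marks.copy()
        return g

    def has_edge(self, i: str, j: str) -> bool:
        return self.marks[self.index(i), self.index(j)] != ABSENT

    def mark(self, i: str, j: str) -> Mark:
        """Mark at the ``j`` endpoint of edge ``i - j``."""
        return Mark(self.marks[self.index(i), self.index(j)])

    def set_edge(self, i: str, j: str, at_i: Mark, at_j: Mark) -> None:
        a, b = self.index(i), self.index(j)
        if a == b:
            raise GraphError("self-loops are not allowed")
        if (at_i == ABSENT) != (at_j == ABSENT):
            raise GraphError("half-edges are not allowed")
        self.marks[b, a] = at_i
        self.marks[a, b] = at_j

    def remove_edge(self, i: str, j: str) -> None:
        self.set_edge(i, j, ABSENT, ABSENT)

    def adjacent(self, v: str) -> list[str]:
        row = self.marks[self.index(v)]
        return [self.nodes[k] for k in np.nonzero(row)[0]]

    def edges(self) -> Iterator[tuple[str, str]]:
        """Unordered adjacent pairs, each once, in node order."""
        n = self.n_nodes
        for a in range(n):
            for b in range(a + 1, n):
                if self.marks[a, b] != ABSENT:
                    yield self.nodes[a], self.nodes[b]

    def edge_type(self, i: str, j: str) -> str:
        """Human-readable edge glyph, e.g. ``'-->'``, ``'o->'``, ``'<->'``."""
        if not self.has_edge(i, j):
            return "   "
        return (
            _MARK_GLYPH_LEFT[self.mark(j, i)] + "-" + _MARK_GLYPH_RIGHT[self.mark(i, j)]
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MarkedGraph)
            and self.nodes == other.nodes
            and np.array_equal(self.marks, other.marks)
        )

    def __repr__(self) -> str:
        es = ", ".join(f"{i} {self.edge_type(i, j)} {j}" for i, j in self.edges())
        return f"<{type(self).__name__} |V|={self.n_nodes}: {es}>"

    # -- ancestry ----------------------------------------------------------

    def _directed_children(self, a: int) -> np.ndarray:
        """Indices j with a --> j (tail at a, arrowhead at j)."""
        return np.nonzero((self.marks[:, a] == TAIL) & (self.marks[a, :] == ARROWHEAD))[0]

    def ancestors(self, targets: Iterable[str]) -> set[str]:
        """Nodes with a directed path (via --> edges) into ``targets``, incl. targets."""
        idx = {self.index(t) for t in targets}
        # parents: i --> t  <=>  marks[i, t] == ARROWHEAD and marks[t, i] == TAIL
        stack = list(idx)
        seen = set(idx)
        while stack:
            t = stack.pop()
            parents = np.nonzero((self.marks[:, t] == ARROWHEAD) & (self.marks[t, :] == TAIL))[0]
            for p in parents:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return {self.nodes[k] for k in seen}

    def to_dot(self, name: str = "g") -> str:
        """Graphviz DOT with mark-decorated arrow ends."""
        arrow = {CIRCLE: "odot", ARROWHEAD: "normal", TAIL: "none"}
        lines = [f"graph {name} {{", "  edge [dir=both];"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for i, j in self.edges():
            lines.append(
                f'  "{i}" -- "{j}" [arrowtail={arrow[self.mark(j, i)]}, '
                f"arrowhead={arrow[self.mark(i, j)]}];"
            )
        lines.append("}")
        return "\n".join(lines)


class MAG(MarkedGraph):
    """Maximal ancestral graph: marks in {ABSENT, ARROWHEAD, TAIL}, ancestral."""

    def validate(self) -> None:
        if np.any(self.marks == CIRCLE):
            raise GraphError("MAG may not contain circle marks")
        ok, cycles = is_valid_ancestral(self)
        if not ok:
            raise GraphError(f"not ancestral; offending sequences: {cycles}")


class PAG(MarkedGraph):
    """Partial ancestral graph: any marks; definite edges must be ancestral."""

    def validate(self) -> None:
        ok, cycles = is_valid_ancestral(self)
        if not ok:
            raise GraphError(f"definite edges not ancestral: {cycles}")


# ---------------------------------------------------------------------------
# ancestral validity


def is_valid_ancestral(g: MarkedGraph) -> tuple[bool, list[tuple[str, ...]]]:
    """Check the definite edges of ``g`` for (almost-)directed cycles.

    A directed cycle is ``x --> ... --> x``; an almost-directed cycle is a
    bidirected edge ``x <-> y`` together with a directed path ``x --> ... --> y``.
    Returns ``(ok, violations)`` where each violation is the offending node
    sequence.
    """
    n = g.n_nodes
    children = [set(g._directed_children(a)) for a in range(n)]
    # reach[a] = set of b with a directed path a --> ... --> b (length >= 1)
    reach: list[set[int]] = []
    for a in range(n):
        seen: set[int] = set()
        stack = list(children[a])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(children[t])
        reach.append(seen)

    violations: list[tuple[str, ...]] = []

    def _dir_path(a: int, b: int) -> list[int]:
        # reconstruct one directed path a -> ... -> b (b may equal a: a cycle)
        prev: dict[int, int] = {}
        visited = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for c in children[u]:
                if c == b:
                    path = [b]
                    cur = u
                    while cur != a:
                        path.append(cur)
                        cur = prev[cur]
                    path.append(a)
                    return path[::-1]
                if c not in visited:
                    visited.add(c)
                    prev[c] = u
                    stack.append(c)
        return [a, b]  # unreachable in practice

    for a in range(n):
        if a in reach[a]:  # directed cycle through a
            cyc = _dir_path(a, a)
            violations.append(tuple(g.nodes[k] for k in cyc))
    for a in range(n):
        for b in range(n):
            if a != b and g.marks[a, b] == ARROWHEAD and g.marks[b, a] == ARROWHEAD:
                if b in reach[a]:  # a <-> b but a --> ... --> b
                    path = _dir_path(a, b)
                    violations.append(tuple(g.nodes[k] for k in path) + (g.nodes[a],))
    # deduplicate rotations/reverses crudely by frozenset of nodes + length
    seen_keys = set()
    uniq = []
    for v in violations:
        key = (frozenset(v), len(v))
        if key not in seen_keys:
            seen_keys.add(key)
            uniq.append(v)
    return (len(uniq) == 0), uniq


# ---------------------------------------------------------------------------
# m-separation


def m_separated(g: MarkedGraph, x: str, y: str, Z: Iterable[str]) -> bool:
    """Is ``x`` m-separated from ``y`` given ``Z`` in the ancestral graph ``g``?

    A path is m-connecting given Z iff every non-collider on it is outside Z
    and every collider on it is an ancestor of Z (itself included).  The
    implementation is a BFS over directed edge states (walk reachability,
    which is equivalent to path reachability for m-connection).
    """
    Z = set(Z)
    xi, yi = g.index(x), g.index(y)
    if x == y:
        raise GraphError("x and y must differ")
    if x in Z or y in Z:
        raise GraphError("x and y must not be in Z")
    zi = {g.index(z) for z in Z}
    anz = {g.index(v) for v in g.ancestors(Z)} if Z else set()

    M = g.marks
    n = g.n_nodes
    adj = [np.nonzero(M[a])[0] for a in range(n)]
    # state: (prev, cur) meaning we arrived at cur along edge prev-cur
    from collections import deque

    seen = set()
    queue: deque[tuple[int, int]] = deque()
    for w in adj[xi]:
        queue.append((xi, w))
        seen.add((xi, w))
    while queue:
        u, w = queue.popleft()
        if w == yi:
            return False
        for v in adj[w]:
            if v == u:
                continue
            collider = M[u, w] == ARROWHEAD and M[v, w] == ARROWHEAD
            if collider:
                if w not in anz:
                    continue
            else:
                if w in zi:
                    continue
            if (w, v) not in seen:
                seen.add((w, v))
                queue.append((w, v))
    return True


# ---------------------------------------------------------------------------
# latent projection DAG -> MAG


def latent_project(dag: MarkedGraph, latent: Iterable[str]) -> MAG:
    """Project a DAG over observed + latent nodes onto its observed MAG.

    Two observed nodes are adjacent in the MAG iff no subset of the other
    observed nodes d-separates them in the DAG; the endpoint at ``a`` is a
    tail iff ``a`` is an ancestor of the other endpoint in the DAG (through
    any nodes), otherwise an arrowhead.
    """
    import networkx as nx

    latent = set(latent)
    for v in latent:
        dag.index(v)
    ok, cycles = is_valid_ancestral(dag)
    if not ok:
        raise GraphError(f"input is cyclic: {cycles}")
    for i, j in dag.edges():
        if {dag.mark(i, j), dag.mark(j, i)} != {ARROWHEAD, TAIL}:
            raise GraphError(f"input must be a DAG (all edges directed): {i}-{j}")

    observed = [v for v in dag.nodes if v not in latent]
    D = nx.DiGraph()
    D.add_nodes_from(dag.nodes)
    for i, j in dag.edges():
        if dag.mark(i, j) == ARROWHEAD:
            D.add_edge(i, j)
        else:
            D.add_edge(j, i)

    anc = {v: nx.ancestors(D, v) | {v} for v in dag.nodes}
    mag = MAG(observed)
    for a, b in itertools.combinations(observed, 2):
        others = [o for o in observed if o not in (a, b)]
        separable = False
        for r in range(len(others) + 1):
            for S in itertools.combinations(others, r):
                if nx.is_d_separator(D, {a}, {b}, set(S)):
                    separable = True
                    break
            if separable:
                break
        if not separable:
            # tail at a iff a is an ancestor of b in the full DAG
            at_a = TAIL if a in anc[b] else ARROWHEAD
            at_b = TAIL if b in anc[a] else ARROWHEAD
            mag.set_edge(a, b, at_a, at_b)
    return mag


# ---------------------------------------------------------------------------
# structural Hamming distance


def shd(g1: MarkedGraph, g2: MarkedGraph, subset: Iterable[str] | None = None) -> int:
    """Structural Hamming distance restricted to pairs within ``subset``.

    +1 if the adjacency of a pair differs; if both graphs have the edge,
    +1 for each endpoint whose mark differs (0-2).
    """
    if subset is None:
        if set(g1.nodes) != set(g2.nodes):
            raise GraphError("graphs must share node labels")
        subset = list(g1.nodes)
    else:
        subset = list(subset)
    for v in subset:
        g1.index(v), g2.index(v)
    d = 0
    for a, b in itertools.combinations(subset, 2):
        e1, e2 = g1.has_edge(a, b), g2.has_edge(a, b)
        if e1 != e2:
            d += 1
        elif e1:
            d += int(g1.mark(a, b) != g2.mark(a, b))
            d += int(g1.mark(b, a) != g2.mark(b, a))
    return d


# ---------------------------------------------------------------------------
# PAG path utilities


def _pd_edge(g: MarkedGraph, u: int, v: int) -> bool:
    """Edge u-v traversable on a possibly-directed path from u to v."""
    return (
        g.marks[u, v] != ABSENT
        and g.marks[v, u] != ARROWHEAD  # no arrowhead at u
        and g.marks[u, v] != TAIL  # no tail at v
    )


def possible_descendants(p: MarkedGraph, x: str) -> set[str]:
    """``x`` plus every node reachable by a possibly-directed path from ``x``."""
    xi = p.index(x)
    seen = {xi}
    stack = [xi]
    while stack:
        u = stack.pop()
        for v in range(p.n_nodes):
            if v not in seen and _pd_edge(p, u, v):
                seen.add(v)
                stack.append(v)
    return {p.nodes[k] for k in seen}


def definite_status_open(
    p: MarkedGraph, path: Sequence[str], Z: Iterable[str]
) -> tuple[bool, bool]:
    """Evaluate a PAG path: is it of definite status, and is it open given Z?

    An interior node is a definite collider if both path edges carry
    arrowheads at it; a definite non-collider if one edge carries a tail at
    it, or both marks at it are circles and its path neighbours are
    non-adjacent.  If any interior node is of neither kind the path is not
    of definite status (second return value is then False).

    Openness: definite non-colliders must be outside Z; colliders must have
    a possible descendant in Z.

    Returns ``(definite_status, open_given_Z)``.
    """
    Z = set(Z)
    if len(path) < 2:
        raise GraphError("path must have at least two nodes")
    for u, v in zip(path, path[1:]):
        if not p.has_edge(u, v):
            raise GraphError(f"not a path: {u} and {v} are not adjacent")
    if len(set(path)) != len(path):
        raise GraphError("path must not repeat nodes")

    definite = True
    open_ = True
    pd_cache: dict[str, set[str]] = {}
    for a, b, c in zip(path, path[1:], path[2:]):
        m_ab = p.mark(a, b)  # mark at b on a-b
        m_cb = p.mark(c, b)  # mark at b on c-b
        if m_ab == ARROWHEAD and m_cb == ARROWHEAD:
            # collider
            if b not in pd_cache:
                pd_cache[b] = possible_descendants(p, b)
            if not (pd_cache[b] & Z):
                open_ = False
        elif TAIL in (m_ab, m_cb) or (
            m_ab == CIRCLE and m_cb == CIRCLE and not p.has_edge(a, c)
        ):
            # definite non-collider
            if b in Z:
                open_ = False
        else:
            definite = False
    return definite, (definite and open_)
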