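"""Constraint-based discovery core (conservative RFCI-style).

Test-agnostic: everything here consumes a CI tester with the
``test(i, j, S) -> CITestResult`` contract (finite-sample mixed tester or
m-separation oracle) and produces a PAG.  Stages:

1. order-independent ("stable") skeleton with a conditioning-set size cap
   and an optional filter vetoing forbidden (pair, conditioning set)
   combinations;
2. RFCI unshielded-triple retention checks with minimal-sepset shrinking;
3. conservative classification of unshielded triples by the majority rule;
4. collider orientation (R0), optional background arrowheads, and the
   complete orientation rule set R1-R10 applied to a fixed point
   (R5-R7 only when selection-bias modelling is enabled).

Ambiguous triples never drive an orientation.  Conflicting definite-mark
demands keep the earlier mark, are logged, and flag the run as unstable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from .graph import (
    ABSENT,
    ARROWHEAD,
    CIRCLE,
    PAG,
    TAIL,
    GraphError,
    MarkedGraph,
    is_valid_ancestral,
)

logger = logging.getLogger(__name__)

# filter contract: (i, j, S) -> True when the test is forbidden
ConditionFilter = Callable[[str, str, frozenset], bool]


@dataclass
class DiscoveryConfig:
    """Tuning knobs of the discovery engine.

    alpha : significance level of the CI tests (no multiplicity correction).
    max_cond_size : cap on conditioning-set size, ``None`` for unlimited;
        fixed covariates inside the tester never count toward the cap.
    majority_rule : classify unshielded triples conservatively by the
        majority of separating sets; when off, use sepset membership alone.
    selection_bias_rules : enable orientation rules R5-R7 (only meaningful
        when selection bias is modelled; off by default).
    """

    alpha: float = 0.05
    max_cond_size: int | None = None
    majority_rule: bool = True
    selection_bias_rules: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_cond_size is not None and self.max_cond_size < 0:
            raise ValueError("max_cond_size must be >= 0")


class TripleStatus(Enum):
    COLLIDER = "collider"
    NONCOLLIDER = "noncollider"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class TripleRecord:
    status: TripleStatus
    vote_fraction: float  # share of separating sets containing the middle node
    n_sepsets: int


class SepsetStore(dict):
    """Map of unordered non-adjacent pair -> (separating set, p-value)."""

    @staticmethod
    def _key(i: str, j: str) -> frozenset:
        return frozenset((i, j))

    def put(self, i: str, j: str, S: Iterable[str], p: float) -> None:
        self[self._key(i, j)] = (frozenset(S), float(p))

    def get_set(self, i: str, j: str) -> frozenset | None:
        entry = self.get(self._key(i, j))
        return entry[0] if entry else None

    def to_jsonable(self) -> dict:
        return {
            "|".join(sorted(k)): {"sepset": sorted(v[0]), "p": v[1]}
            for k, v in self.items()
        }


class TripleTable(dict):
    """Map of unshielded triple <i, k, j> (i < j canonically) -> TripleRecord."""

    @staticmethod
    def _key(i: str, k: str, j: str) -> tuple[str, str, str]:
        a, b = sorted((i, j))
        return (a, k, b)

    def put(self, i: str, k: str, j: str, rec: TripleRecord) -> None:
        self[self._key(i, k, j)] = rec

    def status(self, i: str, k: str, j: str) -> TripleStatus | None:
        rec = self.get(self._key(i, k, j))
        return rec.status if rec else None

    def is_ambiguous(self, i: str, k: str, j: str) -> bool:
        return self.status(i, k, j) == TripleStatus.AMBIGUOUS

    def to_jsonable(self) -> dict:
        return {
            "<%s,%s,%s>" % k: {
                "status": v.status.value,
                "vote_fraction": v.vote_fraction,
                "n_sepsets": v.n_sepsets,
            }
            for k, v in self.items()
        }


@dataclass
class DiscoveryResult:
    """Engine output: PAG plus the evidence that produced it."""

    pag: PAG
    skeleton: MarkedGraph
    sepsets: SepsetStore
    triples: TripleTable
    rule_log: list = field(default_factory=list)
    conflicts: list = field(default_factory=list)
    n_tests: int = 0

    @property
    def unstable(self) -> bool:
        return len(self.conflicts) > 0


# ---------------------------------------------------------------------------
# stage 1: stable skeleton


def stable_skeleton(
    tester,
    nodes: Sequence[str],
    config: DiscoveryConfig,
    condition_filter: ConditionFilter | None = None,
) -> tuple[MarkedGraph, SepsetStore]:
    """Order-independent skeleton search with level-wise frozen adjacencies.

    Starts from the complete graph (all circle marks).  At level ``l`` the
    adjacency sets are frozen before any removal, so the output does not
    depend on variable order.  Candidate conditioning sets of size ``l``
    are drawn from the frozen adjacencies of both endpoints; combinations
    vetoed by ``condition_filter`` are skipped.  An edge is removed at the
    first set with merged p-value above alpha, which is stored as the
    pair's (minimal) separating set.
    """
    nodes = sorted(nodes)
    g = MarkedGraph(nodes)
    for a, b in itertools.combinations(nodes, 2):
        g.set_edge(a, b, CIRCLE, CIRCLE)
    sepsets = SepsetStore()

    level = 0
    while True:
        if config.max_cond_size is not None and level > config.max_cond_size:
            break
        frozen_adj = {v: sorted(g.adjacent(v)) for v in nodes}
        if all(len(frozen_adj[v]) - 1 < level for v in nodes):
            break
        for i, j in itertools.combinations(nodes, 2):
            if not g.has_edge(i, j):
                continue
            candidates: list[frozenset] = []
            seen: set[frozenset] = set()
            for side, other in ((i, j), (j, i)):
                pool = [v for v in frozen_adj[side] if v != other]
                for S in itertools.combinations(pool, level):
                    fs = frozenset(S)
                    if fs not in seen:
                        seen.add(fs)
                        candidates.append(fs)
            for S in candidates:
                if condition_filter is not None and condition_filter(i, j, S):
                    continue
                res = tester.test(i, j, S)
                if res.p_merged > config.alpha:
                    g.remove_edge(i, j)
                    sepsets.put(i, j, S, res.p_merged)
                    break
        level += 1
    return g, sepsets


# ---------------------------------------------------------------------------
# stage 2: RFCI unshielded-triple retention


def _unshielded_triples(g: MarkedGraph) -> list[tuple[str, str, str]]:
    """All <i, k, j> with i-k, k-j adjacent, i-j not, canonical i < j."""
    out = []
    for k in g.nodes:
        adj = sorted(g.adjacent(k))
        for i, j in itertools.combinations(adj, 2):
            if not g.has_edge(i, j):
                out.append((i, k, j))
    return out


def _shrink_sepset(
    tester, x: str, y: str, S: frozenset, alpha: float,
    condition_filter: ConditionFilter | None,
) -> tuple[frozenset, float]:
    """Greedily remove elements of S while x and y stay independent."""
    S = frozenset(S)
    res = tester.test(x, y, S)
    p = res.p_merged
    changed = True
    while changed:
        changed = False
        for v in sorted(S):
            cand = S - {v}
            if condition_filter is not None and condition_filter(x, y, cand):
                continue
            r = tester.test(x, y, cand)
            if r.p_merged > alpha:
                S, p = cand, r.p_merged
                changed = True
                break
    return S, p


def rfci_triple_retention(
    g: MarkedGraph,
    sepsets: SepsetStore,
    tester,
    config: DiscoveryConfig,
    condition_filter: ConditionFilter | None = None,
) -> MarkedGraph:
    """RFCI check of every unshielded triple before orientation.

    For <i, k, j> with separating set S = sepset(i, j), both i _||_ k | S
    and j _||_ k | S are tested; a discovered independence removes that
    edge and stores a minimal separating set obtained by iterative
    shrinking.  Repeats until no triple triggers a removal.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for i, k, j in _unshielded_triples(g):
            S = sepsets.get_set(i, j)
            if S is None:
                continue
            for x, y in ((i, k), (j, k)):
                if not g.has_edge(x, y):
                    continue
                cond = frozenset(S - {x, y})
                if condition_filter is not None and condition_filter(x, y, cond):
                    continue
                res = tester.test(x, y, cond)
                if res.p_merged > config.alpha:
                    g.remove_edge(x, y)
                    Smin, p = _shrink_sepset(
                        tester, x, y, cond, config.alpha, condition_filter
                    )
                    sepsets.put(x, y, Smin, p)
                    changed = True
        # loop again: removals may create new unshielded triples
    return g


# ---------------------------------------------------------------------------
# stage 3: conservative majority-rule triple classification


def classify_triples_majority(
    g: MarkedGraph,
    sepsets: SepsetStore,
    tester,
    config: DiscoveryConfig,
    condition_filter: ConditionFilter | None = None,
) -> TripleTable:
    """Classify every unshielded triple as collider / non-collider / ambiguous.

    With the majority rule, all subsets of each endpoint's adjacency (up to
    the conditioning cap) are tested; among those separating i and j, the
    fraction q containing the middle node decides: q < 1/2 collider,
    q > 1/2 non-collider, q = 1/2 ambiguous.  If no separating subset is
    found, membership of the middle node in the stored sepset decides.
    Without the majority rule, the stored sepset alone decides.
    """
    table = TripleTable()
    for i, k, j in _unshielded_triples(g):
        stored = sepsets.get_set(i, j)
        if stored is None:
            stored = frozenset()
        if not config.majority_rule:
            status = (
                TripleStatus.NONCOLLIDER if k in stored else TripleStatus.COLLIDER
            )
            table.put(i, k, j, TripleRecord(status, float(k in stored), 1))
            continue

        cap = config.max_cond_size
        seen: set[frozenset] = set()
        separating: list[frozenset] = []
        for side, other in ((i, j), (j, i)):
            pool = sorted(v for v in g.adjacent(side) if v != other)
            max_r = len(pool) if cap is None else min(cap, len(pool))
            for r in range(max_r + 1):
                for S in itertools.combinations(pool, r):
                    fs = frozenset(S)
                    if fs in seen:
                        continue
                    seen.add(fs)
                    if condition_filter is not None and condition_filter(i, j, fs):
                        continue
                    if tester.test(i, j, fs).p_merged > config.alpha:
                        separating.append(fs)
        if not separating:
            status = (
                TripleStatus.NONCOLLIDER if k in stored else TripleStatus.COLLIDER
            )
            table.put(i, k, j, TripleRecord(status, float(k in stored), 0))
            continue
        with_k = sum(1 for S in separating if k in S)
        total = len(separating)
        if 2 * with_k < total:
            status = TripleStatus.COLLIDER
        elif 2 * with_k > total:
            status = TripleStatus.NONCOLLIDER
        else:
            status = TripleStatus.AMBIGUOUS
        table.put(i, k, j, TripleRecord(status, with_k / total, total))
    return table


# ---------------------------------------------------------------------------
# stage 4: orientation


def orient_v_structures(g: MarkedGraph, triples: TripleTable) -> PAG:
    """R0: arrowheads at the middle node of every unambiguous collider triple."""
    pag = PAG(g.nodes, g.marks)
    for (i, k, j), rec in triples.items():
        if rec.status == TripleStatus.COLLIDER:
            if pag.has_edge(i, k):
                pag.marks[pag.index(i), pag.index(k)] = ARROWHEAD
            if pag.has_edge(j, k):
                pag.marks[pag.index(j), pag.index(k)] = ARROWHEAD
    return pag


class _Orienter:
    """Fixed-point application of rules R1-R10 with conflict bookkeeping."""

    def __init__(
        self,
        pag: PAG,
        triples: TripleTable,
        sepsets: SepsetStore,
        config: DiscoveryConfig,
    ):
        self.g = pag
        self.triples = triples
        self.sepsets = sepsets
        self.config = config
        self.rule_log: list[tuple] = []
        self.conflicts: list[tuple] = []

    # -- mark helpers ------------------------------------------------------

    def mark(self, i: str, j: str):
        return self.g.mark(i, j)

    def set_mark(self, i: str, j: str, mark, rule: str) -> bool:
        """Set the mark at j on edge i-j; definite marks are never overwritten."""
        cur = self.g.mark(i, j)
        if cur == mark:
            return False
        if cur == ABSENT:
            raise GraphError(f"no edge {i}-{j} to orient ({rule})")
        if cur in (ARROWHEAD, TAIL):
            self.conflicts.append((i, j, int(cur), int(mark), rule))
            logger.warning(
                "orientation conflict at %s on edge %s-%s: %s wants %s, keeping %s",
                j, i, j, rule, mark, cur,
            )
            return False
        self.g.marks[self.g.index(i), self.g.index(j)] = mark
        self.rule_log.append((rule, i, j, int(mark)))
        return True

    def ambiguous(self, a: str, b: str, c: str) -> bool:
        return self.triples.is_ambiguous(a, b, c)

    def adj(self, v: str) -> list[str]:
        return sorted(self.g.adjacent(v))

    # -- rules -------------------------------------------------------------

    def r1(self) -> bool:
        """a*->b o-* c, a and c non-adjacent, unambiguous => b --> c."""
        changed = False
        g = self.g
        for b in g.nodes:
            for a in self.adj(b):
                if g.mark(a, b) != ARROWHEAD:
                    continue
                for c in self.adj(b):
                    if c == a or g.has_edge(a, c):
                        continue
                    if g.mark(c, b) != CIRCLE:
                        continue
                    if self.ambiguous(a, b, c):
                        continue
                    changed |= self.set_mark(b, c, ARROWHEAD, "R1")
                    changed |= self.set_mark(c, b, TAIL, "R1")
        return changed

    def r2(self) -> bool:
        """a->b*->c or a*->b->c, and a*-o c => a*->c."""
        changed = False
        g = self.g
        for a, c in itertools.permutations(g.nodes, 2):
            if not g.has_edge(a, c) or g.mark(a, c) != CIRCLE:
                continue
            for b in self.adj(a):
                if b == c or not g.has_edge(b, c):
                    continue
                chain1 = (
                    g.mark(a, b) == ARROWHEAD
                    and g.mark(b, a) == TAIL
                    and g.mark(b, c) == ARROWHEAD
                )
                chain2 = (
                    g.mark(a, b) == ARROWHEAD
                    and g.mark(b, c) == ARROWHEAD
                    and g.mark(c, b) == TAIL
                )
                if chain1 or chain2:
                    changed |= self.set_mark(a, c, ARROWHEAD, "R2")
                    break
        return changed

    def r3(self) -> bool:
        """a*->b<-*c, a*-o d o-*c, a,c non-adjacent, d*-o b, unambiguous <a,d,c>
        => d*->b."""
        changed = False
        g = self.g
        for b in g.nodes:
            heads = [a for a in self.adj(b) if g.mark(a, b) == ARROWHEAD]
            for a, c in itertools.combinations(heads, 2):
                if g.has_edge(a, c):
                    continue
                for d in self.adj(b):
                    if d in (a, c) or g.mark(d, b) != CIRCLE:
                        continue
                    if not (g.has_edge(a, d) and g.has_edge(c, d)):
                        continue
                    if g.mark(a, d) != CIRCLE or g.mark(c, d) != CIRCLE:
                        continue
                    if self.ambiguous(a, d, c):
                        continue
                    changed |= self.set_mark(d, b, ARROWHEAD, "R3")
        return changed

    def _discriminating_d(self, a: str, b: str, c: str) -> str | None:
        """Search for the far endpoint d of a discriminating path <d,...,a,b>
        for b w.r.t. c: every interior vertex is a collider on the path and a
        parent of c; d is not adjacent to c."""
        g = self.g

        def parent_of_c(w: str) -> bool:
            return (
                g.has_edge(w, c)
                and g.mark(w, c) == ARROWHEAD
                and g.mark(c, w) == TAIL
            )

        stack: list[tuple[str, frozenset]] = [(a, frozenset((a, b, c)))]
        while stack:
            u, visited = stack.pop()
            for w in self.adj(u):
                if w in visited:
                    continue
                if g.mark(w, u) != ARROWHEAD:  # need w *-> u
                    continue
                if not g.has_edge(w, c):
                    return w  # found d
                if parent_of_c(w) and g.mark(u, w) == ARROWHEAD:
                    stack.append((w, visited | {w}))
        return None

    def r4(self) -> bool:
        """Discriminating path rule, decided by the stored sepset of (d, c)."""
        changed = False
        g = self.g
        for b, c in itertools.permutations(g.nodes, 2):
            if not g.has_edge(b, c) or g.mark(c, b) != CIRCLE:
                continue
            for a in self.adj(b):
                if a == c or not g.has_edge(a, c):
                    continue
                # a must be a collider on the path (arrowhead at a from the
                # b side; the d side is checked in the search) and a parent of c
                if g.mark(b, a) != ARROWHEAD:
                    continue
                if not (g.mark(a, c) == ARROWHEAD and g.mark(c, a) == TAIL):
                    continue
                d = self._discriminating_d(a, b, c)
                if d is None:
                    continue
                S = self.sepsets.get_set(d, c)
                if S is None:
                    continue
                if b in S:
                    fired = self.set_mark(b, c, ARROWHEAD, "R4")
                    fired |= self.set_mark(c, b, TAIL, "R4")
                else:
                    fired = self.set_mark(a, b, ARROWHEAD, "R4")
                    fired |= self.set_mark(b, a, ARROWHEAD, "R4")
                    fired |= self.set_mark(c, b, ARROWHEAD, "R4")
                if fired:
                    logger.debug("R4 fired on path d=%s .. %s %s %s", d, a, b, c)
                    changed = True
        return changed

    # R5-R7 only matter under selection bias (tail-tail edges); gated.

    def _uncovered_circle_path(self, a: str, b: str) -> list[str] | None:
        g = self.g

        def circ(u: str, v: str) -> bool:
            return g.mark(u, v) == CIRCLE and g.mark(v, u) == CIRCLE

        stack = [[a, w] for w in self.adj(a) if w != b and circ(a, w)]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u == b:
                if len(path) >= 4:
                    return path
                continue
            for w in self.adj(u):
                if w in path or not circ(u, w):
                    continue
                if len(path) >= 2 and g.has_edge(path[-2], w):
                    continue  # covered step
                stack.append(path + [w])
        return None

    def r5(self) -> bool:
        """a o-o b with an uncovered circle path: orient everything tail-tail."""
        changed = False
        g = self.g
        for a, b in itertools.combinations(g.nodes, 2):
            if not g.has_edge(a, b):
                continue
            if g.mark(a, b) != CIRCLE or g.mark(b, a) != CIRCLE:
                continue
            path = self._uncovered_circle_path(a, b)
            if path is None:
                continue
            if g.has_edge(path[1], b) or g.has_edge(path[-2], a):
                continue
            edges = [(a, b)] + list(zip(path, path[1:]))
            for u, v in edges:
                changed |= self.set_mark(u, v, TAIL, "R5")
                changed |= self.set_mark(v, u, TAIL, "R5")
        return changed

    def r6(self) -> bool:
        """a - b o-* c (a-b undirected) => tail at b on b-c."""
        changed = False
        g = self.g
        for b in g.nodes:
            und = [
                a for a in self.adj(b)
                if g.mark(a, b) == TAIL and g.mark(b, a) == TAIL
            ]
            if not und:
                continue
            for c in self.adj(b):
                if c in und or g.mark(c, b) != CIRCLE:
                    continue
                changed |= self.set_mark(c, b, TAIL, "R6")
        return changed

    def r7(self) -> bool:
        """a -o b o-* c, a,c non-adjacent, unambiguous => tail at b on b-c."""
        changed = False
        g = self.g
        for b in g.nodes:
            for a in self.adj(b):
                if not (g.mark(a, b) == CIRCLE and g.mark(b, a) == TAIL):
                    continue
                for c in self.adj(b):
                    if c == a or g.has_edge(a, c):
                        continue
                    if g.mark(c, b) != CIRCLE:
                        continue
                    if self.ambiguous(a, b, c):
                        continue
                    changed |= self.set_mark(c, b, TAIL, "R7")
        return changed

    def r8(self) -> bool:
        """a->b->c and a o-> c => a --> c (tail at a)."""
        changed = False
        g = self.g
        for a, c in itertools.permutations(g.nodes, 2):
            if not g.has_edge(a, c):
                continue
            if not (g.mark(a, c) == ARROWHEAD and g.mark(c, a) == CIRCLE):
                continue
            for b in self.adj(a):
                if b == c or not g.has_edge(b, c):
                    continue
                ab_dir = g.mark(a, b) == ARROWHEAD and g.mark(b, a) == TAIL
                bc_dir = g.mark(b, c) == ARROWHEAD and g.mark(c, b) == TAIL
                if ab_dir and bc_dir:
                    changed |= self.set_mark(c, a, TAIL, "R8")
                    break
        return changed

    def _uncovered_pd_paths(self, a: str, targets: set[str], skip_edge: str):
        """Uncovered possibly-directed paths from a to any target, not using
        the direct a-skip_edge edge as first step."""
        g = self.g

        def pd(u: str, v: str) -> bool:
            return g.mark(v, u) != ARROWHEAD and g.mark(u, v) != TAIL

        found = []
        stack = [[a, w] for w in self.adj(a) if w != skip_edge and pd(a, w)]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u in targets:
                found.append(path)
                continue
            for w in self.adj(u):
                if w in path or not pd(u, w):
                    continue
                if g.has_edge(path[-2], w):
                    continue  # keep the path uncovered
                stack.append(path + [w])
        return found

    def r9(self) -> bool:
        """a o-> c with an uncovered p.d. path a..c avoiding adj(c) start
        => tail at a."""
        changed = False
        g = self.g
        for a, c in itertools.permutations(g.nodes, 2):
            if not g.has_edge(a, c):
                continue
            if not (g.mark(a, c) == ARROWHEAD and g.mark(c, a) == CIRCLE):
                continue
            for path in self._uncovered_pd_paths(a, {c}, skip_edge=c):
                if len(path) >= 3 and not g.has_edge(path[1], c):
                    changed |= self.set_mark(c, a, TAIL, "R9")
                    break
        return changed

    def r10(self) -> bool:
        """a o-> c, b --> c <-- d, uncovered p.d. paths a..b and a..d whose
        first edges diverge into non-adjacent vertices => tail at a."""
        changed = False
        g = self.g
        for a, c in itertools.permutations(g.nodes, 2):
            if not g.has_edge(a, c):
                continue
            if not (g.mark(a, c) == ARROWHEAD and g.mark(c, a) == CIRCLE):
                continue
            parents = [
                b for b in self.adj(c)
                if b != a and g.mark(b, c) == ARROWHEAD and g.mark(c, b) == TAIL
            ]
            done = False
            for b, d in itertools.combinations(parents, 2):
                paths_b = self._uncovered_pd_paths(a, {b}, skip_edge=c)
                paths_d = self._uncovered_pd_paths(a, {d}, skip_edge=c)
                for p1 in paths_b:
                    for p2 in paths_d:
                        mu, om = p1[1], p2[1]
                        if mu != om and not g.has_edge(mu, om):
                            changed |= self.set_mark(c, a, TAIL, "R10")
                            done = True
                            break
                    if done:
                        break
                if done:
                    break
        return changed

    # -- driver ------------------------------------------------------------

    def run(self) -> None:
        rules = [self.r1, self.r2, self.r3, self.r4]
        if self.config.selection_bias_rules:
            rules += [self.r5, self.r6, self.r7]
        rules += [self.r8, self.r9, self.r10]
        changed = True
        while changed:
            changed = False
            for rule in rules:
                changed |= rule()


def apply_orientation_rules(
    pag: PAG,
    triples: TripleTable,
    sepsets: SepsetStore,
    config: DiscoveryConfig,
    background_arrowheads: Iterable[tuple[str, str]] = (),
) -> tuple[PAG, list, list]:
    """Apply background arrowheads then rules R1-R10 to a fixed point.

    ``background_arrowheads`` are (i, j) pairs demanding an arrowhead at j
    on the edge i-j (enforced non-ancestral knowledge); a pre-existing tail
    there raises, as it contradicts the background knowledge.  Returns the
    oriented PAG, the rule-firing log, and the conflict list.  Raises
    ``GraphError`` if the definite edges of the result are not ancestral.
    """
    pag = PAG(pag.nodes, pag.marks)
    for i, j in background_arrowheads:
        if not pag.has_edge(i, j):
            continue
        if pag.mark(i, j) == TAIL:
            raise GraphError(
                f"non-ancestral knowledge violated: tail at {j} on edge {i}-{j}"
            )
        pag.marks[pag.index(i), pag.index(j)] = ARROWHEAD
    orienter = _Orienter(pag, triples, sepsets, config)
    orienter.run()
    ok, violations = is_valid_ancestral(pag)
    if not ok:
        raise GraphError(
            f"oriented PAG is not ancestral: {violations}; "
            f"rule trace: {orienter.rule_log}"
        )
    return pag, orienter.rule_log, orienter.conflicts


# ---------------------------------------------------------------------------
# full engine run


def run_discovery(
    tester,
    nodes: Sequence[str],
    config: DiscoveryConfig | None = None,
    condition_filter: ConditionFilter | None = None,
    background_arrowheads: Iterable[tuple[str, str]] = (),
) -> DiscoveryResult:
    """Skeleton -> retention -> triple classification -> orientation."""
    config = config or DiscoveryConfig()
    tests_before = getattr(tester, "n_tests", 0)
    skel, sepsets = stable_skeleton(tester, nodes, config, condition_filter)
    skel = rfci_triple_retention(skel, sepsets, tester, config, condition_filter)
    triples = classify_triples_majority(skel, sepsets, tester, config, condition_filter)
    pag0 = orient_v_structures(skel, triples)
    pag, rule_log, conflicts = apply_orientation_rules(
        pag0, triples, sepsets, config, background_arrowheads
    )
    return DiscoveryResult(
        pag=pag,
        skeleton=skel,
        sepsets=sepsets,
        triples=triples,
        rule_log=rule_log,
        conflicts=conflicts,
        n_tests=getattr(tester, "n_tests", 0) - tests_before,
    )
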