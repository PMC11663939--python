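"""Causal-discovery estimators: conservative RFCI and anchorFCI.

`ConservativeRFCI` wraps the constraint-based engine (stable skeleton,
retention checks, majority-rule conservative orientation, R1-R10) behind a
scikit-learn estimator surface: ``fit(X)`` learns ``pag_`` from a pandas
DataFrame.

`AnchorFCI` extends it with non-ancestral background knowledge for a
partially ordered variable split: a set of *interest* variables (e.g.
phenotypes) and a set of *anchor candidates* known not to be caused by any
interest variable (e.g. SNP genotypes).  The pipeline is

1. screen candidates for association with any interest variable;
2. phase-1 discovery over interest + screened candidates, keeping a
   candidate as a *reliable anchor* iff it is adjacent to at least one
   interest variable and every unshielded triple containing it is
   classified unambiguous by the majority rule;
3. phase-2 discovery over interest + reliable anchors, where
   anchor-anchor pairs are never tested conditional on interest variables
   (their minimal separators cannot contain non-ancestors) and every
   anchor-interest edge is enforced to carry an arrowhead at the interest
   endpoint before the orientation rules run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .citest import BINARY, CONTINUOUS, MULTINOMIAL, MixedCITester
from .engine import (
    DiscoveryConfig,
    DiscoveryResult,
    TripleStatus,
    run_discovery,
)
from .graph import ARROWHEAD, TAIL, GraphError, PAG

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariableRoles:
    """Partition of columns into interest variables, anchor candidates known
    not to be caused by any interest variable, and fixed covariates."""

    interest: tuple[str, ...]
    anchors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        sets = [set(self.interest), set(self.anchors), set(self.covariates)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("interest, anchors and covariates must be disjoint")
        if not self.interest:
            raise ValueError("at least one interest variable is required")

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableRoles":
        return cls(
            interest=tuple(d.get("interest", ())),
            anchors=tuple(d.get("anchors", ())),
            covariates=tuple(d.get("covariates", ())),
        )

    def to_dict(self) -> dict:
        return {
            "interest": list(self.interest),
            "anchors": list(self.anchors),
            "covariates": list(self.covariates),
        }


def infer_column_types(data: pd.DataFrame, columns: Iterable[str]) -> dict[str, str]:
    """Heuristic type map: {0,1} -> binary; few integer levels -> multinomial;
    anything else -> continuous."""
    types = {}
    for c in columns:
        v = np.asarray(data[c])
        u = np.unique(v[~pd.isna(v)])
        if set(u) <= {0, 1}:
            types[c] = BINARY
        elif u.size <= 10 and np.allclose(u, np.round(u)):
            types[c] = MULTINOMIAL
        else:
            types[c] = CONTINUOUS
    return types


def adapted_skeleton_filter(roles: VariableRoles):
    """Forbid CI tests between two anchors conditioned on interest variables.

    Minimal separating sets contain only ancestors of the tested pair, and
    interest variables are non-ancestors of every anchor, so skipping these
    combinations loses nothing.
    """
    anchors = set(roles.anchors)
    interest = set(roles.interest)

    def forbidden(i: str, j: str, S: frozenset) -> bool:
        return i in anchors and j in anchors and bool(set(S) & interest)

    return forbidden


def screen_candidates(
    tester, roles: VariableRoles, alpha_screen: float = 1e-5
) -> dict[str, dict]:
    """Marginal (covariate-adjusted) association screen of anchor candidates.

    A candidate passes when its symmetric CI test against at least one
    interest variable (empty conditioning set beyond the fixed covariates)
    has merged p-value <= ``alpha_screen``.
    """
    report = {}
    for cand in roles.anchors:
        pvals = {y: tester.test(cand, y, frozenset()).p_merged for y in roles.interest}
        best = min(pvals.values()) if pvals else 1.0
        report[cand] = {
            "screen_p": pvals,
            "min_screen_p": best,
            "screened": best <= alpha_screen,
        }
    return report


def select_reliable_anchors(
    phase1: DiscoveryResult, roles: VariableRoles, report: dict[str, dict]
) -> list[str]:
    """Keep screened candidates adjacent to the interest set whose every
    unshielded triple is unambiguous."""
    interest = set(roles.interest)
    selected = []
    for cand, rec in report.items():
        if not rec["screened"] or cand not in phase1.skeleton.nodes:
            rec.update(adjacent_interest=[], n_ambiguous_triples=0, selected=False)
            continue
        adj_int = sorted(set(phase1.skeleton.adjacent(cand)) & interest)
        ambiguous = [
            key
            for key, trec in phase1.triples.items()
            if cand in key and trec.status == TripleStatus.AMBIGUOUS
        ]
        ok = bool(adj_int) and not ambiguous
        rec.update(
            adjacent_interest=adj_int,
            n_ambiguous_triples=len(ambiguous),
            selected=ok,
        )
        if ok:
            selected.append(cand)
    return selected


def anchor_arrowhead_pairs(
    anchors: Iterable[str], roles: VariableRoles
) -> list[tuple[str, str]]:
    """(anchor, interest) pairs demanding an arrowhead at the interest end."""
    return [(a, y) for a in sorted(anchors) for y in roles.interest]


def enforce_anchor_arrowheads(
    pag: PAG, anchors: Iterable[str], roles: VariableRoles
) -> PAG:
    """Stamp the known non-ancestral arrowheads onto a PAG.

    Every anchor-interest edge receives an arrowhead at the interest
    endpoint (so such edges can only be ``<->``, ``-->`` or ``o->``); a
    pre-existing tail there contradicts the background knowledge and raises.
    """
    pag = PAG(pag.nodes, pag.marks)
    for a, y in anchor_arrowhead_pairs(anchors, roles):
        if a not in pag.nodes or y not in pag.nodes or not pag.has_edge(a, y):
            continue
        if pag.mark(a, y) == TAIL:
            raise GraphError(
                f"non-ancestral knowledge violated: tail at {y} on edge {a}-{y}"
            )
        pag.marks[pag.index(a), pag.index(y)] = ARROWHEAD
    return pag


def _check_no_interest_to_anchor(pag: PAG, anchors: Sequence[str], roles: VariableRoles):
    for a in anchors:
        for y in roles.interest:
            if (
                a in pag.nodes
                and pag.has_edge(a, y)
                and pag.mark(y, a) == ARROWHEAD
                and pag.mark(a, y) == TAIL
            ):
                raise GraphError(
                    f"invariant violated: definite edge {y} -> {a} into an anchor"
                )


class ConservativeRFCI(BaseEstimator):
    """Conservative RFCI-style discovery of a PAG from mixed data.

    Parameters
    ----------
    alpha : significance level of the CI tests (default 0.05, uncorrected).
    max_cond_size : cap on conditioning-set size (``None`` = unlimited);
        fixed covariates never count toward the cap.
    majority_rule : conservative unshielded-triple classification by the
        majority of separating sets (default True).
    selection_bias_rules : enable orientation rules R5-R7 (default False;
        the data model has no selection bias).
    transform_continuous : rank-based inverse-normal transform of continuous
        variables for their use as Gaussian-regression outcomes.

    Attributes (after ``fit``)
    --------------------------
    pag_ : learned partial ancestral graph.
    skeleton_, sepsets_, triples_ : intermediate evidence.
    n_tests_ : number of CI test queries issued.
    unstable_ : True when conflicting orientations were logged.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        max_cond_size: int | None = None,
        majority_rule: bool = True,
        selection_bias_rules: bool = False,
        transform_continuous: bool = True,
    ):
        self.alpha = alpha
        self.max_cond_size = max_cond_size
        self.majority_rule = majority_rule
        self.selection_bias_rules = selection_bias_rules
        self.transform_continuous = transform_continuous

    def _config(self) -> DiscoveryConfig:
        return DiscoveryConfig(
            alpha=self.alpha,
            max_cond_size=self.max_cond_size,
            majority_rule=self.majority_rule,
            selection_bias_rules=self.selection_bias_rules,
        )

    def _make_tester(self, X, types, fixed_covariates):
        if types is None:
            types = infer_column_types(X, X.columns)
        return MixedCITester(
            X, types, fixed_covariates, transform_continuous=self.transform_continuous
        )

    def fit(
        self,
        X: pd.DataFrame | None = None,
        y=None,
        *,
        types: Mapping[str, str] | None = None,
        fixed_covariates: Sequence[str] = (),
        tester=None,
        nodes: Sequence[str] | None = None,
    ):
        """Learn a PAG.  Either pass a DataFrame ``X`` (a mixed-data tester
        is built from it) or a ready-made CI ``tester`` plus ``nodes``."""
        if tester is None:
            if X is None:
                raise ValueError("either X or tester must be given")
            tester = self._make_tester(X, types, fixed_covariates)
        if nodes is None:
            nodes = list(tester.variables)
        res = run_discovery(tester, nodes, self._config())
        self.tester_ = tester
        self.result_ = res
        self.pag_ = res.pag
        self.skeleton_ = res.skeleton
        self.sepsets_ = res.sepsets
        self.triples_ = res.triples
        self.n_tests_ = res.n_tests
        self.conflicts_ = res.conflicts
        self.unstable_ = res.unstable
        return self


class AnchorFCI(ConservativeRFCI):
    """Conservative RFCI with reliable-anchor selection and enforced
    non-ancestral arrowheads.

    Additional parameters
    ---------------------
    screen_alpha : association threshold for the candidate screen
        (default 1e-5, a genome-wide *suggestive* level).

    Attributes (after ``fit``)
    --------------------------
    pag_ : final PAG over interest variables plus selected anchors.
    anchors_ : reliable anchors selected in phase 1.
    anchor_report_ : per-candidate screening/selection details.
    phase1_ : the unrestricted phase-1 discovery result.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        max_cond_size: int | None = None,
        majority_rule: bool = True,
        selection_bias_rules: bool = False,
        transform_continuous: bool = True,
        screen_alpha: float = 1e-5,
    ):
        super().__init__(
            alpha=alpha,
            max_cond_size=max_cond_size,
            majority_rule=majority_rule,
            selection_bias_rules=selection_bias_rules,
            transform_continuous=transform_continuous,
        )
        self.screen_alpha = screen_alpha

    def fit(
        self,
        X: pd.DataFrame | None = None,
        y=None,
        *,
        roles: VariableRoles | Mapping,
        types: Mapping[str, str] | None = None,
        tester=None,
    ):
        if not isinstance(roles, VariableRoles):
            roles = VariableRoles.from_dict(roles)
        if tester is None:
            if X is None:
                raise ValueError("either X or tester must be given")
            tester = self._make_tester(X, types, roles.covariates)
        config = self._config()
        tests_before = getattr(tester, "n_tests", 0)

        report = screen_candidates(tester, roles, self.screen_alpha)
        screened = [c for c in roles.anchors if report[c]["screened"]]

        phase1_nodes = list(roles.interest) + screened
        phase1 = run_discovery(tester, phase1_nodes, config)
        selected = select_reliable_anchors(phase1, roles, report)

        phase2_nodes = list(roles.interest) + selected
        res = run_discovery(
            tester,
            phase2_nodes,
            config,
            condition_filter=adapted_skeleton_filter(roles),
            background_arrowheads=anchor_arrowhead_pairs(selected, roles),
        )
        _check_no_interest_to_anchor(res.pag, selected, roles)

        self.tester_ = tester
        self.roles_ = roles
        self.anchor_report_ = report
        self.screened_ = screened
        self.anchors_ = selected
        self.phase1_ = phase1
        self.result_ = res
        self.pag_ = res.pag
        self.skeleton_ = res.skeleton
        self.sepsets_ = res.sepsets
        self.triples_ = res.triples
        self.n_tests_ = getattr(tester, "n_tests", 0) - tests_before
        self.conflicts_ = res.conflicts
        self.unstable_ = res.unstable
        return self


def run_anchorfci(
    data: pd.DataFrame,
    roles: VariableRoles | Mapping,
    *,
    alpha: float = 0.05,
    max_cond_size: int | None = None,
    screen_alpha: float = 1e-5,
    types: Mapping[str, str] | None = None,
) -> tuple[PAG, dict, AnchorFCI]:
    """Convenience wrapper: fit `AnchorFCI` and return (PAG, report, model)."""
    model = AnchorFCI(
        alpha=alpha, max_cond_size=max_cond_size, screen_alpha=screen_alpha
    )
    model.fit(data, roles=roles, types=types)
    return model.pag_, model.anchor_report_, model


# ---------------------------------------------------------------------------
# bootstrap edge stability


@dataclass
class StabilityTable:
    """Edge-type frequencies per variable pair across bootstrap replicates."""

    frequencies: pd.DataFrame  # columns: var1, var2, edge_type, frequency
    n_replicates: int
    n_failed: int

    def for_pair(self, a: str, b: str) -> pd.Series:
        f = self.frequencies
        sel = f[(f.var1 == min(a, b)) & (f.var2 == max(a, b))]
        return sel.set_index("edge_type")["frequency"]


def bootstrap_stability(
    data: pd.DataFrame,
    roles: VariableRoles | Mapping,
    B: int = 50,
    seed: int | None = None,
    *,
    types: Mapping[str, str] | None = None,
    **fit_params,
) -> StabilityTable:
    """Refit `AnchorFCI` on ``B`` row-resamples and tally edge types per pair.

    Absence of an edge counts as a type of its own; failed replicates are
    recorded and excluded from the denominator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(roles, VariableRoles):
        roles = VariableRoles.from_dict(roles)
    if types is None:
        types = infer_column_types(data, data.columns)
    master = np.random.default_rng(seed)
    nodes = sorted(set(roles.interest) | set(roles.anchors))
    counts: dict[tuple[str, str], dict[str, int]] = {}
    n_ok = 0
    n_failed = 0
    for b in range(B):
        rep_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        idx = rng.integers(len(data), size=len(data))
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            model = AnchorFCI(**fit_params).fit(sample, roles=roles, types=types)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        n_ok += 1
        pag = model.pag_
        for i, a in enumerate(nodes):
            for bnode in nodes[i + 1 :]:
                if a in pag.nodes and bnode in pag.nodes and pag.has_edge(a, bnode):
                    et = pag.edge_type(a, bnode)
                else:
                    et = "absent"
                counts.setdefault((a, bnode), {}).setdefault(et, 0)
                counts[(a, bnode)][et] += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed")
    rows = [
        {"var1": a, "var2": b, "edge_type": et, "frequency": c / n_ok}
        for (a, b), d in sorted(counts.items())
        for et, c in sorted(d.items())
    ]
    return StabilityTable(pd.DataFrame(rows), n_ok, n_failed)
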