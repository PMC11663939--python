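"""Causal-effect identification and estimation from a learned PAG.

For a definite directed edge X -> Y, identification proceeds in two steps:

* *visibility*: the edge is visible — X and Y share no latent cause — iff
  some vertex not adjacent to Y has an arrowhead into X directly or through
  a collider path of parents of Y;
* *generalized backdoor criterion*: a set Z containing no possible
  descendant of X that blocks every definite-status backdoor path between
  X and Y identifies the effect by covariate adjustment,

      P(Y | do(X = x)) = (1/N) sum_i  f_hat(x, z_i),

  where f_hat is a (generalized) regression of Y on X, Z and the fixed
  covariates, evaluated at X = x with all other predictors at their
  observed values.  Confidence intervals come from a nonparametric
  bootstrap with percentile intervals.

Continuous outcomes are modelled and reported on their (optionally
transformed) analysis scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .citest import BINARY, CONTINUOUS, MULTINOMIAL
from .estimators import VariableRoles
from .graph import (
    ARROWHEAD,
    CIRCLE,
    TAIL,
    GraphError,
    MarkedGraph,
    definite_status_open,
    possible_descendants,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Estimand:
    """An identification query X -> Y with its adjustment set (if any)."""

    treatment: str
    outcome: str
    adjustment: tuple[str, ...] | None
    identifiable: bool
    reason: str


@dataclass
class DoEstimate:
    """Post-interventional estimates over a treatment grid."""

    treatment: str
    outcome: str
    adjustment: tuple[str, ...]
    grid: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment,
                "outcome": self.outcome,
                "adjustment": ",".join(self.adjustment) or "(none)",
                "x": self.grid,
                "estimate": self.estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# ---------------------------------------------------------------------------
# visibility


def _collider_path_into(p: MarkedGraph, x: str, y: str) -> bool:
    """Is there a vertex v non-adjacent to y with a collider path from v
    into x whose interior vertices are all parents of y?"""

    def parent_of_y(w: str) -> bool:
        return (
            p.has_edge(w, y) and p.mark(w, y) == ARROWHEAD and p.mark(y, w) == TAIL
        )

    # walk backward from x through colliders that are parents of y
    stack: list[tuple[str, frozenset]] = [(x, frozenset((x, y)))]
    while stack:
        u, visited = stack.pop()
        for v in sorted(p.adjacent(u)):
            if v in visited:
                continue
            if p.mark(v, u) != ARROWHEAD:  # need v *-> u
                continue
            if not p.has_edge(v, y):
                return True  # found the far endpoint
            if parent_of_y(v) and p.mark(u, v) == ARROWHEAD:
                stack.append((v, visited | {v}))
    return False


def is_visible(p: MarkedGraph, x: str, y: str) -> bool:
    """Is the definite directed edge x -> y free of latent confounding?

    Requires the edge to be definitely directed (tail at x, arrowhead at y);
    otherwise raises.
    """
    if not p.has_edge(x, y):
        raise GraphError(f"no edge {x}-{y}")
    if not (p.mark(x, y) == ARROWHEAD and p.mark(y, x) == TAIL):
        raise GraphError(f"edge {x}-{y} is not definitely directed x -> y")
    return _collider_path_into(p, x, y)


# ---------------------------------------------------------------------------
# generalized backdoor criterion


def _definite_status_backdoor_paths(
    p: MarkedGraph, x: str, y: str, max_len: int | None = None
) -> list[list[str]]:
    """Definite-status paths from x to y whose first edge is not definitely
    out of x (mark at x is an arrowhead or circle)."""
    paths = []
    max_len = max_len or p.n_nodes

    def extend(path):
        u = path[-1]
        if u == y:
            definite, _ = definite_status_open(p, path, set())
            if definite:
                paths.append(list(path))
            return
        if len(path) > max_len:
            return
        for v in sorted(p.adjacent(u)):
            if v not in path:
                extend(path + [v])

    for w in sorted(p.adjacent(x)):
        if p.mark(w, x) in (ARROWHEAD, CIRCLE):  # edge possibly into x
            if w == y:
                paths.append([x, y])
            else:
                extend([x, w])
    return paths


def backdoor_set_valid(
    p: MarkedGraph, x: str, y: str, Z: Iterable[str]
) -> bool:
    """Does Z satisfy the generalized backdoor criterion for (x, y) in p?"""
    Z = set(Z)
    if Z & (possible_descendants(p, x) | {x, y}):
        return False
    for path in _definite_status_backdoor_paths(p, x, y):
        _, open_ = definite_status_open(p, path, Z)
        if open_:
            return False
    return True


def find_backdoor_set(
    p: MarkedGraph, x: str, y: str, size_cap: int = 4
) -> tuple[str, ...] | None:
    """Smallest adjustment set satisfying the generalized backdoor criterion.

    Searches subsets of the non-descendants of x (size at most ``size_cap``)
    in increasing size and lexicographic order.  Returns ``()`` when no
    definite-status backdoor path exists, ``None`` when no admissible set
    is found.
    """
    import itertools

    if x == y:
        raise GraphError("treatment and outcome must differ")
    paths = _definite_status_backdoor_paths(p, x, y)
    if not paths:
        return ()
    forbidden = possible_descendants(p, x) | {x, y}
    candidates = sorted(v for v in p.nodes if v not in forbidden)
    for r in range(min(size_cap, len(candidates)) + 1):
        for Z in itertools.combinations(candidates, r):
            if all(
                not definite_status_open(p, path, set(Z))[1] for path in paths
            ):
                return Z
    return None


# ---------------------------------------------------------------------------
# estimation


def _encode_predictors(
    data: pd.DataFrame, cols: Sequence[str], types: Mapping[str, str]
) -> tuple[np.ndarray, list[tuple[str, np.ndarray | None]]]:
    """Design matrix with intercept; multinomial columns as level indicators.

    Returns the matrix and the encoding recipe (column, levels) so the same
    encoding can be applied to counterfactual copies.
    """
    recipe: list[tuple[str, np.ndarray | None]] = []
    for c in cols:
        if types.get(c) == MULTINOMIAL:
            recipe.append((c, np.unique(np.asarray(data[c]))))
        else:
            recipe.append((c, None))
    return _apply_encoding(data, recipe), recipe


def _apply_encoding(data: pd.DataFrame, recipe) -> np.ndarray:
    blocks = [np.ones((len(data), 1))]
    for c, levels in recipe:
        v = np.asarray(data[c], dtype=float)
        if levels is None:
            blocks.append(v[:, None])
        else:
            blocks.append((v[:, None] == levels[1:]).astype(float))
    return np.concatenate(blocks, axis=1)


def _fit_predictor(y: np.ndarray, X: np.ndarray, family: str):
    """Fit the outcome regression; returns a coefficient-based predictor."""
    import statsmodels.api as sm

    if family == CONTINUOUS:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return lambda Xnew: Xnew @ beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    params = np.asarray(res.params)
    return lambda Xnew: 1.0 / (1.0 + np.exp(-(Xnew @ params)))


def default_grid(
    data: pd.DataFrame, x: str, types: Mapping[str, str]
) -> np.ndarray:
    """Both levels for binary treatments, observed levels for multinomial,
    deciles of the observed distribution for continuous."""
    v = np.asarray(data[x], dtype=float)
    t = types.get(x, CONTINUOUS)
    if t == BINARY:
        return np.array([0.0, 1.0])
    if t == MULTINOMIAL:
        return np.unique(v)
    return np.quantile(v, np.linspace(0.1, 0.9, 9))


def estimate_do(
    data: pd.DataFrame,
    x: str,
    y: str,
    Z: Sequence[str],
    *,
    types: Mapping[str, str],
    grid: Sequence[float] | None = None,
    fixed_covariates: Sequence[str] = (),
    B: int = 500,
    seed: int | None = None,
) -> DoEstimate:
    """Backdoor-adjusted estimate of E(Y | do(X = x)) on a treatment grid.

    Regresses Y on (X, Z, fixed covariates) with the family given by Y's
    type, then averages fitted responses over the observed covariate rows
    with X set to each grid value.  Percentile confidence intervals come
    from ``B`` bootstrap refits.
    """
    if grid is None:
        grid = default_grid(data, x, types)
    grid = np.asarray(grid, dtype=float)
    obs = np.asarray(data[x], dtype=float)
    if grid.min() < obs.min() or grid.max() > obs.max():
        warnings.warn(
            f"extrapolation: grid for {x} extends beyond the observed support",
            stacklevel=2,
        )
    family = types[y]
    cols = [x] + [c for c in Z] + [c for c in fixed_covariates]
    yv = np.asarray(data[y], dtype=float)

    def curve(frame: pd.DataFrame) -> np.ndarray:
        X, recipe = _encode_predictors(frame, cols, types)
        predict = _fit_predictor(np.asarray(frame[y], dtype=float), X, family)
        out = np.empty(grid.size)
        cf = frame[cols].copy()
        for k, val in enumerate(grid):
            cf[x] = val
            out[k] = float(np.mean(predict(_apply_encoding(cf, recipe))))
        return out

    point = curve(data)
    rng = np.random.default_rng(seed)
    boot = np.empty((B, grid.size))
    used = 0
    for b in range(B):
        idx = rng.integers(len(data), size=len(data))
        try:
            boot[used] = curve(data.iloc[idx].reset_index(drop=True))
            used += 1
        except Exception as exc:  # e.g. degenerate resample
            logger.warning("bootstrap replicate failed: %s", exc)
    if used == 0:
        raise RuntimeError("all bootstrap replicates failed")
    lo, hi = np.percentile(boot[:used], [2.5, 97.5], axis=0)
    return DoEstimate(
        treatment=x,
        outcome=y,
        adjustment=tuple(Z),
        grid=grid,
        estimate=point,
        ci_low=lo,
        ci_high=hi,
        n_bootstrap=used,
    )


def effects_report(
    pag: MarkedGraph,
    data: pd.DataFrame,
    roles: VariableRoles,
    *,
    types: Mapping[str, str],
    size_cap: int = 4,
    B: int = 500,
    seed: int | None = None,
) -> tuple[list[DoEstimate], list[Estimand]]:
    """Estimate every identifiable effect along visible directed edges
    among the interest variables; report skipped edges with the reason.

    Adjustment validity is re-checked (descendant exclusion plus blocking)
    before any estimation.
    """
    interest = set(roles.interest) & set(pag.nodes)
    estimates: list[DoEstimate] = []
    estimands: list[Estimand] = []
    for x in sorted(interest):
        for y in sorted(interest - {x}):
            if not pag.has_edge(x, y):
                continue
            if not (pag.mark(x, y) == ARROWHEAD and pag.mark(y, x) == TAIL):
                continue
            if not is_visible(pag, x, y):
                estimands.append(
                    Estimand(x, y, None, False, "possibly confounded (not visible)")
                )
                continue
            Z = find_backdoor_set(pag, x, y, size_cap)
            if Z is None:
                estimands.append(
                    Estimand(x, y, None, False, "no admissible backdoor set found")
                )
                continue
            if not backdoor_set_valid(pag, x, y, Z):
                estimands.append(
                    Estimand(x, y, Z, False, "adjustment set failed re-validation")
                )
                continue
            estimands.append(Estimand(x, y, Z, True, "generalized backdoor"))
            estimates.append(
                estimate_do(
                    data, x, y, Z,
                    types=types,
                    fixed_covariates=roles.covariates,
                    B=B,
                    seed=seed,
                )
            )
    return estimates, estimands
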