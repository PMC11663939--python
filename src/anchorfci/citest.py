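"""Conditional-independence testing for mixed continuous/binary/multinomial data.

The symmetric mixed test evaluates ``Vi _||_ Vj | S`` by testing two null
hypotheses with nested likelihood-ratio tests — ``Vi`` regressed on ``S``
versus ``S + {Vj}``, and vice versa — choosing the regression family by the
outcome's type (Gaussian linear, logistic, or multinomial log-linear).  The
two dependent p-values are merged as ``min(2*min(p1,p2), max(p1,p2))``,
which is symmetric in the pair by construction.

Continuous variables are passed through the rank-based inverse normal
transform once, up front, when they serve as Gaussian-regression outcomes;
raw values are used on the predictor side.  A configurable set of fixed
covariates (e.g. sex, age, age^2, ancestry PCs) is appended to every model
on both sides of each LRT and never counts toward conditioning-set size
caps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .graph import MAG, m_separated

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary"
MULTINOMIAL = "multinomial"
_TYPES = (CONTINUOUS, BINARY, MULTINOMIAL)


class DataError(ValueError):
    """Ill-typed, constant, or incomplete input data."""


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one symmetric conditional-independence test."""

    p1: float
    p2: float
    p_merged: float
    df1: int
    df2: int
    family1: str
    family2: str
    converged: bool = True

    def swapped(self) -> "CITestResult":
        return CITestResult(
            self.p2, self.p1, self.p_merged, self.df2, self.df1,
            self.family2, self.family1, self.converged,
        )


def merge_p_values(p1: float, p2: float) -> float:
    """Combine two dependent p-values as ``min(2*min(p1,p2), max(p1,p2))``."""
    return min(2.0 * min(p1, p2), max(p1, p2))


def rank_inverse_normal(values: Sequence[float], c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    Maps value with (average, for ties) rank ``r`` among ``n`` to
    ``Phi^-1((r - c) / (n - 2c + 1))`` with offset ``c = 3/8``.  Monotone;
    tied inputs map to identical outputs.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("need a 1-d vector with at least two values")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite values in input")
    if np.all(x == x[0]):
        raise DataError("transform undefined for all-identical input")
    r = stats.rankdata(x, method="average")
    return ndtri((r - c) / (x.size - 2.0 * c + 1.0))


def validate_column_types(
    data: pd.DataFrame, types: Mapping[str, str], columns: Iterable[str]
) -> None:
    for col in columns:
        if col not in data.columns:
            raise DataError(f"column {col!r} not in data")
        if col not in types:
            raise DataError(f"no type declared for column {col!r}")
        t = types[col]
        if t not in _TYPES:
            raise DataError(f"unknown type {t!r} for column {col!r}")
        v = data[col]
        if v.isna().any():
            raise DataError(f"column {col!r} has {int(v.isna().sum())} missing values")
        if t == BINARY and not set(np.unique(v)) <= {0, 1}:
            raise DataError(f"binary column {col!r} must be coded 0/1")
        if t == MULTINOMIAL:
            u = np.unique(v)
            if not np.allclose(u, np.round(u)):
                raise DataError(f"multinomial column {col!r} must be integer-coded")


# ---------------------------------------------------------------------------
# nested likelihood-ratio test


def _gaussian_loglik_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _fit_loglik(y: np.ndarray, X: np.ndarray, family: str) -> tuple[float, bool]:
    """Maximized log-likelihood (up to a family-constant) and convergence flag."""
    import statsmodels.api as sm

    if family == CONTINUOUS:
        rss = _gaussian_loglik_rss(y, X)
        n = y.size
        # -n/2 * log(rss/n) + const; constant cancels in the LRT
        return -0.5 * n * np.log(max(rss, 1e-300) / n), True
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == BINARY:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            else:
                res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        llf = float(res.llf)
        if not np.isfinite(llf):
            return 0.0, False
        return llf, converged
    except Exception as exc:  # separation, singular hessian, ...
        logger.warning("GLM fit failed (%s); treating as dependence", exc)
        return 0.0, False


class MixedCITester:
    """Symmetric mixed-data CI tester over a fixed dataset.

    Parameters
    ----------
    data
        Complete rectangular table (no missing values among used columns).
    types
        Column type map: ``continuous`` | ``binary`` | ``multinomial``.
    fixed_covariates
        Columns appended to every regression (both reduced and full models);
        they never count toward conditioning-set size limits.
    transform_continuous
        Apply the rank-based inverse normal transform to continuous columns
        once, for their use as Gaussian-regression outcomes.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        types: Mapping[str, str],
        fixed_covariates: Sequence[str] = (),
        transform_continuous: bool = True,
    ):
        self.types = dict(types)
        self.fixed_covariates = tuple(fixed_covariates)
        cols = [c for c in data.columns if c in self.types]
        validate_column_types(data, self.types, cols)
        self.variables = tuple(c for c in cols if c not in self.fixed_covariates)
        for col in self.variables:
            if np.unique(data[col]).size < 2:
                raise DataError(f"column {col!r} is constant")
        self._n = len(data)

        # outcome vectors
        self._outcome: dict[str, np.ndarray] = {}
        # predictor blocks (n, k) with level indicators for discrete columns
        self._pred: dict[str, np.ndarray] = {}
        for col in cols:
            v = np.asarray(data[col], dtype=float)
            t = self.types[col]
            if t == CONTINUOUS:
                self._outcome[col] = (
                    rank_inverse_normal(v) if transform_continuous else v.copy()
                )
                self._pred[col] = v[:, None]
            elif t == BINARY:
                self._outcome[col] = v.astype(int)
                self._pred[col] = v[:, None]
            else:
                levels = np.unique(v)
                codes = np.searchsorted(levels, v)
                self._outcome[col] = codes
                # indicator contrasts, first level as reference
                self._pred[col] = (codes[:, None] == np.arange(1, levels.size)).astype(
                    float
                )

        self._fixed_block = self._design(self.fixed_covariates)
        self._cache: dict[tuple, CITestResult] = {}
        self.n_tests = 0
        self.n_fits = 0
        self.n_nonconverged = 0

    # -- design matrices ---------------------------------------------------

    def _design(self, predictors: Iterable[str]) -> np.ndarray:
        blocks = [np.ones((self._n, 1))]
        for c in predictors:
            blocks.append(self._pred[c])
        X = np.concatenate(blocks, axis=1)
        # drop empty indicator columns (e.g. unobserved level in a bootstrap
        # resample) so designs stay full rank
        keep = ~np.all(X == 0.0, axis=0)
        return X[:, keep]

    def nested_lrt(
        self, outcome: str, reduced: Sequence[str], full: Sequence[str]
    ) -> tuple[float, int, bool]:
        """p-value of the LRT of ``outcome ~ reduced`` vs ``outcome ~ full``.

        Fixed covariates are appended to both models.  Returns
        ``(p, df, converged)``; a non-convergent fit yields the dependence
        sentinel ``p = 0``.
        """
        if not set(reduced) <= set(full):
            raise DataError("reduced predictor set must be a subset of full")
        family = self.types[outcome]
        y = self._outcome[outcome]
        Xr = self._design(tuple(reduced) + self.fixed_covariates)
        Xf = self._design(tuple(full) + self.fixed_covariates)
        k_out = 1 if family != MULTINOMIAL else int(self._outcome[outcome].max())
        df = (Xf.shape[1] - Xr.shape[1]) * k_out
        if df == 0:
            return 1.0, 0, True
        ll_r, conv_r = _fit_loglik(y, Xr, family)
        ll_f, conv_f = _fit_loglik(y, Xf, family)
        self.n_fits += 2
        if not (conv_r and conv_f):
            self.n_nonconverged += 1
            logger.warning(
                "non-convergent LRT for %s ~ %s vs %s; keeping dependence",
                outcome, list(reduced), list(full),
            )
            return 0.0, df, False
        stat = max(2.0 * (ll_f - ll_r), 0.0)
        return float(stats.chi2.sf(stat, df)), df, True

    # -- the symmetric test ------------------------------------------------

    def test(self, i: str, j: str, S: Iterable[str] = ()) -> CITestResult:
        """Symmetric mixed CI test of ``i _||_ j | S`` (plus fixed covariates)."""
        S = frozenset(S)
        if i == j:
            raise DataError("i and j must differ")
        if i in S or j in S:
            raise DataError("endpoints may not appear in the conditioning set")
        key = (frozenset((i, j)), S)
        swap = i > j
        a, b = (j, i) if swap else (i, j)
        if key not in self._cache:
            Ss = sorted(S)
            p1, df1, c1 = self.nested_lrt(a, Ss, Ss + [b])
            p2, df2, c2 = self.nested_lrt(b, Ss, Ss + [a])
            self._cache[key] = CITestResult(
                p1, p2, merge_p_values(p1, p2), df1, df2,
                self.types[a], self.types[b], c1 and c2,
            )
        self.n_tests += 1
        res = self._cache[key]
        return res.swapped() if swap else res

    __call__ = test


class OracleCITester:
    """Exact CI oracle backed by m-separation in a known MAG.

    Returns ``p_merged = 1`` when the pair is m-separated given the
    conditioning set and ``0`` otherwise; fixed covariates are ignored.
    """

    def __init__(self, mag: MAG):
        self.mag = mag
        self.variables = mag.nodes
        self.fixed_covariates = ()
        self.n_tests = 0
        self._cache: dict[tuple, bool] = {}

    def test(self, i: str, j: str, S: Iterable[str] = ()) -> CITestResult:
        key = (frozenset((i, j)), frozenset(S))
        if key not in self._cache:
            self._cache[key] = m_separated(self.mag, i, j, set(S))
        self.n_tests += 1
        p = 1.0 if self._cache[key] else 0.0
        return CITestResult(p, p, p, 1, 1, "oracle", "oracle")

    __call__ = test


def oracle_ci(mag: MAG) -> OracleCITester:
    """CI tester that answers queries from m-separation in ``mag``."""
    return OracleCITester(mag)
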