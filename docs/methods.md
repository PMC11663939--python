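# Methods

## Graphs and semantics

All graphs are stored as endpoint-mark matrices over labelled nodes
(`0` absent, `1` circle, `2` arrowhead, `3` tail; entry [i,j] is the mark
at j on edge i–j).  A MAG uses arrowheads and tails only and must contain
no directed cycle and no almost-directed cycle (x↔y plus a directed path
x→…→y).  A PAG additionally uses circles for marks that vary within the
equivalence class.  Selection bias is not modelled anywhere: tail–tail
(undirected) edges never arise in the generator or the application
setting, so the MAG type forbids them and orientation rules R5–R7 are
gated behind an off-by-default flag.

m-separation is decided by a BFS over directed edge states: a walk is
m-connecting given Z iff every non-collider on it avoids Z and every
collider is an ancestor of Z; walk- and path-connectivity coincide on
ancestral graphs, so this is O(|E|) per query.  The test suite keeps an
independent simple-path-enumeration oracle and checks agreement on random
MAGs over all queries with |Z| ≤ 3.

Latent projection (DAG with latents → observed MAG) decides adjacency by
exhaustive subset d-separation checks on the DAG (via networkx); endpoint
marks come from DAG ancestry.  At the package's problem sizes (≤ 10
nodes) this exact construction is cheap, and the suite cross-checks that
the projected MAG entails exactly the DAG's observed d-separations.

Structural Hamming distance between two graphs restricted to a node
subset: +1 per pair whose adjacency differs, and, when both graphs have
the edge, +1 per endpoint whose mark differs.  This convention reproduces
the one worked comparison we can check (the 8-node example's RFCI output
vs its true PAG scores exactly 5).

## Mixed-data conditional independence test

`test(i, j, S)` evaluates both directions with nested likelihood-ratio
tests — outcome regressed on S versus S ∪ {other} — with the family chosen
by the outcome's declared type: Gaussian linear (closed-form via least
squares), logistic, or multinomial log-linear (statsmodels).  Discrete
predictors enter as level indicators (first level reference); the LRT
statistic is referred to χ² with df equal to the parameter-count
difference, times (levels − 1) for multinomial outcomes.  The two
p-values merge as `min(2·min(p1,p2), max(p1,p2))`, which is symmetric and
never exceeds either the Bonferroni-2 bound or the larger p-value.

Choices that matter:

* **Rank-based inverse normal transform** with Blom offset c = 3/8 is
  applied once, up front, to continuous variables for their use as
  Gaussian outcomes; raw values serve as predictors.  Re-transforming
  within each test would break the symmetric caching of results.
* **Non-convergent or separated fits count as dependence** (p = 0
  sentinel, logged): a falsely accepted independence cascades into wrong
  orientations, while a kept edge merely costs informativeness.
* **α = 0.05, no multiplicity correction** (same asymmetric-risk
  argument).
* **Fixed covariates** are appended to every model on both sides of every
  LRT and never count toward conditioning-set caps.
* Missing data are refused outright; impute externally first.
* Results are cached per (pair, conditioning set), so the benchmark's two
  algorithms and anchorFCI's two phases share all fits on a dataset.

Calibration is tested empirically: under mixed-type conditional
independence (3-level multinomial vs continuous given a continuous common
cause, n = 2000, 500 replicates) the rejection rate at α = 0.05 must fall
in [0.03, 0.07].

## Discovery engine

Stage order: stable skeleton → retention → triple classification →
R0/background → R1–R10 → ancestrality check.

* **Stable skeleton**: level-wise search with adjacency sets frozen per
  level, candidate conditioning sets drawn from both endpoints'
  adjacencies, optional size cap (fixed covariates excluded from the
  count), and an optional veto filter for forbidden (pair, set)
  combinations.  Output is invariant to variable order.
* **Retention**: for each unshielded triple ⟨i,k,j⟩ the pairs (i,k) and
  (j,k) are re-tested given sepset(i,j); a discovered independence
  removes the edge and stores a minimal separator found by greedy
  single-element shrinking, iterating until stable.
* **Majority rule**: all subsets (up to the cap) of either endpoint's
  adjacency are tested; among separating sets, the fraction containing
  the middle node decides collider (< ½) / non-collider (> ½) / ambiguous
  (= ½, exact tie on counts).  If no separating subset is found the
  stored sepset's membership decides.  With the rule switched off, the
  stored sepset alone decides and nothing is ambiguous.
* **Orientation**: R0 orients unambiguous colliders; background
  arrowheads (the anchor knowledge) are stamped next, erroring on a
  contradicting definite tail; then R1–R4 and R8–R10 run to a fixed
  point.  Ambiguity blocks R1/R3 (and R7 when enabled).  R4 searches
  discriminating paths under the current marks and decides by the stored
  sepset of the path's far endpoints; firings are logged.  The RFCI
  variant's additional edge-removal retests along discriminating paths
  are not performed — under a faithful oracle they never trigger, and
  every R4 firing is auditable in the rule log.
* **Conflicts**: a rule demanding a different mark where a definite mark
  already sits keeps the earlier mark, logs the conflict, and marks the
  run unstable.  A final check rejects outputs whose definite edges form
  directed or almost-directed cycles (carrying the rule trace), which at
  small samples happens in roughly 1% of benchmark runs.

## AnchorFCI

Phase 0 screens each anchor candidate against each interest variable
(covariate-adjusted, empty graph-side conditioning set) at 10⁻⁵ — a
genome-wide *suggestive* threshold.  Phase 1 runs the full engine on
interest ∪ screened candidates without restrictions.  A candidate becomes
a **reliable anchor** iff it is adjacent to at least one interest variable
in the phase-1 skeleton and *every* unshielded triple containing it is
unambiguous — the strict reading: one ambiguous triple can corrupt
downstream orientations, and under exact tests no triple is ever ambiguous,
so the strict predicate costs nothing asymptotically.  Unselected
candidates are dropped entirely from phase 2, which reruns the engine on
interest ∪ selected anchors with (a) the anchor–anchor test filter
(separators of two anchors cannot contain interest variables, because
minimal separators contain only ancestors) and (b) the enforced
arrowheads.  Phase 1 runs unfiltered; the filter is a pure optimisation
whose correctness argument is independent of the phase, and the shared
test cache makes the difference moot.

The output invariantly contains no definite interest→anchor edge:
enforcement stamps the interest-side arrowhead before any rule can place
a tail there, and a belt-and-braces check still validates every fit.

Bootstrap stability resamples rows with replacement (per-replicate seeds
spawned from a master seed), refits, and tallies edge-type frequencies
per pair with absence as its own type; failed replicates are excluded
from the denominator and reported.

## Synthetic data and benchmark

The generator emulates a genotype/phenotype study: `n_anchors = 3`
exogenous 3-level multinomial anchors with level probabilities
(0.5, 0.3, 0.2), each with one interest-variable child;
`n_interest = 5` continuous variables with pairwise directed edges drawn
at probability 0.4 along a random topological order; with probability 0.5
one latent confounder parenting two random interest variables.  Structural
coefficients (and the per-level shifts of multinomial parents) have
magnitude Uniform(0.3, 1.0) with random sign, drawn per dataset; noise is
standard Gaussian.  The observed ground truth is the latent projection of
this DAG.

What this emulates — and does not: mixed types, the partial order, latent
confounding, and weak-to-moderate effects are represented; linkage
between anchors, Hardy–Weinberg structure, nonlinearities, measurement
error, and missingness are not.  Passing benchmarks therefore demonstrate
the algorithmic claims (anchor knowledge improves accuracy and
informativeness) rather than field performance on real cohorts.  Because
the generator's density and coefficient law are package choices, absolute
score levels are tied to those choices; the *paired* comparison between
the two algorithms on identical data is the meaningful quantity, and it
is what the tests assert (anchorFCI strictly better at every N, both
improving with N, one-sided Wilcoxon on paired differences).

Scoring: SHD-difference over interest-variable edges, i.e.
SHD(inferred, true MAG) − SHD(true MEC PAG, true MAG), where the true
MEC's PAG comes from the same engine run with the m-separation oracle and
no background knowledge.  Zero means "as informative as achievable
without the partial order"; negative means more informative (anchorFCI
reaches this routinely).  Problem sizes in the shipped tests and the
acceptance script — 10 MAGs × 5 datasets at N ∈ {500, 1000} — were chosen
as the smallest design at which the paired Wilcoxon comparison is stably
significant across seeds; the CLI exposes the full 50 × 30 × four-N
design.

## Effects

Visibility of x→y is the two-clause graphical criterion: some vertex not
adjacent to y with an arrowhead into x, directly or through a collider
path whose interior vertices are all parents of y.  The backdoor search
enumerates definite-status paths whose first edge is not definitely out
of x, then scans candidate sets (non-descendants of x only, size ≤ 4 by
default, smallest first) for one blocking all of them; the empty set is
returned when no such path exists.  Admissibility is re-checked
independently before any estimation.

Estimation fits Y on (X, Z, fixed covariates) — least squares for
continuous outcomes, binomial GLM for binary — and averages fitted
responses over the observed covariate rows with X forced to each grid
value (both levels for binary X, deciles for continuous).  The empirical
average implements the adjustment integral; with Z = ∅ and no covariates
it reduces exactly to the regression prediction.  Confidence intervals
are nonparametric bootstrap percentiles (B = 500 default; grid values
outside the observed support trigger an extrapolation warning).
Continuous outcomes are modelled and reported on their analysis scale
(optionally rank-INT or log transformed upstream); no back-transformation
to the original scale is attempted.

## Known limitations

* No selection-bias modelling (R5–R7 exist but are untested against data
  because the generator cannot produce undirected edges).
* R4 omits the RFCI-specific retention retests along discriminating paths
  (logged firings allow auditing).
* The conservative engine can still emit non-ancestral orientations under
  gross unfaithfulness; such runs abort loudly rather than repair.
* Effect estimation covers the generalized backdoor criterion only — no
  generalized adjustment criterion, no complete identification calculus,
  no mediation.
* The screen-then-fit pipeline reuses the same data for selection and
  estimation; reported intervals do not account for selection.
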