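# anchorfci

Constraint-based causal discovery for mixed genotype/phenotype data, with
**reliable anchors**: variables that are known a priori not to be caused by
the variables of interest (the canonical case being SNP genotypes relative
to phenotypes).  The package learns a **partial ancestral graph (PAG)** —
a representation of the Markov equivalence class of maximal ancestral
graphs (MAGs) that is valid under latent confounding — and then identifies
and estimates interventional effects along its visible directed edges.

## Who this is for

Epidemiologists and systems biologists who have a modest set of phenotypic
/ clinical variables, a set of candidate genetic anchors, and fixed
covariates (sex, age, ancestry PCs), and who want causal structure *and*
effect sizes without assuming causal sufficiency or instrument validity.

## The method

The discovery core is a conservative RFCI-style algorithm: an
order-independent ("stable") skeleton search with a cap on
conditioning-set size, RFCI unshielded-triple retention checks with
minimal-separator shrinking, conservative classification of unshielded
triples by the **majority rule** (a triple ⟨i,k,j⟩ is a collider if k lies
in fewer than half of the separating sets of (i,j), a non-collider if in
more than half, ambiguous on a tie — and ambiguous triples never drive an
orientation), and the complete orientation rules R1–R10.

`AnchorFCI` adds three adaptations for a partial order
{anchors} ≺ {interest}:

1. **Reliable-anchor selection** — candidates significantly associated
   with the interest set (screen at p ≤ 10⁻⁵) that are adjacent to an
   interest variable and form only unambiguous triples in a phase-1 run;
2. **Adapted skeleton** — no CI test between two anchors is conditioned on
   interest variables (minimal separators contain only ancestors, and
   interest variables are non-ancestors of anchors);
3. **Enforced arrowheads** — every anchor–interest edge gets an arrowhead
   at the interest endpoint before the orientation rules run, and the
   result is checked to be a valid ancestral graph.

Conditional independence on mixed data is tested symmetrically: both
H₀₁: P(Vᵢ|S) = P(Vᵢ|Vⱼ,S) and H₀₂ with roles swapped are tested by nested
likelihood-ratio tests (Gaussian linear, logistic, or multinomial
log-linear by outcome type; continuous outcomes rank-inverse-normal
transformed), and the p-values merged as

    p = min(2·min(p₁,p₂), max(p₁,p₂)).

Fixed covariates enter every regression and never count toward the
conditioning-set cap.  Testing is at α = 5% without multiplicity
correction: causal discovery depends on reliable *independencies*, and
corrections that suppress false dependencies inflate false independencies,
which cascade into wrong orientations.

For a visible directed edge X→Y, effects are identified by the
**generalized backdoor criterion** (a set Z of non-descendants of X
blocking all definite-status backdoor paths) and estimated by covariate
adjustment, P̂(Y|do(X=x)) = N⁻¹ Σᵢ f̂(x, zᵢ), with bootstrap percentile
confidence intervals.

## Worked example

```bash
anchorfci simulate --seed 3 --n 2000 --out data.csv \
    --roles-out roles.yaml --mag-out mag.csv
anchorfci discover --data data.csv --roles roles.yaml --out pag.csv
```

prints

```
PAG over 7 nodes written to pag.csv
reliable anchors: G1, G2
```

The generating MAG was `G1-->E, G2-->C, G3-->A, C-->B, C-->D, E-->D`.
Two of the three anchors pass the 10⁻⁵ screen and selection; the learned
PAG `B <-- C, C --> D, C <-o G2, D <-- E, E <-o G1, A o-o C` recovers all
four interest-variable edges *with their orientations* — the enforced
anchor arrowheads let R1-style propagation fix C→B, C→D and E→D as
definite causal — at the cost of one false adjacency (A o-o C) from an
uncorrected α = 0.05 test.  Estimation then runs along the visible edges:

```bash
anchorfci effects --data data.csv --roles roles.yaml --pag pag.csv \
    --bootstrap 100 --seed 1 --out eff.csv
# C -> B: identified
# C -> D: identified
# E -> D: identified
```

Each identified edge was unconfounded in the PAG, so the graph-side
adjustment set is empty; `eff.csv` holds E(Y|do(X=x)) over a decile grid
of x with 95% bootstrap intervals — e.g. E(B|do(C=-1.83)) = 1.07
[0.99, 1.14], tracking the simulated coefficient.

The same pipeline is available as scikit-learn-style estimators:

```python
from anchorfci import AnchorFCI, VariableRoles
roles = VariableRoles(interest=("A","B","C","D","E"),
                      anchors=("G1","G2","G3"))
model = AnchorFCI(alpha=0.05, max_cond_size=2).fit(df, roles=roles)
model.pag_, model.anchors_, model.triples_
```

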