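# Methods

## Covering rough-set model

A covering decision table is `S = (U, Δ, D)`: a finite universe `U` of
event objects, a family `Δ` of coverings (one per condition attribute;
blocks are non-empty, may overlap, and union to `U`), and a decision
partition `U/D`.  For one covering, the neighbourhood of `x` is
`N(x) = ⋂{K ∈ C : x ∈ K}`; the minimal (maximal) description of `x` is
the set of containing blocks with no proper containing sub-block
(super-block).  The positive domain of a covering is the set of objects
whose neighbourhood lies inside one decision class — the neighbourhood
operator is used for the single-covering lower approximation because it
makes the consistent covering of the worked example positive-region
preserving, which matches that example's printed reduct set.

A block is *effective* when it is a subset of one decision class.  The
certificate set `r(x)` collects the coverings owning an effective block
containing `x`; the *family* is the deduplicated collection of the
`r(x)`.  The membership condition for effective blocks is implemented as
"block ⊆ some decision class": this is the reading that reproduces the
worked example's per-object certificate sets exactly.  Objects contained
in no effective block carry no certificate; they are excluded from the
family and reported in a diagnostics field rather than silently dropped.

**Reducts.**  A reduct is a minimal hitting set of the family.  The
exhaustive route builds the discernibility function — a CNF with one
clause per family member — and expands it to a minimal DNF clause by
clause with absorption after every product step, which keeps the term
set equal to the set of minimal transversals throughout.  An independent
power-set enumeration oracle (`brute_force_reducts`) exists purely for
cross-checking and is exercised on hundreds of seeded random tables in
the test suite.

**A-DRE.**  The cost-aware pipeline converts the family to a hypergraph
(vertices = coverings with acquisition costs, edges = family members) and
runs a greedy cover: repeatedly take the vertex maximising
(uncovered edges hit)/cost, ties to the earlier vertex in input order.
Greedy covers need not be minimal, so a pruning pass drops redundant
members (most expensive first) until removing any member would uncover
an edge.  The greedy criterion and the pruning pass are this package's
design choices — a greedy minimum vertex cover over the family
hypergraph admits several selection rules, and density-per-unit-cost is
the standard one for weighted set cover (it carries the usual H(n)
approximation guarantee).  Positive-region preservation of the final
reduct is verified and reported, not assumed.

**Rules.**  Each effective block of a reduct covering becomes one rule
`x ∈ block ⇒ class`, with support `|block|/|U|` and coverage
`|block|/|class|`.  Rules are ordered by (coverage desc, support desc,
covering cost asc, block serialization order) — coverage first because
it measures how much of the consequent class the antecedent explains,
which is the emphasis in ordered-rule classification; the remaining keys
are deterministic tie-breaks.  Classification walks the ordered list and
returns the first match, falling back to the majority class.  Records
are block-membership vectors (covering id → block, or block index); the
scikit-learn wrapper instead matches unseen feature values through the
generator predicates stored at granulation time (value equality for
symbolic blocks, `[centre − tol, centre + tol]` windows for numeric
ones).

**Granulation.**  Symbolic attributes become equal-value partitions.
Numeric attributes become δ-neighbourhood coverings: the block of `x` is
`{y : |a(y) − a(x)| ≤ δ·range(a)}`, duplicates merged, with δ a fraction
of the attribute's range (default 0.2, per-attribute configurable; a
zero-range attribute degenerates to the single block `U`).  This is a
design choice: range-fraction neighbourhoods are the common granulation
for numeric attributes in covering rough sets and expose δ as the single
resolution knob.

**Cross-validation harness.**  `evaluate_rules` runs seeded stratified
k-fold CV (default 5 folds).  Training restricts block effectiveness and
rule statistics to training objects while retaining full blocks, so
held-out objects have well-defined membership; inconsistent training
folds degrade to majority-class prediction.

## Grey cumulative prospect model

Entries of the evaluation matrix are grey values: scalars (treated as
degenerate intervals), intervals `[lo, hi]`, single linguistic terms, or
term pairs.  The default linguistic scale is the 7-term tiling of
[0, 1]: VP [0, 0.1], P [0.1, 0.25], MP [0.25, 0.4], M [0.4, 0.55],
MG [0.55, 0.7], G [0.7, 0.85], VG [0.85, 1]; it is config-overridable.
A term pair such as `[G, M]` resolves to the spanning interval
[min lo, max hi] of the two terms.

Editing against the reference vector: for gain criteria
`Δ = [v.lo − r.hi, v.hi − r.lo]`; for cost criteria the sign flips so
that sitting below the reference is a gain.  Scalar criteria are used
unscaled against their scalar reference; no cross-criterion
normalisation is applied — each criterion is judged only against its own
reference entry.

Valuation: `v(d) = d^α` (gains), `−λ(−d)^β` (losses), applied
endpoint-wise (legitimate because `v` is strictly increasing).
Probability weighting: `π(p) = p^γ/[p^γ + (1−p)^γ]^{1/γ}`, γ = χ on the
gain branch and γ = δ on the loss branch; the branch for each state is
chosen by the sign of that state's delta midpoint.  Defaults are the
canonical Tversky–Kahneman estimates α = β = 0.88, λ = 2.25, χ = 0.61,
δ = 0.69 (all config-exposed; the weighting exponents are constrained to
(0.28, 1], below which π loses monotonicity).  Time frames without
printed probabilities are treated as equiprobable states; explicit state
probabilities are honoured when supplied.  Interval prospect values are
collapsed to midpoints for the final utility
`U(x) = Σ_j ω_j·mid(V_j)` and ranking.

These conventions (scale, parameters, frame probabilities, midpoint
collapse) are all genuinely open design points: sensitivity of the
absolute utilities to them is substantial, while the *ranking* of the
worked rescue case is stable across every convention family we examined
(raw vs max-normalised criteria, interval vs midpoint editing, weighted
vs plain probabilities) — scheme x2 is strictly best in all of them.
Absolute utility values should therefore be compared only within one
convention set.

## Group aggregation

Department prospect matrices are aggregated in three steps: consensus
matrix as the entry-wise mean of interval endpoints (chosen for the
idempotence property: a unanimous group reproduces the individual
matrix); per-department distance
`d_k = Σ_ij (|ΔL| + |ΔU|)/2` to the consensus; weights
`w_k ∝ m_k/(1 + d_k)` normalised to one, where `m_k` is an optional
per-department multiplier serving as the hook for collaboration-cost
adjustments (no quantitative synergy model is fitted).  The group matrix
is the weighted endpoint sum, and the scheme maximising the
criterion-weighted midpoint utility is selected.  Mean consensus,
interval distance and inverse-distance weighting are package design
choices; they satisfy idempotence, permutation equivariance, endpoint
convexity and weight monotonicity in distance, all property-tested.

## Synthetic data

`synth_table` emulates the tabular structure of an emergency event table
(defaults: 30 objects, 8 coverings, 3 decision classes, 3 planted
informative coverings — a desk-scale stand-in shaped like a real
response-level dataset with tens of events and a handful of retained
attributes).  The decision partition is drawn first; *informative*
coverings partition the consistent objects within their classes, so
every within-class block is effective and the planted set hits the whole
family; *noise* coverings consist solely of blocks forced to straddle at
least two classes (borrowing one outside object when a random block
lands pure — overlap is legal in a covering) and therefore contribute no
effective block.  At consistency 1.0 this makes planted-reduct recovery
exact by construction, which is what the recovery experiments measure;
at consistency 0 with no planted coverings the family is empty and the
error path is exercised.  What the generator does **not** emulate:
attribute correlation structure, missingness, epidemiological dynamics,
or class imbalance patterns of real surveillance data — passing recovery
tests demonstrate correctness of the reduction machinery, not field
performance.  `synth_evaluation` mirrors the evaluation-matrix structure
(mixed scalar/interval/linguistic entries, per-cell state probabilities
normalised to sum exactly one).

## Numerical choices and degenerate inputs

* Probabilities must sum to 1 within 1e−9; criterion weights within
  1e−9.
* Deterministic ordering everywhere: objects and coverings keep input
  order, sets serialise sorted by universe order, JSON output has sorted
  keys and a trailing newline.
* Greedy ties break to the earlier vertex in input order; equal-utility
  schemes rank by input order and are flagged as ties.
* All randomness flows through `numpy.random.default_rng(seed)`.
* Test problem sizes (≤ 12 objects / ≤ 8 coverings for the oracle
  cross-checks, 100 replicates for recovery) keep the exhaustive oracles
  exact while the whole suite runs in seconds.

## Known limitations

* The greedy cover is an approximation; optimality is only guaranteed on
  instances where it coincides with the exhaustive search (asserted on
  the worked example and bounded against it on random instances).
* Rule matching for unseen records requires either block membership or
  granulation predicates; arbitrary unseen symbolic values fall to the
  default rule.
* Continuous cumulative prospect theory with rank-dependent decumulative
  weighting over many ordered outcomes is out of scope, as are iterative
  consensus-reaching negotiation loops.
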