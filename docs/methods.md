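# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind `gennet`, in the spirit of the methods documentation that
accompanies statistical packages.

## The search problem

A Bayesian network over variables `V = {v_1, …, v_p}` is a DAG written as a
parent-set vector `G = (G_1, …, G_p)`, `G_i ⊆ V \ {v_i}`.  Score-based
structure learning maximizes a decomposable score

    score(G) = Σ_i localscore(v_i, G_i)

over DAGs.  Because every DAG has a sink (a node with no outgoing edges),
the optimum over a node set `V` satisfies the removal recursion

    bestscore(V) = max_{s ∈ V} bestscore(V \ {s}) + bestScore(s, V \ {s})
    bestScore(v, U) = max_{g ⊆ U, |g| ≤ d} localscore(v, g)

with `d` the in-degree cap.  Iterating over the subset lattice from
singletons downward gives the classic exact dynamic program, which is
exponential in `p` and practical only up to roughly 25–30 variables.

`gennet` restricts the lattice with screened *possible-parent sets*
`pp(v)`.  An ordering of nodes is **generational** when every node after
the first has at least one possible parent among its predecessors; it is
**complete** when it covers the whole feasible set.  The dynamic program
expands a subset `S` only by nodes `v ∉ S` with `pp(v) ∩ S ≠ ∅` (singletons
start unconditionally), so only subsets reachable along generational
orderings are materialized.  Two facts make this sound and useful:

* Without parent-set restrictions every node is a possible parent of every
  other node, so all `p!` orderings are traversed and, counting the
  `2^(k−1)` parent combinations available to the k-th sink of each path,
  the traversal covers `p!·2^(p choose 2)` network structures — the full
  space.  The test suite verifies this count for `p = 1..5` by exhaustive
  instrumentation.
* With restrictions, the program searches exactly the space of DAGs that
  are consistent with the `pp` map and realizable under a complete
  generational ordering.  The suite cross-checks the DP optimum against a
  brute-force enumeration oracle on 4-node instances (random `pp` maps and
  the unrestricted case, where the oracle ranges over all 543 labeled DAGs).

**Admissibility restricts the search space, not the chosen parents**: a node
admitted to a subset still receives the empty parent set when that
maximizes its local score.

### Incomplete coverage

When no complete generational ordering exists (that is, no subset of full
cardinality is reachable — typical when screening leaves some nodes with no
associations at all), the networks are reconstructed from the best
maximal-cardinality reachable subsets and the remaining nodes are attached
as isolated, empty-parent-set nodes.  This fallback is total,
score-monotone, and logged prominently.  When several maximal reachable
subsets exist, larger cardinality is preferred first, then higher
cumulative score; this is a package convention for a case the lattice
construction itself leaves open.

### Ties

Continuous scores tie only at numerical coincidence or across
score-equivalent structures (systematic under BGe).  Two scores within
`1e-9` (absolute) are treated as tied everywhere — best-parents tables,
best-sink lists, terminal subsets.  All tied optimal networks are
enumerated deterministically (sinks expanded in ascending node order) up to
`max_tied_networks` (default 32).

## Screening

* Continuous–continuous pairs: Pearson correlation with the two-sided
  t-test on `N − 2` degrees of freedom.  Categorical–continuous: one-way
  ANOVA F-test; categorical–categorical: Pearson chi-square test of
  independence.  Pairs involving a constant column, or any pair when
  `N < 3`, are untestable and receive p = 1 (screening stays total rather
  than erroring).
* Selection is either by Benjamini–Hochberg q-value ≤ `alpha_fdr`, with the
  BH family being **all** p(p−1)/2 tested pairs jointly (a single family is
  the conservative, reproducible choice when nothing dictates a per-node
  family), or by `|statistic| ≥ corr_cutoff` (meaningful for Pearson
  statistics; the correlation mode is intended for all-continuous data).
  Selected pairs yield symmetric candidacy: each member becomes a possible
  parent of the other.
* A designated outcome is treated as a pure sink — the phenotype terminates
  the pathway — and never enters any other node's possible parents.
  Survival outcomes are screened per feature by Cox proportional-hazards
  likelihood-ratio tests (1 df, chi-square), binary outcomes by logistic
  likelihood-ratio tests, both BH-adjusted across features; these paths
  require the FDR threshold since no correlation statistic exists.
  Optional covariates can be added to every Cox fit, entering both the
  feature model and the null.
* Phenotype-driven mode keeps the outcome's ancestor levels: level 1 is
  `pp(outcome)`, level k the union of possible parents of level k−1 nodes
  not already assigned a lower level, up to 2 or 3 levels.  The feasible
  set is the outcome plus those levels, and every parent set is intersected
  with it.

A non-convergent Cox or logistic fit during screening yields p = 1 with a
warning rather than an error.

## Local scores

All scores are on the "larger is better" scale; the BIC penalty
`(k/2)·ln N` corresponds to `k·ln N` on the −2·log-likelihood scale.

* **Linear-Gaussian (continuous child).**  OLS of the child on intercept +
  parents (categorical parents one-hot encoded, first level dropped), MLE
  residual variance `RSS/N`; `k` = design rank + 1 (coefficients, intercept
  and variance all count).  A rank-deficient design is fit by the
  least-squares pseudo-solution with `k` counting the rank, with a warning,
  so duplicated parents do not change the score.  A zero-variance fit gets
  the `−inf` sentinel: the search can never select a degenerate family, and
  ties at `−inf` are not enumerated.
* **Multinomial (categorical child, categorical parents).**  Saturated MLE
  cell probabilities per observed parent configuration;
  `k = (r − 1)·q` with `r` the child's level count and `q` the number of
  *observed* parent configurations (unobserved configurations contribute no
  likelihood and no parameters).  A categorical child with continuous
  parents is rejected with an instructive error: no conditional model is
  defined for that direction.
* **Binary outcome.**  Logistic regression, `k` = parents + intercept.
  Complete separation or non-convergence gives the `−inf` sentinel with a
  warning.
* **Survival outcome.**  Cox partial likelihood with Efron tie handling;
  `k` = number of parents (no intercept or variance in a partial
  likelihood) and the penalty uses `ln(#events)` — the effective sample
  size of the partial likelihood.  The covariate-free null partial
  log-likelihood is computed directly (for a tied group of `D` events with
  risk-set size `R` it contributes `−Σ_{l<D} log(R − l)`), matching the
  fitted-model convention.  Scoring a survival node inside a network by
  penalized Cox partial likelihood is a modeling choice of this package;
  the partial likelihood is not a joint density, so the total score mixes
  likelihood types when a survival outcome is present.
* **BGe.**  Normal–Wishart prior with `alpha_mu = 1`,
  `alpha_w = p̄ + 2`, prior mean `ν` = the sample mean, and
  `T = t·I` with `t = alpha_mu (alpha_w − p̄ − 1)/(alpha_mu + 1)` — the
  standard parameterization that guarantees score equivalence (all DAGs in
  a Markov-equivalence class receive equal totals; verified to `1e-8` on
  random data).  With `ν` at the sample mean the posterior scatter is
  `R = t·I + S_N` (the mean-shift term vanishes).  The local score is the
  difference of two subset log marginal likelihoods,

      log m(W) = −(l·N/2)·log π + (l/2)·log(α_μ/(α_μ+N))
                 + log Γ_l((N+δ)/2) − log Γ_l(δ/2)
                 + (δ/2)·log|T_W| − ((N+δ)/2)·log|R_W|

  with `l = |W|` and the subset degrees of freedom `δ = α_w − p̄ + l`.  The
  single-node case was validated against direct numerical integration of
  the normal–gamma integrand.  A non-positive-definite `R_W` raises an
  error (degenerate data).  BGe requires an all-continuous family.

Local-score tables hold every `(v, g)` with `g ⊆ pp(v)`, `|g| ≤ d`, plus
the empty set, i.e. `Σ_{j ≤ d} C(|pp(v)|, j)` entries per node.
Best-parents tables are filled by the standard subset recursion (best over
`U` = better of `U` itself, if within the cap, and the best over its
one-smaller subsets) over bitmasks of each node's possible parents; a
possible-parent set larger than 22 members is rejected with a pointer to
tighten screening (the table is exponential in that size).

## The simulator

The generator emulates the evaluation conditions for structure recovery:
`p` nodes split into independent (`p0`), source (`p1`), intermediate
(`p2`) and sink (`p3`) roles.  Role blocks are ordered sources →
intermediates → sinks (each block randomly permuted), which makes the role
semantics realizable under the parents-only-from-above rule; each
intermediate/sink draws 1..`indegree_true` parents (default 2, matching
the in-degree used in the recovery experiments) uniformly from the
eligible earlier sources/intermediates.  Data follow a linear-Gaussian
structural equation model: roots and independents are N(0, 1), children
are `Σ β·parent + N(0, noise_sd²)` with `|β|` uniform in `[0.5, 1.5]` and
random sign — mid-strength signals at N in the hundreds-to-thousands.
Defaults are fixed package-wide; where the evaluation design leaves a value
open (role proportions), the default split is roughly 20% independent,
30% sources, 20% sinks, remainder intermediate, with at least one source
and one sink.

A survival helper attaches exponential proportional-hazards event times
with rate `baseline_hazard · exp(Σ effect·x)` and independent exponential
censoring whose rate is solved (Brent root-finding on
`mean[c/(c + rate_i)] = censor_rate`) so the expected censored fraction
matches the request.

What the simulator does **not** emulate: non-Gaussian or nonlinear
dependencies, categorical variables, confounded measurement noise,
realistic gene-expression correlation structure.  Tests passing on this
generator demonstrate correctness of the search and calibration of the
screening under the linear-Gaussian model, not performance on real omics
data.

## Recovery metrics and the trend experiment

Predicted networks are compared to the generating DAG either on directed
edges or on skeletons.  `FDR = FP/(FP+TP)` with the no-discovery case 0/0
defined as 0; `Hamming = FP + FN` (directed by default, skeleton as an
option).  With tied optimal networks, metrics are computed per network and
summarized as best and mean; Markov-equivalent ties share a skeleton, so
undirected metrics coincide across them.

`gennet.experiments.recovery_study` runs replicated recovery across sample
sizes.  Replicates are paired by default — one generating network per
replicate, evaluated at every N with fresh data — because between-network
difficulty dominates the variance of cross-N comparisons and pairing
cancels it.  Under the default settings (p = 10, FDR cutoff 0.3, in-degree
2) mean undirected FDR decreases with N (≈0.10 at N = 500 vs ≈0.07 at
N = 2000 when estimated with 100 replicates per N).  The per-replicate
spread is large relative to that gap, so comparisons based on few dozen
replicates remain noticeably stochastic: with 25 paired replicates the
N = 2000 ≤ N = 500 ordering of the two means holds for roughly 4 out of 5
random seeds.  This is a power limitation of small replicate counts at
these effect sizes, not of the estimator.

## Numerical conventions

* Score-tie tolerance `1e-9` absolute, everywhere.
* Gaussian variance floor `1e-12` below which a fit is degenerate (`−inf`).
* Subsets are bitmasks over feasible-set indices; lattice levels are
  processed in cardinality order so level k reads only level k−1.
* All randomness flows through `numpy` Generators seeded explicitly;
  identical (parameters, seed) reproduce bit-identical networks and data.
* Missing values are rejected at load: every local score must reuse the
  same N, and no per-family complete-case convention is defined.
  Categorical labels are encoded as integer codes 0..L−1 in sorted label
  order with the label table retained.

## Known limitations

* The exhaustive test oracle enumerates DAGs on at most 5 nodes; the DP's
  optimality beyond that scale rests on the verified recursion, not direct
  enumeration.
* BGe and survival/binary outcomes cannot be combined (BGe families must be
  all-continuous); use BIC for mixed or outcome-bearing networks.
* Correlation-cutoff screening applies the cutoff to whatever association
  statistic the pair produced; with mixed data kinds (F or chi-square
  statistics) the FDR mode is the meaningful choice.
* The in-degree cap makes the search exact *conditional on the cap*; true
  networks with denser parents are represented by their best
  cap-constrained approximation.
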