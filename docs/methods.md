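# Methods

This note records the statistical model, the algorithms, the synthetic-data
conventions and the numerical choices behind `metatree`, at the level of
detail a user would need to audit or extend the package.

## Subgroup meta-analysis machinery

Per-study inputs are an observed standardized mean difference `d_k` and its
within-study sampling variance `var_k > 0`. For a partition into J
subgroups:

* FE weights `w = 1/var`; subgroup summaries are inverse-variance weighted
  means; `Q_j`, `Q_B`, `Q_T` are the weighted within/between/total sums of
  squares, with `Q_T = ΣQ_j + Q_B` exactly (both sides computed from the
  same group sums; tiny negative round-off in `Q_j` is clamped to 0).
* Residual heterogeneity is the pooled DerSimonian–Laird moment estimator
  with per-subgroup degrees of freedom `K_j − 1`, truncated at 0. A
  partition of all singletons carries no information (`ΣC_j = 0`); it
  returns τ² = 0 with a warning instead of erroring so that growth to the
  minimum node size never aborts.
* RE weights `1/(var + τ²)` with the *common* pooled τ². `Q*_B` is computed
  as the direct between-group sum of squares (algebraically identical to
  `Q*_T − ΣQ*_j`), so that a τ² = 0 fit reproduces the FE fit bit-for-bit.
* The subgrouping is tested by referring `Q_B` (or `Q*_B`) to χ² with
  `J − 1` df. Confidence intervals are normal-theory Wald intervals
  `mean ± z·(Σ weights)^(−1/2)` with the model's own weights; the model
  never specifies otherwise, and the FE intervals' deliberate neglect of τ²
  is exactly the undercoverage the simulation study quantifies.

## Tree growth

Moderators are encoded once per dataset: binary 0/1, ordinal by declared
level rank, continuous as-is (all split by `code ≤ t`, thresholds at
midpoints between consecutive observed values), nominal by level index
(split by subsets; all `2^(L−1) − 1` proper bipartitions of the observed
levels are enumerated — L is 3 in the reference design, so exhaustive
enumeration is exact and cheap). Candidate order is canonical — moderator
index ascending, thresholds ascending, subset bitmasks ascending — and ties
keep the earliest candidate, making growth deterministic with no RNG.
Row-subsets (cross-validation folds) inherit the parent's level coding so
fold rules live in one shared code space.

* **FE**: recursive partitioning minimising `Q_left + Q_right`
  (= maximising local `Q_B`). Node-best splits are independent, so the
  grown tree is order-invariant; the recorded order is best-first by local
  gain. Minimum node size 2 (configurable); a node is splittable only if
  both children reach it; zero-gain splits are allowed before pruning.
* **RE**: sequential partitioning. Every terminal node is a candidate
  parent; every candidate rule is scored by the whole-tree `Q*_B` after
  re-pooling τ² for the candidate partition (per-node `Q`, `C`, `K` enter
  the DL formula as cached scalars; the `Q*` sums are then accumulated over
  all studies at the candidate's τ²). The per-step τ² and `Q*_B` are
  recorded and are reproducible by re-fitting the terminal partition.

The hot loops (FE split search, RE step scoring) are numba-compiled; a
pure-Python full-refit reference path (`score_split_re`, `best_split_re`)
is kept and the test suite checks the two agree to 1e−7 on every step of
small instances of all four moderator types.

## Pruning

Candidate subtrees form a nested cost-complexity family:

* FE trees: CART weakest-link pruning on the FE-weighted node sums of
  squares; all minimising links collapse together; each family member
  carries the critical complexity α at which it becomes optimal.
* RE trees: the nested family of a sequential tree is the prefix chain of
  its split order; the cost-complexity members are the prefixes on the
  lower convex minorant of training impurity against size, with the same
  per-member critical α. (Pure size-indexed prefixes and the minorant
  convention bracket the reference null rejection rates from above and
  below; the minorant is the convention consistent with CART and is used
  throughout.)

Ten-fold cross-validation (folds uniform at random over studies, seeded;
the only randomness in a fit): each fold grows its own tree and family and
is evaluated at the geometric mean of each main candidate's α interval —
the rpart convention — rather than at matched size. A validation study's
error is its weight times the squared deviation from the training node
summary it routes to. FE uses weight `1/var`; RE uses the *marginal*
training weight `1/(var + τ²_0)` with τ²_0 estimated once per fold without
subgrouping — a per-size τ² would deflate the apparent error of small
trees (their own unmodelled heterogeneity inflates τ² and shrinks their
weights), collapsing every fit to the trivial tree. RE predictions are the
per-size RE node means. A nominal level unseen in a training node routes
to the child with more training studies (ties left). The error per size is
the mean per-study contribution; its SE is the sd of contributions divided
by √K. The c·SE rule picks the smallest size within `c·SE(argmin)` of the
minimum; the recommended c is 1 below the model's K threshold (80 for FE,
120 for RE) and 0.5 at or above it.

## Synthetic data

The generator emulates a factorial Monte-Carlo design: K ∈ {40, 80, 120}
studies; M ∈ {5, 10, 20} moderators of one type per dataset (binary,
3-level nominal, 3-level ordinal, continuous); independent or correlated
moderators; residual heterogeneity σ²τ ∈ {0, 0.025, 0.05}; effect size
δ_I ∈ {0.3, 0.4, 0.5, 0.8}; five true structures (A none, B main effect,
C two-way, D two two-way, E three-way interaction).

Latent variables are multivariate normal. Continuous moderators are
N(20, 10²) rounded to one decimal (≈ 37/71/102 distinct values at
K = 40/80/120); binary dichotomizes at the mean; nominal/ordinal cut at the
1/3 and 2/3 population quantiles (nominal interval labels A/B/C randomly
permuted per column; ordinal keeps order). Correlated datasets draw a
one-factor correlation matrix `R = λλ' + diag(1 − λ²)`, loadings uniform
on ±√0.4 — positive definite by construction with pairwise correlations in
(−0.4, 0.4), the range of the real co-occurrence matrix the design
emulates; polytomization attenuates the realized correlations, as in real
data. What a one-factor structure does *not* emulate is an arbitrary
multi-factor correlation pattern; none of the reported quantities are
sensitive to this (the reference's own variance analysis finds the
correlation factor negligible).

The effective side of a moderator is the side away from its lowest
category: binary level 1, ordinal {2, 3}, nominal {B, C}, continuous
> 20. Models: B effect on eff(x1); C on eff(x1)∧eff(x2); D on
(eff(x1)∧eff(x2)) ∨ (¬eff(x1)∧eff(x3)); E on eff(x1)∧eff(x2)∧eff(x3);
effective subgroups have mean δ_I, others 0.

Study sizes are **per-arm**: n_k ~ N(n̄, (n̄/3)²), rounded, clamped at 5
(10 subjects total). True effects δ_k ~ N(Δ_k, σ²τ); observed effects come
from the two-group noncentral-t model: t ~ nct(df = 2n−2, ncp = δ√(n/2)),
d = t·√(2/n) times the Hedges factor 1 − 3/(4df − 1) (a flag, default on),
variance 2/n + d²/(4n). Two closed-form fingerprints of the reference
results calibrate these conventions: the FE undercoverage
2Φ(1.96·√(v/(v+τ²)))−1 = 0.834 at v = 2/80, τ² = 0.025, and the
between-replication SDs of the three subgroup estimates in the medium
design cell, which imply subgroup sizes near 27/14/38 out of K = 80. Both
are reproduced; the total-n reading and a top-tercile-only ordinal side
are not.

Passing tests on these data show the pipeline behaves as designed under
the stated sampling model; they do not certify behaviour under publication
bias, dependent effect sizes, missing moderators, or non-SMD outcomes,
none of which the generator emulates.

## Evaluation harness

Criteria per replication: (1)/(2) a pruned tree with ≥ 1 split whose Q
test is significant at α (Type I error under model A, power otherwise);
(3) recovery — the pruned tree's set of splitting moderators equals the
true set exactly, with no significance requirement attached (a switch adds
one). The meta-regression comparator encodes the true structure as
indicator regressors (intercept plus one term per interaction branch),
fits by weighted least squares with unscaled `(X'WX)⁻¹` covariance and
z-tests (FE), or re-weights with the DL residual τ² (RE) — the standard
meta-analytic conventions, cross-checked against metafor in the tests —
and scores recovery as all true terms significant at 0.05.

Subgroup-estimate bookkeeping uses the single medium cell (model C, K=80,
n̄=80, σ²τ=0.025, M=10, δ_I=0.5, correlated ordinal moderators) and scores
only trees matching the canonical two-split shape (x1 at the root, x2
inside x1's effective side; the mirrored split order is excluded so
subgroups stay comparable) — about 46% of replications, matching the
reference's retrieval fraction.

Design-cell sampling is balanced: each factor's levels are repeated to the
cell count and shuffled independently, so marginals are exact while
combinations vary. Every replication derives its data seed and CV seed
from `SeedSequence(base_seed, spawn_key=(rep,))`, making results
independent of execution order.

## Problem sizes in the shipped runs

`scripts/acceptance.py` uses: 24 cells × 100 reps (FE, K=40; both c),
18 × 100 (FE, K=120), 16 × 100 (RE, K=120; both c), 800 reps of the medium
cell for coverage, 24 × 75 for model-B recovery — about 12–15 minutes on
one CPU. The test suite runs the same computations at roughly one-quarter
scale with tolerances of three Monte-Carlo standard errors at that scale.
Type I means are insensitive to the non-K design factors, so balanced
sub-samples of cells estimate the full-design mean without visible bias;
the between-cell SD enters the tolerance explicitly.

## Known limitations

* The greedy (FE) and sequential (RE) searches find local optima; a
  look-ahead or global search can find splits with larger Q_B.
* Continuous moderators with many candidate thresholds invite spurious
  local spikes; recovery is lowest for them, as in the reference design.
* The Q test after tree search is a pseudo-test — Type I error is
  controlled by the pruning rule, not by the χ² reference — so results are
  hypothesis-generating, not confirmatory.
* Per-subgroup (non-pooled) τ², alternative τ² estimators (REML,
  Paule–Mandel) and Knapp–Hartung adjustments are out of scope.
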