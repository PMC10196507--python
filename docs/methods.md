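# Methods

## Model and problem

`binscm` addresses causal discovery on complete binary records. The data
model is a binary structural causal model (b-SCM): each variable
X_k ∈ {0,1} is the logical OR of its parents and an independent
Bernoulli(p) noise term N_k drawn fresh per row and per variable. OR gates
encode "any active cause suffices" — natural for deprivation indicators,
where any one of several upstream problems can switch an indicator on —
and have two consequences the inference leans on: an active parent forces
its child on in every row (deterministic implication), and conditioning on
a variable that sits on every path between two others collapses at least
one of them to a constant inside the stratum.

Two outputs are distinguished. The *directed* graph claims direct
cause-effect relations. The *transitive* reading accepts mediated
relations (X causes Z through Y) and is scored by comparing reachability
closures. We define the transitive output as the closure of the directed
edges of the final graph; edges the direction test leaves undirected are
association claims without a direction claim and enter neither task. A
supported alternative would count an undirected edge as both orientations,
but that lets a single confounded-but-unresolved pair inject two false
positives into the closure, which contradicts how the two tasks separate
empirically; analysts who want the permissive reading can closure the
undirected pairs themselves from the report.

## Estimation

All probabilities are support/confidence counts: exact integer numerators
and denominators, one division at the end, so algebraic identities (joint =
conditional × marginal; odd difference = P̂₁₁ − P̂₁·P̂·₁) hold to rounding.
Pair *alignment* evaluates every pair at the value configuration that
carries the association: if the raw odd difference at (1,1) is negative,
column j is complemented and the flip recorded, so downstream reports can
always state the association sign on the original coding. For binary
variables the absolute covariance is identical across all four value
assignments, so alignment affects signed statistics only.

Uncertainty comes from a row bootstrap: q replicate datasets (default
q = 100, a compromise between CI resolution at the 2.5% tails and runtime;
configurable), each statistic evaluated once per replicate, and 95%
percentile confidence intervals (linear interpolation between order
statistics) reported throughout. Replicate streams are spawned from one
master seed, making every result a pure function of (data, q, α, seed).

## Decision rules

Each statistic's bootstrap sample is turned into a decision on
H0: "the statistic is zero" in one of two ways:

* **Rank-against-zero** (dependency degrees, which are nonnegative by
  construction): a Mann-Whitney rank test of the q samples against an
  equal-length all-zero reference, tie-corrected normal approximation.
  Because the statistic is an absolute value, this asks whether *any*
  nonzero dependency mass is present; it returns p = 1 exactly when the
  samples are all zero. It is deliberately sensitive — its role is to
  certify the exact-zero case, not to calibrate a false-positive rate.
* **Sign-consistency** (signed statistics: odd difference, causal
  direction, and the filter's per-stratum conditional covariance):
  p = 2·min(frac(samples < 0), frac(samples > 0)), with p = 1 for an
  identically zero sample. For smooth statistics this coincides with
  "the 95% percentile CI excludes zero" and holds the false-positive rate
  of the association step near α (the false-positive property test in
  `tests/test_acceptance.py` measures this over 200 independent-pair seeds
  at α = 0.05). The atom at exactly zero is counted against neither
  side: statistics that are scaled counts of rare row configurations — the
  covariance of a deterministically implied pair is p̂(cause)·n₀₀/n, where
  n₀₀ counts the handful of rows with the child off — are bounded at zero
  and never cross it, so their zero-mass is one-sided concentration rather
  than evidence for the null. This matters at high noise (p = 0.5, n = 500
  the child X6 is off in ~8 rows): treating the atom as a null-side tail
  would erase exactly the weak edges the method is supposed to find, while
  a straddling distribution (a genuinely independent pair) still fails.

A naive alternative — ranking the bootstrap sample against zeros for the
signed statistics too — has no level control at all: under independence
the bootstrap distribution is centred on the *point estimate* with the
same spread, so any test that treats the q samples as independent evidence
about the mean rejects for |estimate| ≳ 0.2·σ/√n (false-positive rate
≈ 85%). That construction is available for comparison via
`test_nonzero(..., method="rank-zero")` but is not used for signed
decisions.

## Graph inference

1. **Association.** For every pair of non-degenerate columns, keep the
   pair when the dependency test (one-sided, rank-against-zero) and the
   odd-difference test (two-sided, sign-consistency) both reject at α
   (default 0.05, per test, uncorrected — estimation statistics are
   reported precisely so that readers can apply their own stringency;
   users can lower α for a Bonferroni-style correction).
2. **Confounding filter.** For each candidate (i, j) and each third
   variable Z: test the conditional covariance in the strata Z = 0 and
   Z = 1 (two-sided, sign-consistency). A stratum is informative when
   non-empty in at least half the replicates. Z screens the pair off when
   no informative stratum rejects; any screened pair is removed. Under OR
   determinism a separating Z makes each stratum degenerate (one variable
   constant), the conditional covariance is exactly zero in every
   replicate, and removal is certain; for a merely confounded pair the
   non-degenerate stratum is independent and fails with probability ≈ 1−α.
   Conditioning sets are single variables; the framework does not claim
   faithfulness beyond that.
3. **Orientation.** For each surviving edge, the causal-direction test
   (two-sided, sign-consistency): rejection orients the edge toward the
   sign of the mean; otherwise the edge stays undirected — the
   "dependency without causal relation" outcome that, on real survey data,
   flags a likely unmeasured confounder. Directed records carry
   P̂(effect = 1* | cause = 1*) (at aligned values) with mean and CI, the
   degree of causal direction; for a parentless cause this equals the
   interventional P(effect | do(cause)).

The per-replicate pair counts are matrix products (O(d²n) per replicate),
and stratum counts are built lazily per conditioning variable, so the
whole pipeline is O(q·d²·n) with small constants; the benchmark
(d = 10, n = 1000, q = 100) runs in well under a second.

## Simulator and what the tests do (and do not) show

The simulator draws i.i.d. noise and evaluates gates in topological order;
an enumeration oracle computes exact marginals by summing over the 2^m
ancestral noise assignments (m ≤ 20), giving closed forms such as
P(X6 = 1) = 1 − (1 − p)^6 in the 10-variable benchmark. The benchmark
fixes three gates (X1 ← X2 ∨ X3, X4 ← X2 ∨ X5, X6 ← X1 ∨ X4) and seven
parentless indicators, with noise p ∈ {0.5, 0.3, 0.1, 0.05} and sample
sizes up to n = 1000 — the study conditions reproduced by
`scripts/acceptance.py` and `tests/test_acceptance.py` (10 simulation
seeds per regime, q = 100, α = 0.05).

What passing these tests shows: the pipeline recovers OR-gate structures
of this size and noise range, controls false positives on independent
pairs, and the statistics obey their algebraic identities. What it does
not show: behavior under non-OR mechanisms (AND/XOR gates, inhibition),
latent confounding beyond single measured variables, selection effects,
missing data (rejected at parse time, never imputed), or the very sparse
regime where both indicators of a pair are rare and the percentile
bootstrap's small-sample bias can fabricate sign-consistent negative
covariance. Deterministic implication is load-bearing for the filter: on
mechanisms with exceptions ("noisy OR"), separating strata are no longer
exactly degenerate and the filter loses its certainty, degrading gracefully
into the merely-confounded case.

## The frequent-pattern baseline and scoring

The baseline keeps pairs with aligned joint support ≥ 0.05 (support
thresholds in frequent-pattern mining are conventionally a few percent;
the value is configurable) and a significant odd difference, then orients
by directly comparing the two confidences — no confounding check and no
significance requirement on the direction. That makes it strong on the
transitive task (every ancestor pair is associated) and weak on the
directed task, the contrast the benchmark runner quantifies. Scoring
counts ordered edges: precision TP/(TP+FP), recall TP/(TP+FN), F1 their
harmonic mean, with the transitive task closing both edge sets first.

## MPI

The deprivation degree d_i is the unweighted fraction of active indicators
in row i; a row is deprived when d_i strictly exceeds the threshold (ties
are not deprived — the cutoff is country-specific policy, so it is a
required parameter rather than a default); q0 is the deprived fraction,
a0 the mean d_i among the deprived (0 when none), and M0 = q0 × a0.
Weighted indicator schemes are out of scope.

## Numerical and degenerate-input conventions

Degenerate (constant) columns produce warnings and are excluded from pair
enumeration; a dataset with fewer than two usable columns is an error. A
conditional probability with a zero-support conditioning event raises a
distinct error rather than returning 0. An odds ratio with a zero
denominator cell returns +inf plus the zero-cell names — no continuity
correction, since the finite odd difference carries the inference and a
correction would mask sparsity. Replicates on which a statistic is
undefined are skipped and counted; a statistic undefined on more than half
the replicates is refused as unstable. Report pairs are sorted
lexicographically and outputs are byte-reproducible for a fixed
configuration.
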