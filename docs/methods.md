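# Methods

`sevnet` compares the structure of symptom-domain interrelations across
groups at different levels of psychopathology severity. Because group
differences in symptom *severity* mechanically change item variances —
and hence the covariances that network models are built from — the
pipeline first equalizes endorsement prevalences across groups with
per-group severity thresholds, then estimates a binary Markov random
field per group, and finally compares the groups on global strength,
edge-level similarity and community structure. A synthetic-cohort
generator with a known planted dependence structure serves as the test
bench for every stage.

## The Ising model and its conventions

Each group's network is a pairwise Markov random field over binary
endorsement states x ∈ {0,1}^p:

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} β_ij x_i x_j )

**States are coded {0,1}, not {−1,+1}.** Couplings are encoding-dependent:
a β of 1.5 in this convention is *not* the same dependence strength as a
1.5 in spin coding. The {0,1} convention is used because the conditional
distribution of node i given the rest is then exactly a logistic
regression with intercept τ_i and coefficients β_ij, which is what the
nodewise estimator fits.

For p ≤ 16 the distribution is enumerated over all 2^p states. The
enumeration is the package's internal oracle: the exact i.i.d. sampler
draws from it, the Gibbs sampler is validated against it, and estimator
tests compare fitted coefficients to the true conditionals it implies.

## Synthetic cohorts

The generator emulates a broadband self-report questionnaire (items rated
0 = not true / 1 = somewhat or sometimes true / 2 = very or often true)
aggregated into 11 symptom domains, for four severity groups of 492, 205,
291 and 303 individuals. Per group:

1. **Latent states.** Each individual's binary domain-endorsement vector
   is drawn from that group's ground-truth Ising network (exact sampler).
   The default ground truth plants two communities — an ADHD-like triple
   (attention, hyperactivity, impulsivity; pairwise couplings 1.5) and a
   depression/anxiety-like quadruple (core depression, negative
   cognitions, worrying, fearfulness; couplings 1.0) — with the remaining
   four domains (fatigue, pain, emotion dysregulation, substance use)
   isolated. Thresholds are set so marginal endorsement prevalences are
   moderate (≈ 0.24–0.30).
2. **Item emission.** Item k of domain d is a cumulative-logit draw over
   {0,1,2} with location `difficulty_k + 4.0·z_d + offset_g + trait`,
   where z_d is the latent state, offset_g ∈ (0, 0.5, 1.0, 1.5) is the
   group severity shift, and `trait` ~ N(0, 1) is an individual,
   *domain-specific* heterogeneity term. Item difficulties are spread over
   (−3.5, 0) within each of the 8 items per domain.

Design rationale for the emission defaults, fixed once: the slope of 4
makes items strong indicators of the latent state (so the binarized
domain scores carry enough signal for network recovery at group sizes of
a few hundred, as in the study setting); the trait term produces the
within-group score dispersion real broadband questionnaires show and
smooths the domain-score distributions, so the integer threshold grid is
fine enough for prevalence matching; making the trait independent across
domains keeps all *cross-domain* dependence attributable to the planted
Ising structure. The mildest group sits near the floor of the response
scale (most item scores 0) — exactly the floor-effect regime the
thresholding stage exists to neutralize.

What the generator does **not** emulate: item-level content overlap
between domains, measurement non-invariance across severity, missing
data, and any general ("p-factor") severity correlation beyond the
planted network. Passing tests therefore demonstrate that the pipeline
recovers known structure under clean conditions, not that it is robust to
those real-data complications.

## Severity thresholds

For each group and domain, the integer cutoff c (endorsed iff score ≥ c)
minimizing |achieved prevalence − target| is chosen, ties broken to the
lower cutoff. The default per-domain target is the pooled-sample
prevalence at the most-severe group's median-crossing cutoff (the
smallest c at which that group's prevalence drops to ≤ 0.5); targets are
configurable. For binary variables the variance is p(1−p), so matched
prevalences imply matched variances; the pipeline verifies this with
Brown–Forsythe (median-centered Levene) tests, chosen for robustness to
the extreme non-normality of 0/1 data. Cross-group prevalence ranges are
bounded by the discreteness of the achievable-prevalence grid, which the
reports quote alongside the ranges.

## Network estimation (eLasso)

Each node is regressed on all others by L1-penalized logistic regression
over a 100-point log-spaced penalty grid running from the data-derived
λ_max (the smallest penalty zeroing all coefficients, by the KKT
conditions) down to 0.01·λ_max. The penalty per node is selected by the
extended Bayesian information criterion

    EBIC(λ) = −2ℓ + k·ln(n) + 2γ·k·ln(p−1),

with k the number of nonzero coefficients and γ = 0.25 (the standard
eLasso default; configurable). Directed coefficients are symmetrized by
the AND rule — an edge is present only if both directions survive — with
the edge weight the mean of the two coefficients; the OR rule is
available. Both choices are recorded on every fitted network.

Numerical notes:

- The solver is a glmnet-style iteratively-reweighted quadratic
  approximation with inner cyclic coordinate descent and warm starts
  along the path. Convergence is objective-scaled (largest per-update
  h_j·Δβ_j² below 1e-7 times the null deviance), the convention of
  pathwise coordinate-descent software; an absolute per-coefficient
  criterion is scale-dependent and needlessly slow on correlated data.
  At tight tolerance the unpenalized limit agrees with an independent
  IRLS fit to ~1e-7.
- λ_max carries a 1e-8 relative margin so the first path point is exactly
  the empty model: EBIC must be able to select k = 0, otherwise null data
  would be compared only among spurious k ≥ 1 fits.
- Binary design matrices are collapsed to unique row patterns with counts
  before fitting — an exact reweighting of the likelihood that makes the
  permutation and bootstrap loops (tens of thousands of refits) feasible.
- Nodes constant within a group are an error at the user-facing fit; in
  permutation/bootstrap resamples they are dropped for that refit only
  (re-entering as isolated nodes) and the event count is reported.

## Group comparison

**Global strength** is Σ_{i<j} |w_ij|. Differences between two groups are
tested by permutation: individuals are pooled and repeatedly regrouped at
the original group sizes, both networks are re-estimated with identical
settings, and |ΔS| is recorded; the two-sided p-value uses the add-one
estimator (1 + #{|ΔS_perm| ≥ |ΔS_obs|}) / (1 + B), so p ≥ 1/(B+1) and an
exact zero is impossible. Pooled rows are put in canonical order before
permuting, making the null distribution invariant to input row order and
(for equal group sizes) to swapping the group labels. With K groups all
K(K−1)/2 pairs are tested; no omnibus K-group test is attempted.

**Similarity** between two fitted networks is summarized by the Spearman
rank correlation over all p(p−1)/2 upper-triangle weights (zero weights
included — excluding them would condition on the estimation outcome;
configurable) and by the Jaccard index of the edge sets, with 1 returned
(and logged) when both sets are empty.

## Community detection

Estimated edge weights can be negative, where modularity is undefined;
community detection and modularity therefore consume absolute weights.
Newman's weighted modularity Q is 0 for the all-in-one partition on every
input, and values above 0.30 are conventionally read as clear community
structure. Two algorithms are run per network:

- **Walktrap** (igraph implementation, walk length 4), cut at the
  modularity-maximizing level of the merge tree.
- **Girvan–Newman edge betweenness**, implemented in-package so that
  betweenness can use the distance transform 1/weight (strong edges are
  short) while modularity is evaluated on the original absolute weights;
  ties in betweenness break lexicographically on the sorted node pair and
  modularity ties keep the coarsest stage, making runs bit-reproducible.

For small graphs an exhaustive search over all set partitions (p ≤ 10)
provides the reference optimum; both algorithms accept an
`exhaustive_check` flag that records their gap to it. Cross-group
community similarity is reported as adjusted Rand indices plus a per-node
membership trajectory table.

## Stability

Edge-weight accuracy is assessed by a nonparametric bootstrap: rows are
resampled with replacement at the original n, the full network is
re-estimated per resample, and each edge is summarized by its percentile
CI (95% default) and selection frequency. Percentile CIs of a penalized
estimator need not contain the point estimate, and shrinkage biases them
toward zero — at moderate endorsement prevalences the CI of even a strong
edge can sit visibly below the generating coupling. Per-resample seeds
are derived from the master seed by counter, so results do not depend on
execution order. Because symptom-network CIs are typically wide and
overlapping, the robustness re-run repeats strength comparison, NCT,
Jaccard and community detection on unweighted (0/1) networks, where
global strength degenerates to the edge count.

## Problem sizes in the test suite and acceptance script

The validation suite uses enumerable fixtures (p = 6 chain with couplings
1.5 and thresholds −0.75; two-community nets; a p = 5 single-edge net
with coupling 2.0 and thresholds −2.0, chosen to match the ≈ 0.2
endorsement prevalences of the thresholded cohorts). Simulation studies
run at: 50 replicates for estimator recovery (n = 2000) and null
specificity (n = 1000); 200 replicates of 200-permutation tests for NCT
size and 50 replicates of 500-permutation tests for power; 30 replicates
of 200-resample bootstraps for CI behavior. The acceptance script runs
the full default cohort with 300 permutations and 250 bootstrap
resamples — comfortably past the point where the reported quantities
stabilize, while keeping a full from-scratch reproduction to minutes on
one CPU. For substantive analyses the package defaults remain 10 000
permutations and 2 500 resamples.

## Known limitations

- Exact sampling and the enumeration oracle require p ≤ 16; beyond that
  only the Gibbs sampler is available and estimator tests lose their
  exact reference.
- The NCT refits EBIC-selected sparse networks inside every permutation;
  with very small groups, permutations can produce constant nodes, which
  are dropped per-refit (counted) and slightly blur the null when drops
  are frequent.
- Modularity on absolute weights treats a strong negative association as
  cohesive; with predominantly positive estimated edges (the regime here)
  this is immaterial, but signed-network community methods are out of
  scope.
- The walktrap stage delegates to igraph; its merge order for exactly
  tied distances follows that library's internal conventions (still
  deterministic for fixed input).
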