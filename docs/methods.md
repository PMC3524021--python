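# Methods

## Model

The disease phenotype X (0 = control, 1 = case) and M genotyped SNPs
(minor-allele counts 0/1/2, each treated as a 3-state categorical variable
even when a state is unobserved) form a two-layer Bayesian network: edges
run only from SNP nodes into X. Learning which SNPs are parents of X is a
model-selection problem over parent sets Pa(X); a parent set of size k has
q = 3^k configurations and complexity q(r−1) with r = 2 phenotype states.
Everything is expressed in natural logarithms (nats); a fixed log base
rescales all scores identically and cannot change rankings.

For a parent set, the maximized local log-likelihood is
Σ_jk N_jk log(N_jk/N_j) with the 0·log 0 = 0 convention, so unobserved
configurations contribute nothing; equivalently −N·H(X|Pa(X)). The mutual
information MI = H(X) − H(X|Pa(X)) links the likelihood gain over the empty
structure to the G² independence statistic, G² = 2N·MI, with
DF = (r−1)(q−1) counted from the theoretical q (an `observed_configurations`
switch uses the observed configuration count instead; off by default, since
the theoretical count matches the standard G²/χ² convention).

### Scores

* AIC: loglik − q(r−1). Algebraically identical to
  ½(G² − 2·DF) + (empty-structure AIC), i.e. the AIC penalty is half the
  χ² null variance of G².
* BIC: loglik − ½ q(r−1) log N.
* EpiScore (default): ½(G² − Var_D(G²)) + (empty-structure AIC), replacing
  2·DF with a variance estimated from the data itself. For the empty
  structure the EpiScore is the empty-structure AIC (no variance penalty).
  Substituting Var_D(G²) = 2·DF recovers the AIC exactly, which the test
  suite asserts as an identity.

The shared additive constant is the penalized empty-structure score
loglik₀ − (r−1) (loglik₀ = −N·H(X)). The published upper-bound expression
N·H(X) + loglik₀ is implemented literally in `score_upper_bound`; note that
it is identically zero, since loglik₀ = −N·H(X): every EpiScore on a
dataset is ≤ 0.

### Variance estimation

Var_D(G²) is the variance of G²(X, Pa(X)) under the null of no X–Pa(X)
association *given the observed margins*, estimated by phenotype
permutation: B relabelings of the case/control labels, sample variance
(ddof = 1) of the resulting G² values. Implementation device: conditional
on all margins, the case-count vector across configurations under random
relabeling is exactly multivariate hypergeometric, so the B replicate
tables are drawn from that distribution directly — the identical null in
O(B·q) instead of O(B·N) per parent set. A test cross-checks the
hypergeometric sampler against brute-force label shuffling.

**Choice of B.** Default B = 1000. The search compares on the order of M
candidate children per expansion and keeps the argmax, so Monte-Carlo error
in the penalty is *selected on*: children whose penalty happens to be
underestimated look like score improvements (a winner's-curse effect). At
B = 100 the penalty's relative standard error (≈ 15–30%) produced spurious
parent additions at several times the exact-penalty rate in simulation; at
B = 1000 the relative SE is ≈ 4–5% and the spurious-addition rate matches
the exact-penalty limit. B remains a `ScoringConfig` parameter. Each
estimate is seeded deterministically from (global seed, sorted parent
tuple) and cached per sorted tuple, making all results reproducible and
independent of traversal order; the contingency table is always built in
sorted parent order (G² is invariant to configuration relabeling) so the
estimate itself is order-invariant.

**Calibration.** On large well-filled null tables the permutation variance
converges to the χ² value 2·DF (asserted at N = 5000, one parent, within
sampling tolerance of 4). At moderate N the deviation from 2·DF grows with
the parent count; its *direction* depends on cell filling: at MAF 0.5 and
N = 1000 three-parent tables sit systematically above 52 (measured mean
≈ 55), while low-MAF (sparse) tables fall below 2·DF because empty and
near-empty configurations cannot contribute variability. The directional
calibration test therefore uses MAF-0.5 genotypes, the regime the simulated
study operates in.

## Search

Depth-first search over parent sets starting from the empty set, children
canonicalized to sorted tuples and never revisited. Candidate children are
ordered by descending single-SNP G² (tie: ascending index).

* `practical` (default): greedy deepening. At each state, children are
  scored in order; a child that strictly improves the state's score is
  recursed into; the first non-improving child ends the sibling loop. Not
  guaranteed globally optimal, but every scored state remains a candidate
  for the returned maximum, and the returned best dominates the whole
  visited trace.
* `bounded`: recurses into every child unless the variance-increment bound
  fires (the penalty increment between nested parent sets exceeds 2N·H(X),
  the largest possible G² gain). Because the bound essentially never fires
  on realistic data, bounded mode is exhaustive — and therefore exact — up
  to `max_parents`; it is used as the oracle mode on small panels and
  verified against brute-force enumeration.

**Statistical-domain guard.** Parent sets stop growing once the average
samples per configuration would drop below `min_samples_per_config`
(default 10, a Cochran-style adequacy rule): beyond that point the
saturated likelihood drives G² mechanically toward its ceiling 2N·H(X)
while the true permutation variance plateaus at O(N) — far below the
2·DF-scale growth — so the variance penalty can no longer track complexity
and score comparisons become meaningless overfitting contests. At
N = 2000 this caps parent sets at 4 SNPs (q = 81); setting the parameter
to 1 disables the rule. The same cap applies to MCMC screening states.

## Screening

Metropolis-Hastings over parent sets with uniform add/remove-one-SNP
proposals; acceptance probability min{1, exp(ΔEpiScore)} under a uniform
structure prior. The neighbourhood-cardinality ratio is fixed at one even
at the two boundary states (empty set, size cap), a deliberate
simplification with negligible effect on screening. With the cap at least
M, every state has exactly M neighbours and the chain's stationary law is
exactly the Gibbs distribution exp(EpiScore)/Z, which the test suite
verifies on an enumerable 4-marker instance via batch-means standard
errors. Edge posteriors are post-burn-in inclusion frequencies; the default
candidate rule keeps any SNP with posterior > 0 (any occurrence), with a
configurable threshold because the literal rule grows permissive with chain
length. Defaults: 200·M iterations, 10% burn-in, state cap 10 (before the
domain guard). Screening runs automatically above a 1000-marker panel
(`screen_threshold`); smaller panels go directly to search.

## Simulator

Four penetrance models over two or three unobserved disease loci with
baseline risk α (default 0.01 — typical for this model family; penetrances
are validated ≤ 1, never silently clipped):

| model | penetrance f(g) |
| --- | --- |
| 1 multiplicative | α(1+λ)^(g₁+g₂) |
| 2 interaction multiplicative | α(1+λ)^(g₁·g₂) |
| 3 interaction threshold | α(1+λ·1[g₁≥1 ∧ g₂≥1]) |
| 4 three-locus genotypic | α·θ^1[g ∈ risk set] |

The default model-4 risk set is every combination with at least one minor
allele at all three loci; it is configurable, as the exact published
three-locus table admits variants, and with MAF 0.5 it leaves the
single-locus signal far weaker than the joint signal on the evidence
scale (asserted in tests).

Disease-locus genotypes are Hardy-Weinberg draws at `disease_maf`; disease
status is Bernoulli(penetrance); the cohort is filled to exactly
n_cases/n_controls by rejection from a population stream (retrospective
sampling). Each locus is observed through a tag marker of equal MAF in LD
r²: per haplotype, the marker allele is Bernoulli with
P(m=1|l=1) = p + r(1−p), P(m=1|l=0) = p(1−r), r = √r², realizing
D = r·p(1−p); r² = 1 copies the locus exactly. Remaining markers are null
HWE SNPs with MAFs uniform on (0.05, 0.5) — a standard common-SNP range —
and disease-marker positions are placed uniformly at random (seeded),
recorded only in the `SimTruth` object so position cannot leak to methods
under test. Replicate seeds derive deterministically from
(base seed, replicate index) and stay below 2³¹; any replicate regenerates
standalone.

What the simulator does *not* emulate: LD blocks and haplotype structure
among null markers, population stratification, genotyping error and
missingness. Passing tests therefore demonstrate correct behaviour under
clean HWE panels with a single tagged signal, not robustness to the
confounders of real GWAS data.

## Evaluation

precision = |detected ∩ truth|/|detected| (0 for an empty detection — a
total order over replicates is needed for averaging), recall =
|detected ∩ truth|/|truth|, distance = √((1−precision)² + (1−recall)²),
power = fraction of replicates detecting *exactly* the truth. Per-model
tallies: `o` counts replicates with every disease SNP detected (recall 1,
extras allowed), `plus`/`minus` sum extra/missed SNPs over replicates.
Spreads are sample standard deviations. Per-replicate failures are recorded
in the summary, never silently dropped.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full study conditions: 50 replicates per
model, 100 markers, 1000/1000 cohorts (a few minutes on one CPU). The test
suite runs the same two experiments at 25 replicates — the three-locus
claim is degenerate-perfect, so reduced replication preserves it — plus
exhaustive-search oracles at M = 8, stationarity at M = 4 with 2·10⁵
iterations, and variance calibration at N ≤ 5000.

## Known limitations

* The EpiScore's variance penalty equals ≈ 2·DF on well-filled tables, so
  its behaviour there is AIC-like; its advantage over AIC appears at
  moderate N/q, and outside the χ² regime (q ≳ N/10) no variance estimate
  tracks complexity — hence the domain guard rather than a claim that the
  score self-regularizes.
* Greedy practical search follows marginal-signal gradients; pure
  zero-marginal interactions (e.g. exact XOR pairs) can be missed unless
  bounded mode (exhaustive on small panels) or screening-plus-restriction
  is used.
* Screening posteriors are qualitative shortlists, not calibrated
  probabilities; acceptance-rate and trace output are the only convergence
  diagnostics provided.
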