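# Methods

## The estimation problem

A cohort of offspring is produced by an unknown number of parents N_P.
A random sample of N_OBS offspring, with parentage known (in practice,
reconstructed from genotypes; here, known by simulation), yields a
*detection vector* y: for each of the N_DET distinct parents named by the
sample, the number of sampled offspring naming it. Each offspring names
exactly one mother and one father, so Σy = 2·N_OBS. The task is to infer
N_P — detected parents plus the parents whose offspring were never
sampled — from the shape of y, exactly as species-richness estimators
infer unseen species from the abundance histogram of seen ones.

## Nonparametric estimators

**Chao1** (bias-corrected): `N̂ = N_DET + [a₁(a₁−1)/(2(a₂+1))]·k` with
`k = (N_OBS−1)/N_OBS` and a_j the number of parents detected exactly j
times. The `a₂+1` device keeps the estimate finite when no doubletons
exist. The variance uses the canonical bias-corrected form

    var = a₂[ (k²/4)r⁴ + k²r³ + (k/2)r² ],   r = a₁/a₂     (a₂ > 0)

with the standard no-doubleton form
`k·a₁(a₁−1)/2 + k²·a₁(2a₁−1)²/4 − k²·a₁⁴/(4N̂)` when a₂ = 0, and
variance 0 (degenerate interval, flagged) when a₁ = 0. Several published
branch sets exist for these edge cases; the ones above are the branches
this package commits to, stated here rather than in scattered code paths.

**iChao1** adds `a₃/(4a₄)·max(a₁ − a₂a₃/(2a₄), 0)`; when a₄ = 0 it is
replaced by 1 in that term, mirroring the `a₂+1` device, which keeps the
estimator finite and ≥ Chao1. Its variance is computed by the delta
method on the full frequency histogram: the gradient of the closed-form
estimator with respect to each frequency count (central differences on
the smooth expression) combined with the multinomial-style covariance
`cov(a_i, a_j) = a_i(δ_ij − a_j/N̂)`. No compact printed form of this
variance is reliable across the edge cases, so the package differentiates
the one implementation of the point estimate rather than transcribing a
second formula that could drift from it.

**Confidence intervals** for both use a log-transform of the excess
T = N̂ − N_DET: with `R = exp(z₀.₉₇₅·√ln(1 + var/T²))` the interval is
`[N_DET + T/R, N_DET + T·R]`. This respects the hard bound N̂ ≥ N_DET
and the right skew of the sampling distribution. T = 0 collapses the
interval to a point and is flagged.

## The Bayesian data-augmentation model

y is padded with zeros to fixed length L = ⌈factor·N_DET⌉ (default factor
50), converting the unknown-dimension problem into inference on a fixed
set of slots:

    z_j ~ Bernoulli(ψ)            slot j corresponds to a real parent
    y_j ~ Binomial(N_OBS, z_j·p)  each sampled offspring "detects" a
                                  present parent independently with
                                  probability p
    N_P = Σ_j z_j

with ψ, p ~ Beta(1, 1) by default (configurable). L acts as a uniform
prior ceiling on N_P: factors below ~2 truncate the posterior (the
package warns), while very large factors waste computation.

The model is fully conjugate, so sampling is exact Gibbs:
z_j = 1 whenever y_j ≥ 1; an undetected slot is occupied with probability
`q = ψ(1−p)^N_OBS / (ψ(1−p)^N_OBS + 1−ψ)`;
`p | z, y ~ Beta(α_p + Σy, β_p + N_OBS·Σz − Σy)`;
`ψ | z ~ Beta(α_ψ + Σz, β_ψ + L − Σz)`.
Because the undetected z_j are exchangeable and everything downstream
depends only on their sum, that sum is drawn directly as
Binomial(L − N_DET, q) — the identical Markov chain on (N_P, ψ, p) at
O(1) cost per sweep instead of O(L). Correctness is pinned three ways in
the test suite: a brute-force enumerated marginal posterior of N_P
(`exact_posterior`, total-variation agreement on small instances), a
well-specified-data calibration check, and a cross-check against the same
model declared in JAGS via rjags.

Defaults follow a 3-chain protocol: 3500 discarded sweeps per chain
(an adaptation phase is meaningless for exact conditionals, so the
1000-sweep adaptation and 2500-sweep burn-in of the original JAGS
protocol are pooled into burn-in), then 5000 sweeps thinned by 50
(100 retained per chain, 300 pooled). Point estimates are posterior
medians (reported unrounded, so pooled medians can be half-integer);
intervals are 95% highest-posterior-density (shortest window containing
⌈0.95·n⌉ sorted draws, first window on ties). Convergence is the classic
Gelman–Rubin potential scale reduction factor (no split chains, no rank
normalization), computed for N_P, ψ and p, with the flag requiring
max R̂ < 1.1 (threshold configurable; 1.05 is a common stricter choice).
Two degenerate R̂ cases are defined explicitly: chains that are constant
and identical (legitimate when the posterior is degenerate at N_DET)
give R̂ = 1; constant but disagreeing chains give R̂ = ∞.

## The cohort simulator

The simulator emulates a polygynandrous, semelparous breeding event with
salmonid-scale defaults: each female takes a zero-truncated Poisson(λ = 4)
number of distinct mates (capped at the number of males) and produces a
discrete-uniform 2500–6500 total of offspring. Three choices were
genuinely open and are fixed as follows:

* **Mate reconciliation** is female-driven; any male left unmated is then
  assigned one uniformly chosen female. Zero-truncation plus this repair
  guarantees every configured adult is a true parent, so the configured
  N_P is exactly the estimand.
* **Allocation** of a female's fecundity among her mates is multinomial
  with equal probabilities, after one guaranteed offspring per mate (so
  no mating is sterile). This preserves the per-female fecundity
  distribution exactly.
* **Sex ratios**: a total abundance is split by a male:female ratio with
  the integer remainder assigned to males.

Cohorts are stored as per-mating-pair offspring counts (a 500-parent
cohort of ~10⁶ offspring is ~10³ pairs), and offspring samples are drawn
without replacement via the multivariate hypergeometric distribution,
which is exactly uniform sampling from the pooled cohort.

**Pedigree-error injection** mimics sibship-reconstruction failure modes.
Type I (false positive): only offspring sharing no parent with any other
sampled offspring are eligible; each of their parent slots flips with the
given rate to a uniformly chosen different same-sex parent from the
original sample's pool (merging two parents). Type II (false negative):
only offspring with at least one sampled sibling are eligible; a flipped
slot becomes a brand-new unique same-sex parent (splitting one off).
Eligibility is evaluated once, before any flips, and the input sample is
never mutated, so several error rates can be applied to the same base
sample for comparability.

What the simulator does **not** emulate: genotypes, marker error
mechanisms, sibship-inference algorithms, overlapping generations,
offspring mortality between spawning and sampling, or spatial structure.
Passing benchmarks therefore demonstrate estimator behaviour under known
parentage with idealized random sampling, not end-to-end performance of a
genetic pedigree pipeline.

## Benchmark harness and metrics

Three experiment modes: a factorial grid over N_P × N_OBS, a uniform-draw
mode (N_P, N_OBS ~ integer-uniform, default [25, 500]) probing behaviour
as a function of the N_OBS:N_P ratio, and an error grid applying every
error rate to the same base sample per replicate. Metrics per cell: mean
and median bias ratio N̂/N_P, CV (100·SD/mean with sample SD, matching
the R `sd` convention), RMSE, and the fraction of 95% intervals
containing the truth. In uniform mode the truth varies per replicate, so
CV and RMSE are computed on the bias ratio around 1. Headline Bayesian
metrics are restricted to converged fits; raw result tables keep
everything, and failed replicates are counted, never silently dropped.
Replicates are seeded from a single master seed through `SeedSequence`
spawning, so serial and process-parallel runs produce identical tables.

Desk-scale problem sizes are the package defaults: 200–250 replicates for
the uniform-draw experiments and 100 per error-grid cell, with the
original study's 1000-replicate grids available by configuration.

## Known limitations

* Detection probability p is shared by all parents. Real (and simulated)
  parents differ in offspring share — males especially, through variable
  mate numbers — and this heterogeneity biases the posterior of N_P
  downward at moderate-to-deep sampling, since undetected low-share
  parents look implausible under a common p fitted to well-detected ones.
  The mid-range underestimation (~90% of truth) measured by the benchmark
  is exactly this effect, and the posterior intervals do not account for
  it: HPD coverage under the heterogeneous simulator falls well below
  nominal even though the sampler is exactly calibrated on
  model-generated data. A beta-binomial (per-parent p) extension would
  address this and is deliberately out of scope.
* The Chao-type intervals rely on asymptotic variances; with very sparse
  vectors (a₁ dominating) they can be extremely wide, and with no
  singletons they degenerate to a point.
* The Type II injector creates strictly unique new parents; it cannot
  represent partial family fragmentation, and both injectors treat the
  two parent slots of an offspring independently.
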