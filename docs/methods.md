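# Methods

## The models

The quantity of interest is β_age, the effect of a parent's age at a
child's birth on the number of crossovers that child inherited from that
parent. Counting crossovers requires families: with a single child per
parent the parent's baseline rate α and the residual cannot be separated,
so every model here is fitted to parents with at least two counted
meioses, and α_j is a parent-level random effect.

**Normal model (M1).** Y_{i,j,c} ~ N(β_age·age_{i,j,c} + α_{j,c}, τ²),
α_{j,c} ~ N(μ_c, σ²_c) per cohort c. Counts are treated as continuous.
β_age is additive: crossovers per year.

**Negative-binomial models (M2, M2\*).** Counts are overdispersed relative
to Poisson, so Y is negative binomial with shape a = m/(ω−1) and success
probability 1/ω, giving E(Y) = m = exp(β_age·age + α) and Var(Y) = ω·m
with overdispersion ω > 1 (ω → 1 recovers Poisson; the implementation
falls back to the Poisson pmf within 1e-8 of that boundary). The
exponential link keeps a > 0; β_age is multiplicative: the expected count
grows by a factor exp(β_age) per year. M2\* draws α_{j,c,f} from a
N(μ_{c,f}, σ²_{c,f}) specific to cohort × family configuration f, which
absorbs the configuration-dependent under-calling of crossovers in
partially informative meioses and lets those meioses enter the analysis.

**Per-cohort age effects (M1.2, M2.2, M2.2\*).** β_{age,c} ~
N(β_{age,global}, σ²_β), with β_{age,global} ~ N(0,1).

### Priors

- β_age ~ N(0, 1): previously reported effects span roughly −0.5 to +0.2
  crossovers/year, so a unit normal is weakly informative on either scale.
- μ_c ~ N(41, 100) for maternal counts (41 is the canonical female
  genome-wide crossover count); for fathers the prior mean is the
  empirical paternal mean. For the negative-binomial models the prior
  *mean* is log-transformed (log 41 ≈ 3.7) but the variance is kept at
  100. This is deliberate: transferring the variance to the log scale by
  the delta method (100/41² ≈ 0.06) makes the μ prior informative, and
  because the group means and the age effect are linked through
  E(log Y) ≈ μ + β_age·age, a tight μ prior measurably biases β_age. The
  package's recovery simulations showed a ~1.5-posterior-SD downward bias
  under the delta-method variance, which vanishes with the wide prior.
- σ²_c (and σ²_{c,f}) ~ InverseGamma(shape, scale), empirical Bayes: the
  shape starts at 3 (finite mean and variance) and the scale is solved so
  the central 95% prior interval covers the per-cohort empirical variances
  of parent mean counts (log parent means for the count models); if the
  empirical spread is too wide for shape 3, the shape is relaxed toward
  heavier tails until the interval can cover it.
- τ² ~ InverseGamma(3, scale) with prior mean equal to the empirical count
  variance across fully informative meioses (normal model only).
- ω⁻¹ ~ U(0, 1), constraining ω to (1, ∞).
- σ²_β ~ InverseGamma(3, scale) with prior mean 0.1² on the additive scale
  and (0.1/baseline)² on the log scale — the spread of previously reported
  effects.

Robustness reruns refit M2\* with one prior at a time replaced by an
uninformative alternative: β_age ~ N(0, 100²); μ with variance 10⁴; a flat
(improper) prior on σ_{c,f}, the standard recommendation for group-level
scale parameters; and a half-Cauchy(25) prior on ω−1 in place of the
uniform on ω⁻¹. The original forms of these relaxations are not fully
specified in the source material; these are the package's choices.

## Sampling

Models are fitted with an in-package No-U-Turn Sampler (slice variant,
dual-averaging step size targeting 0.8 acceptance, diagonal mass matrix
estimated in doubling warmup windows) over hand-derived analytic
gradients; the gradients are checked against finite differences in the
test suite, and the sampler against exact Gaussian targets and a
conjugate normal-normal posterior.

Unconstrained parameterization: parent effects are non-centered
(α = μ_g + σ_g·z_j, z_j ~ N(0,1)); variances are sampled on the log
scale, ω⁻¹ through a logit, with Jacobian corrections. Internally ages
are centered and the group means shifted to μ̃_g = μ_g + β_age·(mean age)
— an exact linear reparameterization that removes the extreme β–μ
posterior correlation (≈ −0.98 with raw ages ~28 ± 5) and cuts sampling
cost roughly in half; all reported parameters are mapped back to the
raw-age scale, so the fitted model is the one written above, with ages
as-is (an explicit centering option is unnecessary for the user because
the sampler already benefits internally).

Default protocol: 4 chains × 10,000 draws, first half discarded as
burn-in; convergence by split R-hat (between- vs within-chain variance on
half-chains) with threshold 1.05; if exceeded, every chain is extended
(default: by the original number of draws, step size and mass frozen) up
to a cap, after which fitting fails loudly with the R-hat report.
Optional thinning is available but off by default. Variance-type
parameters and the age effect can be pinned (`fixed={"tau2": ..., ...}`)
instead of sampled, which is how the conjugate and grid-quadrature oracle
tests condition on known components — point-mass priors would make the
Hamiltonian geometry needlessly hostile. Degenerate inputs:
an empty table yields the prior (used by the prior-predictive test);
parents with a single meiosis are dropped with a warning; a non-finite
initial log density raises immediately.

## Synthetic data

The generator emulates a nine-cohort SNP-chip pedigree study: three large
twin-registry-like cohorts and six smaller isolate-like cohorts, families
in six configurations (1/2 = ≥3 children with one/both parents genotyped,
3/4 = two children with one/both parents, 5/6 = two children plus the
target parent's parents; 2 and 6 are fully informative), truncated-normal
maternal ages (means 27.5–29.5 y, sd ≈ 5, range ~16–45) with inter-birth
intervals of at least one year, and mother baselines giving observed
maternal means near 38–41 crossovers. Defaults: negative-binomial family
with ω = 1.3 and σ² = 0.01 on the log scale (normal family: τ² = 22,
σ² = 6), β_age = 0.002/year multiplicative or 0.082 crossovers/year
additive — the scale of the small positive maternal effect. Partially
informative configurations under-call crossovers via binomial thinning of
the true counts (detection 0.75–0.9; exactly 1 for configurations 2 and
6). One pseudo-random stream per cohort, split per family, so adding a
cohort leaves others' data unchanged byte for byte.

Call-level tables expand each observed crossover into one call with
P > 0.5 and can inject, per meiosis, a tight spurious call pair (flanking
SNP separation below the cohort's X) and low-confidence calls (P ≤ 0.5),
with every injection recorded so the filters can be scored against truth.
Placement is arranged so real calls are never within X of each other —
the generator tests filter bookkeeping, not hotspot biology. What passing
tests on these data do **not** show: robustness to genotyping-error
processes correlated with age, non-linear age effects, real SNP-density
variation along chromosomes, or family-size/recombination correlations —
none of which the generator produces.

## Model checking

Posterior predictive checks simulate replicate datasets of the observed
size and design from either the single highest-log-posterior draw or
distinct joint-posterior draws, re-drawing parent effects from their group
distribution each time. Compared statistics: median, minimum, and sample
skewness (the third standardized moment, as the concrete measure of the
count distribution's asymmetry), plus per-quantile ECDF envelopes. Normal
model replicates are left continuous and unbounded, which is exactly why
the replicate minimum falls below the observed minimum on floored,
right-skewed counts — the diagnostic that favours the count model.

Coverage (γ) and power (π) of the credible intervals are estimated by
simulate-and-refit: either resampling full parameter sets from ten
equal-count bins of the β_age posterior draws (each bin ≥ 1,000 draws) or
drawing hyperparameters from the prior (simulation-based calibration; if
the model is implemented correctly, the level-L interval covers the
simulating β_age in a fraction L of replicates). Refits default to a
reduced protocol (2 chains × 2,000 draws) with the R-hat rule intact; a
full-protocol flag exists. Failed refits are dropped from the rates and
reported.

## Problem sizes and numerical choices

The bundled tests and the acceptance script run desk-scale versions of
every procedure: recovery on 5 cohorts × 4 configurations × ~1,500 (tests)
or ~1,000 (script) mothers at 4 chains × 2,000 draws; calibration on a
2-cohort, 26-parent normal-model template with 100 (tests) or 60 (script)
replicates at 2 chains × 1,000 draws; PPC with 400 replicates. These
sizes are the package's chosen study conditions for its own validation;
the full 4 × 10,000-draw protocol is the library default for real
analyses. Numerical guards: the exponential link is clipped at |η| = 30;
ω−1 is floored at 1e-10; variance estimates from the mixed model are
truncated at zero at the REML boundary, where the fixed effects are
recomputed by OLS (their exact zero-variance limit); the LMM slope t-test
uses df = n_meioses − n_parents − 1 by convention (configurable), and the
ML-vs-REML choice is fixed at REML, standard for variance components.

## Known limitations

- The NUTS implementation is single-threaded and uses a diagonal mass
  matrix; strongly correlated posteriors (e.g. per-cohort age effects with
  few cohorts) sample more slowly than they would under a dense metric.
- The negative-binomial hierarchy assumes a single global ω; binomial
  thinning of counts in partially informative configurations implies
  slightly configuration-dependent effective overdispersion, which M2\*
  absorbs only through its group means and variances.
- Empirical-Bayes priors reuse the analysis data; with very few cohorts
  the σ² hyperprior interval-covering construction is fragile and falls
  back with a warning.
- Monozygotic-twin deduplication requires an externally supplied pair
  list; the package does not infer zygosity.
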