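# Methods

## Model

The midpoint-primary-process (MPP) IRTree model represents a response on a
5-point Likert item as up to three sequential binary decisions. Person *v*
facing item *i* first decides whether to use the midpoint (node M); if not,
whether to agree or disagree (node A); and finally whether to respond in the
extreme (node E). Each node *k* is a two-parameter logistic model

    P(yes at node k) = σ(α_ki θ_vk + d_ki),

with item discrimination α_ki > 0, intercept d_ki on the log-odds scale, and
a node-specific latent trait θ_vk. The five category probabilities are the
branch products

    P(1) = (1−p_M)(1−p_A) p_E        P(2) = (1−p_M)(1−p_A)(1−p_E)
    P(3) = p_M
    P(4) = (1−p_M) p_A (1−p_E)       P(5) = (1−p_M) p_A p_E

which sum to one by construction. A complete Likert matrix decomposes into
three binary pseudo-items per item: category 3 maps to (M, A, E) = (1, –, –)
and the directed categories to M = 0 with the appropriate (A, E) pair. The
agreement and extreme codes are *structurally missing* exactly when M = 1,
and the Bernoulli likelihood of the observed codes equals the categorical
likelihood of the original responses (a tested invariant). This missingness
is the mechanism of interest: it thins the effective sample for every node
past the first.

### Parameterization: intercept vs difficulty

Two common 2PL conventions exist — the slope/difficulty form α(θ − b) and
the slope/intercept form αθ + d. This package uses the **intercept form
throughout, with d = α·b derived from a difficulty b drawn on the trait
scale**. The generator draws α and b independently per item and node, and
the sampler places its difficulty prior on b with d derived, mirroring the
generator. This convention is recorded prominently because recovery metrics
on the d scale and the b scale differ; `detail_records(..., scale="b")`
scores on the b scale instead.

## Generative study conditions

The generator's defaults are the study conditions and are not meant to be
tuned:

| quantity | midpoint | agreement | extreme |
|---|---|---|---|
| α ~ log-normal(location, scale) | (−0.5, 0.5) | (0.3, 0.2) | (0.5, 0.5) |
| b ~ normal(mean, sd) | (−1, 0.5) | (0, 1) | (1, 0.5) |

"Location/scale" are the mean and sd of log α (the `rlnorm` convention), so
the implied mean discriminations are roughly 0.69, 1.38, and 1.87. Traits
are trivariate standard normal with r(M,A) = −0.10, r(A,E) = 0.10,
r(M,E) = −0.50. The design grid crosses N ∈ {500, 1000, 1500, 5000} with
J ∈ {10, 15, 20} (12 cells); the full-scale study uses 2,000 replicates per
cell, and a `scale` factor shrinks that proportionally for desk-scale runs.

Two genuinely open generator choices were resolved as follows:

- **Extreme-node discriminations** are an independent draw from
  log-normal(0.5, 0.5) — the stated distribution — not entrywise reciprocals
  of the midpoint draws, which "inverse" might alternatively suggest. The
  stated distribution is the only unambiguous specification.
- **Item-parameter refresh**: item parameters are drawn once per test-length
  condition and held fixed across replicates and sample sizes, so RMSE per
  item across replicates is well defined against a single truth. A
  per-replicate redraw mode exists behind `StudyConfig.redraw_items`.

What the generator deliberately does *not* emulate: real scales have content
factors beyond the three response-style traits, item-specific
multidimensionality, person misfit, and non-normal trait distributions.
Passing recovery tests therefore demonstrate the estimator's behavior *when
the MPP model is true*, which is the study's question — not robustness to
model misspecification.

## Estimation

The three-node model is fit by an adaptive random-walk Metropolis-within-
Gibbs sampler written for this package (self-contained, deterministic under
seed, testable against brute-force integration):

- **Blocks.** One joint 3-vector proposal per person for (θ_M, θ_A, θ_E);
  one joint proposal per node × item for (log α, b). Sampling log α enforces
  positivity and turns the log-normal prior into a normal one in sampling
  coordinates; no further identification constraints are needed.
- **Priors.** Centered on the generating distributions: log α ~
  N(loc_k, scale_k), b ~ N(mean_k, sd_k) with the table above; traits are
  independent standard normal per node. The trait correlation matrix is
  *not* estimated; `PriorConfig.fixed_R` optionally fixes it at a known
  value, coupling the trait update through the corresponding precision
  matrix.
- **Adaptation.** Per-block proposal scales follow a Robbins–Monro recursion
  toward 30% acceptance (the middle of the 20–50% band that is efficient for
  low-dimensional random-walk blocks) during burn-in only; scales are frozen
  afterward so the retained chain is a valid Markov chain.
- **Numerics.** Per-cell Bernoulli log-probabilities use y·z − log(1 + eᶻ)
  (log-sigmoid form), which is overflow-safe for |z| far beyond 35.
  Structurally missing cells contribute exactly zero. The per-cell
  log-likelihood matrices are cached and updated only for accepted blocks.
- **Defaults.** 3 chains × 4,000 iterations with 2,000 burn-in and an R-hat
  flag threshold of 1.1, in line with common practice for Bayesian 2PL fits
  of this size. Non-convergence flags a fit; it is never discarded, and
  flagged fits are included in recovery summaries (a strict caller can
  filter on the flag).
- **Diagnostics.** Split-chain Gelman–Rubin R-hat (defined as exactly 1 for
  zero-variance sequences) and an effective sample size from chain-averaged
  autocorrelations with Geyer's initial-positive-sequence truncation; both
  are cross-checked against an independent implementation in the tests.
- **Degenerate inputs.** Zero persons yields the prior as posterior (a
  tested property). A pseudo-item with fewer than two observed values is
  flagged and effectively returns its prior. Posterior quantiles use
  numpy's linear-interpolation percentile rule.

## Evaluation and design effects

The unit of analysis is the **item**: for each (node, N, J, item) the
posterior means across replicates are scored against the generating value,
giving RMSE = √mean((est − truth)²) and bias = mean(est − truth). Cell
values are unweighted means over the cell's items; the cell's mean estimate
carries an SE (sd over items / √J) and a normal 95% CI. With the full grid
this yields 540 item-level observations in 36 cells, so the factorial ANOVA
residual has 504 degrees of freedom — the item-level unit of analysis is
chosen precisely because it reproduces that residual df.

The ANOVA is a between-subjects factorial of item-level RMSE on sample size
× test length × node with **Type II sums of squares** (robust to the
imbalance in item counts across test lengths; Type I/II coincide on balanced
sub-designs). Effect sizes are partial η² = SS_eff / (SS_eff + SS_resid);
sums of squares below a relative floor of 1e−10 of the response's total
magnitude are clamped to zero so a constant response yields exactly zero
effects. Pairwise node contrasts use the pooled residual mean square and
residual df, signed hierarchy-first so a negative t means the earlier node
recovers better. Raw p-values are the default; Bonferroni and Holm
adjustments are available and reported alongside, since no single adjustment
convention is canonical here.

## Orchestration and reproducibility

Seeds derive from a single base seed via `numpy.random.SeedSequence`
spawning keyed on (condition index, replicate index) — never on execution
order — so any replicate is reproducible in isolation and results are
identical for any worker count. Per-condition estimates are checkpointed as
CSV (read back with exact float round-trip) and a JSON manifest records
seeds and failures; deleting any replicate's rows and resuming regenerates
only that replicate. Failed replicates are excluded with counts reported,
and a study aborts only when more than 10% of a cell's replicates fail.

## Problem sizes used in the shipped checks

The full-scale study (12 cells × 2,000 replicates × multi-thousand-iteration
chains) is cluster-scale. The package's own checks run at desk scale, chosen
as the smallest sizes at which the properties under test are stable:

- sampler-vs-grid-oracle agreement on a 1-item/10-person toy with traits
  held fixed (tolerance 0.05 on posterior means);
- midpoint recovery at the largest cell (N = 5,000, J = 20): truth-estimate
  correlation > 0.9 for midpoint α and d;
- the error-inflation gradient midpoint < agreement < extreme over 20
  replicates at N = 500, J = 10;
- `scripts/acceptance.py`: the full 12-cell grid at 4 replicates per cell
  with 2-chain × 800-iteration fits, plus a 100,000-person check of the
  trait-correlation structure.

## Known limitations

- Quantitative RMSE/bias values for the agreement and extreme nodes depend
  on the estimation conventions (prior spreads, d vs b scale, sampler
  parameterization); under the faithful-priors configuration used here the
  later nodes' absolute errors are smaller than a JAGS-style fit with other
  conventions would give, while the qualitative ordering of the nodes is
  stable. The node *ordering*, not the later nodes' absolute error, is the
  robust quantity.
- The trait correlation matrix is fixed, not estimated; model comparison
  (GRM/GPCM alternatives), even-point agreement-primary trees, and scales
  other than 5 points are out of scope.
- The sampler is a random-walk scheme: adequate for this model size, but
  effective sample sizes per iteration are modest compared to gradient-based
  samplers; R-hat flags should be heeded for small-N, short-chain runs.
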