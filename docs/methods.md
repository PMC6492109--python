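# Methods

## Model and assumptions

`hetnma` fits the contrast-based random-effects NMA model for binary outcomes:
arm counts are binomial, each study has an unrelated fixed baseline log-odds
μ_j with a vague N(0, 10⁴) prior, and the study's vector of contrasts against
its baseline arm is multivariate normal around the consistency means
d_0k − d_0b. Consistency (agreement of direct and indirect evidence) is
assumed; inconsistency models, meta-regression, exchangeable-variance models
and ranking probabilities are out of scope. The baseline arm of a study is the
lowest treatment index present — the likelihood only requires the contrasts to
be taken against *some* arm, and this convention is deterministic.

All heterogeneity modelling happens through the p×p covariance **Σ** of the
contrasts with the overall reference treatment. Positive semidefiniteness of
**Σ** is the operational form of second-order consistency: it is what makes
τ_AC ≤ τ_AB + τ_BC hold for every triple. Structures 1, 3 and 4 are PSD by
construction; structure 2 (proportional variances) is not automatically PSD,
so the constructor checks eigenvalues (tolerance −1e-8 relative to the largest
eigenvalue, loose enough not to reject boundary cases from rounding) and the
sampler rejects proposals that leave the PSD cone.

## Priors and moment matching

The bundled catalogs hold log-normal predictive distributions for τ²_kl by
outcome type, Beta priors for the spherical-angle cosines by network size
(4–10 treatments; a 3-treatment network has a single angle and needs a
user-supplied Beta prior), and comparison-type-specific log-normal priors for
two worked contexts (smoking-cessation counselling; prostate-cancer all-cause
mortality), extensible via a user catalog file. Catalog values are stored as
the exact printed decimals and never re-rounded.

**Arm-level matching (structure 3).** With τ²_k, τ²_l iid LN(m, s²)
independent of ρ_kl (mean m_ρ = 0.5, variance s²_ρ = 0.07, approximating a
U(0,1) correlation conditional on PSD), the implied prior for
τ²_kl = τ²_k + τ²_l − 2ρτ_kτ_l has closed-form mean and variance (derived from
E[X^q] = e^{qm+q²s²/2}; stated in `priors.py`). `match_arm_prior` solves the
two moment equations for (m, s) in unconstrained (m, log s) coordinates from
the start (m_D − 0.5, log s_D), with up to 5 jittered restarts and relative
residual tolerance 1e-10. The published variance expression for this
derivation is typographically ambiguous, so the implementation relies on the
re-derived form, which the tests verify against a seeded Monte-Carlo oracle
drawing (τ²_k, τ²_l, ρ) directly. One consequence worth
knowing: the exact solve for target LN(−4.28, 1.61²) gives (−4.836, 1.696),
which rounds to (−4.84, 1.70); the catalogued 2-decimal entry for that row is
(−4.83, 1.69), and the whole-table regression test therefore asserts agreement
within one unit in the second decimal.

**Scaled-Wishart matching (structure 4).** The Wishart convention is the
rate/BUGS one (density ∝ |M|^{(t−p−1)/2}e^{−tr(SM)/2}), pinned by the diagonal
marginal Σ_kk ~ λ·IG((t−p+1)/2, S_kk/2). Degrees of freedom t = p + 1 are the
smallest for which the log-variance spread can be matched (the requirement is
s²_D > ψ₁((t−p+1)/2) = π²/6 ≈ 1.645 at t = p+1, satisfied by every catalogued
s_D ∈ [1.60, 1.62]); larger t would increase the prior correlation between
heterogeneity variances and hence the borrowing across comparisons. S_kl =
S_kk/2 makes the implied priors for reference and non-reference contrast
variances identical (verified distributionally in the acceptance tests). Note
the matching equates the *mean and variance of log Σ_kk* with (m_D, s²_D); the
implied distribution is the convolution of a normal with a log-inverse-gamma
and is not itself log-normal, so its median sits slightly below e^{m_D}.

**Spherical correlation matrices.** R = LᵀL with unit-norm upper-triangular
columns; column j consumes the cosines of pairs (1,j)...(j−1,j) in
lexicographic order (the 3×3 case reduces to the familiar closed forms; the
ordering for larger networks is a convention of this package, chosen because
no canonical ordering exists). Cosines live in (0,1): first-row correlations
are then positive (arm effects are expected to be positively correlated),
while deeper correlations can take any achievable value. A side effect of the
ordering is that the implied prior is *not* perfectly exchangeable across
pairs: the prior correlation of log τ²_kl for comparison pairs sharing the
first treatment is ≈0.37 versus ≈0.39 for other shared-treatment pairs, and
single-pair implied medians in an 8-treatment vague network range 1.18–1.24.
Reported characterizations therefore average correlations over all
shared-treatment (or disjoint) comparison pairs and pool quantiles over all
comparisons; the pooled summaries reproduce published figures (shared/disjoint
correlations 0.39/0 and 0.71/0.64; pooled vague median 1.21 with 95% range
0.25–2.08).

## Sampler

Component-wise adaptive random-walk Metropolis within Gibbs, all chains
advanced together as vectorized numpy operations:

* μ_j and the per-study random-effect vectors: Metropolis with per-study,
  per-chain step sizes adapted toward 0.44 acceptance in windows of 50
  iterations, during burn-in only (so the post-burn-in chain is Markovian).
* basic parameters **d**: exact Gibbs — given the random effects, their full
  conditional is Gaussian under every structure.
* heterogeneity block: component-wise Metropolis on unconstrained scales
  (log variances, logit of bounded SDs and angle cosines, Cholesky factor with
  log diagonal for the Wishart matrix, log λ), with transform Jacobians in the
  prior density.

Defaults are 4 chains; the draw count contract is
(iterations − burn_in)/thin per chain. Convergence is assessed by classic
split R-hat on the basic parameters (threshold 1.01, reported via a warning,
overridable); `summary.convergence` reports split R-hat and an
initial-positive-sequence effective sample size for every monitored quantity,
and is cross-checked in the tests against an independent implementation.
Multi-arm trials contribute through their joint trial-level contrast
covariance (equivalently, the sequential conditional decomposition exposed by
`conditional_factors`, whose product-of-conditionals identity is unit-tested
against the joint density). Initial values are empirical logits with seeded
overdispersion; all randomness flows from a single seeded generator, so runs
are bit-reproducible given the seed.

During development the sampler was validated against an independent
general-purpose Gibbs sampler on the bundled prostate network and on simulated
data; posterior medians and interval endpoints agreed to Monte-Carlo error.
The test suite instead validates it self-containedly: against dense-grid
numerical integration of a 2-treatment posterior, by parameter recovery on
simulated 40-study networks, and by prior-only runs reproducing each
structure's forward-simulated heterogeneity marginals.

## Synthetic data

`simulate_network` draws from exactly the fitted model: μ_j ~ N(logit(0.3),
0.5²) by default (the model treats baselines as unrelated fixed effects, so
any dispersed choice is valid; 30% is a realistic event probability and the
value is overridable), trial contrast vectors from the restriction of
N(d, Σ), and binomial counts. It emulates a connected network with arbitrary
arm compositions and any PSD Σ. It does *not* emulate features of real trial
collections such as arm-size imbalance, selective reporting, baseline-risk /
effect correlation, or non-exchangeable study effects — so passing recovery
tests demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to their violation.

## Problem sizes and numerical choices

* Prior characterizations use 10⁶ forward draws (Monte-Carlo SE of the
  reported correlations ≈ 0.001).
* The acceptance script's prostate fits use 4 chains × 60 000 iterations
  (15 000 burn-in); the test suite uses 4 × 30 000. Both were checked against
  4 × 120 000 reference runs; medians agree to two decimals.
* Quantiles are type-7 (linear interpolation), the numpy default, because
  published 2-decimal interval endpoints are sensitive to the quantile
  definition.
* Degenerate inputs: r = 0 and r = n arms are accepted without continuity
  corrections (the Bayesian binomial likelihood needs none); zero conditional
  variances in singular trial covariances are handled by pseudo-inverse with a
  point-mass conditional; a disconnected network is refused by the sampler but
  merely flagged by `validate_network`.

## Known limitations

* Arm-level binary data only; no contrast-level (log-OR + SE) input and no
  continuous outcomes.
* The proportional-variances structure can leave the PSD cone for some
  networks/prior combinations; the package detects and refuses rather than
  repairs (use structures 3 or 4 there).
* Component-wise heterogeneity updates make approach-3 fits on large networks
  (many angles) slow relative to approaches 1, 2 and 4.
* The smoking-cessation example ships as a design skeleton only (treatments,
  classes, per-comparison trial counts); its outcome data are not bundled, so
  analyses of that network require the user to supply the data file.
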