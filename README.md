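# hetnma

Bayesian random-effects network meta-analysis (NMA) of binary outcomes, with
externally informed prior distributions for the between-study heterogeneity
variances of every treatment comparison.

## Who this is for

In a network meta-analysis, each pairwise comparison's heterogeneity variance
τ²_kl is typically informed by only one or two trials, so heterogeneity — and
through it the credible intervals of every treatment effect — is very
imprecisely estimated. Evidence-based predictive distributions for τ²,
estimated from large collections of published meta-analyses, can serve as
informative priors. `hetnma` implements four ways of placing such priors on
the *multiple* heterogeneity variances of a network while keeping the contrast
covariance matrix **Σ** positive semidefinite, which guarantees second-order
consistency (the heterogeneity SDs of any treatment triple obey the triangle
inequality).

## Model

For arm k of study j with baseline treatment b:

    r_jk ~ Binomial(π_jk, n_jk),      logit(π_jk) = μ_j + δ_jbk·[k > b],

with the study's contrast vector drawn from the restriction of N(**d**, **Σ**)
to its arms, vague N(0, 10⁴) priors on the μ_j and the basic parameters
d_01..d_0p, and consistency (d_kl = d_0l − d_0k) assumed throughout. The four
heterogeneity structures:

1. **Common variance** — Σ = τ²P (unit diagonal, 0.5 off-diagonal); one
   log-normal prior (or τ ~ U(0,2)) for τ².
2. **Proportional variances** — τ²_kl = τ² e^{m_kl} with offsets m_kl taken
   from comparison-type-specific catalogued priors and a study-count-weighted
   common log-scale SD; PSD checked at construction.
3. **Arm-based** — τ²_kl = τ²_k + τ²_l − 2ρ_kl τ_k τ_l with iid log-normal
   priors on the arm variances (moment-matched so the *implied* τ²_kl prior
   has the mean and variance of a catalogued target) and a
   spherical-angle correlation matrix with Beta priors on the cosines.
4. **Scaled inverse-Wishart** — Σ = λM⁻¹, M ~ Wishart(S, t = p+1), S_kk = 1,
   S_kl = ½, log λ normal with closed-form matching
   m_λ = m_D − log(S_kk/2) + ψ((t−p+1)/2), s²_λ = s²_D − ψ₁((t−p+1)/2).

Posterior sampling is a native adaptive random-walk Metropolis-within-Gibbs
sampler (exact Gibbs updates for the basic parameters), vectorized across
chains; multi-arm trials enter through the sequential conditional
decomposition of their contrast vector.

## Worked example

The bundled fixture is a 17-trial network of eight treatments for localised
prostate cancer (all-cause mortality): observational management (A, the
reference), prostatectomy (B), five radiotherapy regimes (C–G), and
cryotherapy (H).

```python
import numpy as np
import hetnma as h

ds = h.prostate_fixture()
print(h.validate_network(ds))
# 17 studies, 8 treatments, connected=True
#   A vs B: 3 studies
#   A vs E: 1 studies
#   ...

# equal heterogeneity variances, vague tau ~ U(0, 2)
cfg = h.MCMCConfig(chains=4, iterations=120_000, burn_in=20_000, seed=1)
fit = h.sample_posterior(ds, h.CommonVariance(), cfg)
tau = fit.het_natural()["tau"]
dab = fit.contrast_samples(0, 1)
print(f"tau median {np.median(tau):.2f} "
      f"({np.quantile(tau, 0.025):.3f}, {np.quantile(tau, 0.975):.2f})")
print(f"d_AB median {np.median(dab):.2f}")
```

prints

```
tau median 0.09 (0.004, 0.35)
d_AB median -0.23
```

i.e. low between-study heterogeneity (SD of the log odds ratio about 0.09) and
no clear mortality difference between observational management and
prostatectomy. Refitting with the informative all-cause-mortality prior
`h.CommonVariance(prior=h.LogNormalPrior(-4.28, 1.61))` narrows the τ interval
(median 0.08) while barely moving the treatment effects.

Matching an arm-level prior so the implied comparison-level prior hits a
catalogued target:

```python
>>> h.match_arm_prior(h.LogNormalPrior(-4.28, 1.61))
LogNormalPrior(m=-4.836..., s=1.696...)
```

The same operations are available from the shell via the `nma` command
(`nma fit`, `nma prior-mc`, `nma check-psd`, `nma catalog`, ...).

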