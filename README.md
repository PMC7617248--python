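# nmabridge

Bayesian network meta-analysis (NMA) that **borrows strength across patient
subgroups**: results from a *dense* treatment network (a subgroup with many
trials and direct comparisons) are extrapolated into informative priors for
a *sparse* network (a subgroup, such as children and adolescents, with one
or two trials per comparison), where standard NMA yields wide, unstable
credible intervals.

## The model

Outcomes are continuous (e.g., symptom change scores) analyzed on the
standardized mean difference (SMD) scale. For study *i*, arm *k* with
treatment *t_k*, observed mean *y_ik*, arm SD *sd_ik* and size *n_ik*:

```
y_ik     ~ N(theta_ik, sd_ik^2 / n_ik)
delta_i,1k = (theta_ik - theta_i1) / sd_i^pooled
delta_i  ~ N_{K_i-1}(mu_vec, Sigma),   Sigma = tau^2 on the diagonal,
                                        tau^2/2 off it (multi-arm trials)
```

Only the *basic parameters* `mu_1j` (each treatment versus a common
reference) are sampled, so consistency `mu_jl = mu_1l - mu_1j` holds by
construction. Default priors: `mu_1j ~ N(0, 10000)` (variance) and
`tau ~ HN(1)`.

**Stage 1 (extrapolation).** The dense subgroup P2 is fitted with two
additions: a per-comparison *location shift* `beta_1j = mu_1j^P2 - mu_1j^P1`
with an informative prior, and a per-study *scale weight* `w_i in (0, 1]`
dividing the likelihood variance (`y_ik ~ N(theta_ik, sd_ik^2/(n_ik w_i))`)
— a power-prior-style downweight with, e.g., a `Beta(3, 3)` prior for
moderate downweighting. The extrapolated effects `mu* = mu^P2 - beta` plus
the source heterogeneity give predictive priors
`N(mean(mu*), var(mu*) + E[tau_P2^2])` for the target subgroup.

**beta priors** come either from the data (joint pairwise meta-analyses of
each bridge comparison in both subgroups with shared heterogeneity,
`d_1j = u_1j^P2 - u_1j^P1`) or from expert opinion (elicited change scores
pooled by a confidence-weighted random-effects model on the standardized
scale).

**Stage 2.** A standard NMA of the sparse subgroup in which the basic
parameters carry the stage-1 predictive priors.

Inference outputs include league tables, SUCRA rankings and node-splitting
inconsistency checks with Bayesian p-values `2*min{P, 1-P}`.

Sampling uses a collapsed Gibbs scheme: study-level random effects are
integrated out analytically, location parameters get exact conjugate
multivariate-normal draws, and `tau`/`w_i` are updated by slice sampling —
no tuning, fast mixing, exact for this model class.

## Worked example

```python
from nmabridge import (
    MCMCSettings, ModelSpec, ScalePriorSpec, ScenarioConfig,
    assign_scale_priors, data_based_beta_priors, fit_informed_nma,
    fit_nma, fit_stage1, generate_scenario, sucra,
)

cfg = ScenarioConfig(seed=77)          # 4 treatments; sparse: 1 study/edge
sparse, dense, truth = generate_scenario(cfg)
mcmc = MCMCSettings(iterations=4000, burnin=1000, seed=1)
spec = ModelSpec(reference="Placebo")

t_c = ["Placebo", "DrugA", "DrugB", "DrugC"]
beta = data_based_beta_priors(sparse, dense, t_c, "Placebo", mcmc)
w = assign_scale_priors(dense, ScalePriorSpec(scheme="none"))
s1 = fit_stage1(dense, beta, w, spec, mcmc, t_c=t_c)
informed = fit_informed_nma(sparse, s1.predictive, spec, mcmc)
standard = fit_nma(sparse, spec, mcmc)
print(standard.summary().round(2)[["mean", "q2.5", "q97.5"]])
print(informed.summary().round(2)[["mean", "q2.5", "q97.5"]])
```

prints

```
           mean  q2.5  q97.5
parameter
mu[DrugA]  0.52 -1.74   2.70
mu[DrugB]  0.76 -1.35   2.94
mu[DrugC]  0.50 -1.70   2.71
tau        0.79  0.03   2.28
           mean  q2.5  q97.5
parameter
mu[DrugA]  0.52 -0.18   1.21
mu[DrugB]  0.81  0.21   1.49
mu[DrugC]  0.44 -0.29   1.11
tau        0.36  0.01   1.22
```

The first block is the standard NMA of the sparse network alone: with a
single study per comparison, heterogeneity is essentially unidentified and
the credible intervals span several SMD units. The second block is the
informed fit: every interval narrows to roughly a third of its width while
the point estimates remain compatible with the generating values
(0.2, 0.4, 0.6 plus single-study sampling noise) — the priors extrapolated
from the dense subgroup add precision without dominating the sparse data.

The same pipeline is available from the shell:

```bash
nmabridge simulate --seed 77 --out scen/
nmabridge fit --model informed --sparse scen/sparse.csv --dense scen/dense.csv \
    --reference Placebo --beta-source data --dw none --out run/
nmabridge sucra --data scen/sparse.csv --reference Placebo \
    --direction smaller_better --out sucra.csv
```

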