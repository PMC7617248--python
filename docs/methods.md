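# Methods

This note documents the statistical models, the numerical scheme, the
synthetic-data generator and the design choices behind `nmabridge`.

## Hierarchical NMA on the SMD scale

The core model is an arm-based-likelihood, contrast-based-parameter
hierarchical NMA for continuous outcomes. Each observed arm mean is normal
around a latent arm mean with variance `sd^2/n` (the squared standard
error); the latent standardized contrasts of every non-baseline arm versus
the study baseline follow a multivariate normal with mean given by the
basic parameters and covariance `Sigma = tau^2 * S`, where `S` has 1 on
the diagonal and 1/2 off it. The `tau^2/2` covariance is exactly what a
common-heterogeneity random-effects model induces between contrasts
sharing a baseline arm, and `S` is positive definite for any number of
arms. Because only basic parameters (treatment versus the network
reference) are sampled, consistency holds for every posterior draw by
construction.

The pooled within-study SD is the standard `(n_k - 1)`-weighted pooled
sample SD with denominator `sum(n_k) - K`. It is treated as a known
plug-in constant, not a latent quantity — standard practice for SMD
likelihood weighting, and no prior for it is part of the model. No
small-sample (Hedges) correction is applied by default; an option exists.

A configuration switch `likelihood_sd` controls whether the arm-level
likelihood variance is `sd^2/n` (default, `"se"`) or the literal arm
variance `sd^2` (`"sd"`). The default is the only reading under which
sample size influences a study's weight, which any meta-analytic
likelihood must allow.

Default priors: `N(0, 10000)` on every basic parameter (10000 is the
*variance*, i.e. precision 1e-4 in BUGS convention) and half-normal
`HN(1)` on `tau`. Posterior summaries are means with equal-tailed 95%
intervals. Convergence is checked with the Gelman–Rubin diagnostic on the
basic parameters, shift parameters and heterogeneity SDs; `rhat < 1.1`
for all monitored parameters counts as converged.

## Sampling: collapsed Gibbs

Given `(tau, w)` the model is linear-Gaussian, so the study-level random
effects and latent arm means are integrated out analytically: each study
contributes a Gaussian block `x_i ~ N(X_i phi, tau^2 S_i + C_i / w_i)`
on observed standardized contrasts, where `C_i` is the (correlated)
sampling covariance of the contrasts and `phi` collects all location
parameters (basic effects, shifts, split-node direct effects, expert-pool
means). The sampler alternates

1. an exact multivariate-normal draw of `phi` from its full conditional
   (conjugate; one Cholesky factorization per iteration),
2. a univariate slice-sampling update of `tau` (stepping-out + shrinkage,
   no tuning parameters),
3. a univariate slice update of each stochastic study weight `w_i` on its
   prior support.

Because step 1 is a full conditional draw over the entire location vector,
autocorrelation is low and short chains suffice; the unit-test suite runs
2 chains of 1,500 iterations and the heavier checks 2 x 4,000 with 1,000
burn-in, at which Monte-Carlo standard errors are an order of magnitude
below every tolerance tested. Chains are initialized overdispersed
(prior-centered draws with spread capped at SD 2, `tau` from a half-normal)
with chain seed = `seed + chain`. Posterior draws of the latent study
effects are not stored: the marginal posterior over `(mu, beta, tau, w)`
is identical to that of the full arm-level parameterization, and no
inference output needs the latents.

Degenerate inputs: a single-contrast slice whose likelihood evaluations
all fall below the slice level (possible only with pathological fixtures)
keeps the current value; draws exactly at zero in the node-split
probability count one half each.

## Stage 1: location shift and scale weights

The dense-network fit adds, for every bridge comparison (treatments
common to both subgroups), a shift parameter `beta_1j` = dense-minus-
sparse difference of summary effects, with a normal prior constructed
from data or expert opinion, and optionally per-study weights `w_i` with
Beta or uniform priors on (0, 1] that divide the likelihood variance —
the power-prior interpretation: a study's likelihood raised to the power
`w_i`. Weights are shared across arms within a study. Priors allowing
`w > 1` are deliberately not supported (they would amplify external
evidence). Downweighting schemes: none, high risk-of-bias studies,
studies evaluating at least one non-bridge treatment (NCT), or a custom
per-study map. The stage can run on the full dense network or on the
subnetwork of studies entirely within the bridge set (`common_subnetwork`);
the NCT scheme only makes sense on the full network.

One modeling subtlety is deliberate: the likelihood informs the dense
summary effects `mu^P2` only, while `beta` is identified purely by its
prior; the extrapolated effects are formed draw-wise as
`mu* = mu^P2 - beta`. Writing the shift into the likelihood mean instead
would let the data pin the combination `mu^P2 - beta` directly, making
the `beta` prior inert and collapsing the "extrapolation" onto the
unshifted dense estimates. The package's parameterization reproduces the
intended behaviors exactly: a point-mass `beta = 0` recovers the plain
dense NMA, and a point-mass `beta = c` shifts every extrapolated mean by
`-c`. The shift convention (`beta = mu^P2 - mu^P1`) can be flipped via
`beta_sign="p1_minus_p2"`.

Predictive priors for the target subgroup are
`N(mean(mu* draws), var(mu* draws) + E[tau_P2^2 draws])`. The variance is
computed by the law of total variance rather than by adding one simulated
heterogeneity deviate per draw: the two estimators have the same
expectation, but the analytic form removes Monte-Carlo noise and makes
the predictive variance dominate `var(mu*)` deterministically, as it must
(a new population's effect inherits the source network's between-study
heterogeneity). Predictive priors are exported only for bridge
comparisons; everything else falls back to the vague prior in stage 2.

## Location priors

*Data-based*: for each bridge comparison with direct evidence in both
subgroups, a joint pairwise meta-analysis with a single shared
comparison-specific heterogeneity SD (`HN(1)` prior) yields draws of
`u_P2 - u_P1`; the prior is the normal summary of that per-draw
difference, which respects the correlation induced by the shared
heterogeneity. Comparisons lacking direct data on either side get
`N(0, 10000)`.

*Expert-based*: each response (change score `x`, SD, confidence 1–10 for
one treatment) is modeled as `x ~ N(c, sd^2/gamma)` with
`gamma = confidence/10`, so full confidence leaves the stated uncertainty
untouched and low confidence inflates it — a power-weight reading of the
confidence scale; the mapping is overridable. Opinions are standardized
by the median pooled SD of the *target* subgroup's studies (configurable
to include both subgroups) — the elicited values must land on the target
network's SMD scale — and pooled with a between-expert SD `sigma ~ HN(1)`.
The latent per-expert opinions are marginalized analytically; no separate
prior is placed on them (their hierarchical distribution *is* the prior —
adding another vague prior on the same quantity would double-count).
Elicited contrasts `xi_j - xi_ref` replace the sparse-subgroup pairwise
estimates in the shift construction; the dense-side estimates still come
from pairwise meta-analyses of the dense data, and the two posterior
streams are paired draw-wise (they are independent fits, so pairing order
is immaterial for the mean/variance summary).

## Inference outputs

SUCRA is computed by ranking treatments within each posterior draw
(direction must be stated explicitly: `smaller_better` for outcomes where
negative SMDs favor the treatment) and averaging the cumulative rank
probabilities; the mean SUCRA across treatments is 0.5 for any
doubly-stochastic rank matrix, which the implementation asserts in tests.
Node splitting refits the network with a separate direct-effect parameter
for the chosen comparison: head-to-head studies are re-baselined to the
first treatment of the pair and their split contrast loads on the direct
parameter, while all remaining evidence informs the basic parameters; the
Bayesian p-value is `2*min{P, 1-P}` with `P = Pr(direct - indirect > 0)`
estimated from the joint draws. A comparison is splittable only if the
network minus that edge still connects the two treatments.

## Synthetic-data generator

`generate_scenario` draws, for each two-arm study on a requested edge, a
true standardized contrast from `N(mu_b - mu_a, tau)`, converts it to arm
means on an instrument scale (baseline change score -20, SD 10 — values
typical of symptom-scale psychiatry trials), and adds standard-error
noise to the observed means. Arm SDs come from a narrow lognormal around
the baseline SD so the pooled-SD code path sees unequal SDs. The dense
subgroup's basic parameters are the sparse ones plus a known
per-comparison shift (default 0.3 everywhere). Defaults: four treatments;
the sparse network is a single-study-per-edge star (the sparse regime the
method targets), the dense network a complete graph with three studies
per edge; 60 participants per arm, giving study totals near the
motivating sparse network's median of ~113 patients; `tau = 0.1` in both
subgroups. Risk-of-bias labels (30% high) and publication years are
assigned randomly to exercise the downweighting schemes. Everything is
deterministic given the scenario seed, and the generator writes the same
CSV dialect the reader consumes.

What the generator does *not* emulate: multi-arm trials (multi-arm code
paths are exercised by hand-built fixtures), non-normal outcomes,
missingness, systematic differences in measurement scales between
subgroups, or aggregation bias. Passing recovery tests therefore show
that the machinery is correct under the model's own assumptions, not that
the approach is robust to violations of them.

## Problem sizes in the checks

The heavier validation studies use scaled-down but statistically adequate
designs: credible-interval coverage is assessed over 40 replicate fits of
the default dense scenario (120 intervals; a 95% interval should cover in
[85%, 100%] of cases at this replication); the shift-recovery study uses
20 replicates with three sparse studies per comparison at n = 200 per arm,
chosen so the Monte-Carlo standard error of the averaged shift estimate
(~0.015) sits well inside the ±0.05 recovery band — with single-study
sparse edges the per-comparison estimate has SD ≈ 0.15 and a 60-value
average could not resolve a shift of 0.3 at that precision; the
precision-gain comparison runs one sparse scenario against both the
standard and the informed model at 2 chains x 4,000 iterations.

## Known limitations

* Continuous outcomes and arm-level input only; no contrast-level input,
  binary/count outcomes or multi-outcome handling.
* The data-based prior route uses the dense data twice (once in the prior,
  once in stage 1); the induced correlation is ignored, as in the
  underlying two-stage formulation.
* Heterogeneity in stage 2 is estimated independently of the dense
  network (`HN(1)`); no informative heterogeneity borrowing.
* The target subgroup's network reference must match the dense network's;
  the prior exchange format is reference-relative.
* No design-by-treatment-interaction inconsistency model; node splitting
  is the only inconsistency diagnostic.
* In very small networks with a free heterogeneity prior, the node-split
  Bayesian p-value is conservative (pushed toward 1): with one study per
  edge, `tau` is barely identified and its posterior uncertainty widens
  the direct-minus-indirect distribution. The calibration test therefore
  pins `tau = 0`; users splitting single-study-per-edge networks should
  read large p-values as absence of evidence, not evidence of consistency.
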