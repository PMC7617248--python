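"""Stage 1: extrapolate the dense network to the target population.

The dense (source) subgroup is fitted with a modified NMA in which the
random-effects mean of every bridge comparison is shifted by a location
parameter beta (the subgroup difference, carrying an informative prior
from :mod:`nmabridge.priors`) and the likelihood variance of selected
studies is inflated by a per-study scale weight w in (0, 1] — a
power-prior style downweight.  The extrapolated summary effects
mu* = mu_P2 - beta, combined with the source-network heterogeneity,
yield predictive normal priors N(mean, variance) for the target
subgroup's basic parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._sampler import WeightPrior, run_gibbs
from .data_model import SubgroupDataset, ValidationError, _key
from .engine import (
    MCMCSettings,
    ModelSpec,
    PosteriorSamples,
    VAGUE_MEAN,
    VAGUE_VAR,
    study_block,
    _check_connectivity,
)
from .priors import LocationPrior

__all__ = [
    "FixedWeight",
    "ScalePriorSpec",
    "PredictivePrior",
    "Stage1Result",
    "assign_scale_priors",
    "summarize_scale_prior",
    "common_subnetwork",
    "fit_stage1",
]


@dataclass(frozen=True)
class FixedWeight:
    """A degenerate scale prior: w fixed at a constant in (0, 1]."""

    value: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.value <= 1):
            raise ValidationError("fixed weight must be in (0, 1]")


WeightFamily = FixedWeight | WeightPrior


@dataclass(frozen=True)
class ScalePriorSpec:
    """Which studies get a non-trivial scale prior, and which family.

    scheme:
      * ``none``   — every study keeps weight 1;
      * ``rob``    — studies rated at high risk of bias get ``family``;
      * ``nct``    — studies evaluating >= 1 treatment outside the bridge
                     set get ``family``;
      * ``custom`` — per-study families from ``custom_map``.
    """

    scheme: str = "none"
    family: WeightFamily = field(default_factory=lambda: WeightPrior("beta", 3.0, 3.0))
    custom_map: Mapping[str, WeightFamily] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in {"none", "rob", "nct", "custom"}:
            raise ValidationError(f"unknown downweighting scheme {self.scheme!r}")
        if self.scheme == "custom" and not self.custom_map:
            raise ValidationError("custom scheme requires custom_map")


@dataclass(frozen=True)
class PredictivePrior:
    """Normal prior for a target-subgroup basic parameter, from stage 1."""

    treatment: str
    reference: str
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValidationError(
                f"predictive variance for {self.treatment!r} must be positive"
            )


@dataclass
class Stage1Result:
    posterior: PosteriorSamples  # mu[t], beta[t], tau, w[study]
    mu_star: dict[str, np.ndarray]  # treatment -> flat draws of mu_P2 - beta
    predictive: list[PredictivePrior]


def assign_scale_priors(
    dense: SubgroupDataset,
    spec: ScalePriorSpec,
    t_c: Sequence[str] | None = None,
) -> dict[str, WeightFamily]:
    """Map every dense-subgroup study to its weight-prior family."""
    assignment: dict[str, WeightFamily] = {
        s.study_id: FixedWeight(1.0) for s in dense.studies
    }
    if spec.scheme == "none":
        return assignment
    if spec.scheme == "custom":
        for sid, fam in spec.custom_map.items():
            if sid not in assignment:
                raise ValidationError(f"custom_map names unknown study {sid!r}")
            assignment[sid] = fam
        return assignment
    if spec.scheme == "rob":
        missing = [s.study_id for s in dense.studies if s.rob is None]
        if missing:
            raise ValidationError(
                f"rob scheme needs risk-of-bias ratings; missing for {missing[:5]}"
            )
        for s in dense.studies:
            if s.rob == "high":
                assignment[s.study_id] = spec.family
        return assignment
    # nct
    if t_c is None:
        raise ValidationError("nct scheme requires the bridge treatment set T_c")
    from .data_model import flag_nct_studies

    for sid in flag_nct_studies(dense, t_c):
        assignment[sid] = spec.family
    return assignment


def summarize_scale_prior(family: WeightFamily) -> tuple[float, tuple[float, float]]:
    """Analytic mean and equal-tailed 95% interval of a weight prior."""
    if isinstance(family, FixedWeight):
        return family.value, (family.value, family.value)
    if family.family == "beta":
        d = stats.beta(family.a, family.b)
    else:
        d = stats.uniform(family.a, family.b - family.a)
    return float(d.mean()), (float(d.ppf(0.025)), float(d.ppf(0.975)))


def common_subnetwork(dense: SubgroupDataset, t_c: Sequence[str]) -> SubgroupDataset:
    """Restrict the dense subgroup to studies whose arms all lie in T_c."""
    ck = {_key(t) for t in t_c}
    keep = [
        s.study_id
        for s in dense.studies
        if all(_key(t) in ck for t in s.treatments)
    ]
    if not keep:
        raise ValidationError("no dense study lies entirely within the bridge set")
    return dense.subset(keep)


def fit_stage1(
    dense: SubgroupDataset,
    beta_priors: Sequence[LocationPrior],
    scale_assignment: Mapping[str, WeightFamily],
    spec: ModelSpec,
    mcmc: MCMCSettings,
    *,
    t_c: Sequence[str] | None = None,
    beta_sign: str = "p2_minus_p1",
) -> Stage1Result:
    """Fit the extrapolation model and export predictive priors.

    ``beta_priors`` give N(mean, variance) priors per bridge treatment;
    bridge comparisons without an entry get the vague prior (with an
    identifiability warning, since neither data nor prior then separates
    mu_P2 from beta).  Predictive priors are exported for every bridge
    treatment: the predictive mean is the mean of the extrapolated draws
    mu* = mu_P2 - beta and the predictive variance adds the posterior
    mean of tau^2 (a new-population effect inherits the between-study
    heterogeneity of the source network).

    ``beta_sign='p1_minus_p2'`` flips the shift convention (the model is
    then mu* = mu_P2 + beta with the priors negated internally).
    """
    if beta_sign not in {"p2_minus_p1", "p1_minus_p2"}:
        raise ValidationError("beta_sign must be 'p2_minus_p1' or 'p1_minus_p2'")
    sign = 1.0 if beta_sign == "p2_minus_p1" else -1.0

    studies = list(dense.studies)
    if not studies:
        raise ValidationError("empty dense dataset")
    label_of: dict[str, str] = {}
    for s in studies:
        for t in s.treatments:
            label_of.setdefault(_key(t), t)
    rk = _key(spec.reference)
    if rk not in label_of:
        raise ValidationError(f"reference {spec.reference!r} not in dense data")
    _check_connectivity(studies, spec.reference, informed=set())

    others = sorted(k for k in label_of if k != rk)
    mu_cols = {k: i for i, k in enumerate(others)}

    prior_by_key = {_key(p.treatment): p for p in beta_priors}
    if t_c is None:
        bridge = sorted(prior_by_key)
    else:
        bridge = sorted(_key(t) for t in t_c if _key(t) != rk)
    bridge = [k for k in bridge if k in label_of]
    if not bridge:
        raise ValidationError("no bridge treatment present in the dense data")
    beta_cols = {k: len(others) + i for i, k in enumerate(bridge)}
    d = len(others) + len(bridge)

    prior_mean = np.full(d, spec.mu_prior[0])
    prior_var = np.full(d, spec.mu_prior[1])
    for k, col in beta_cols.items():
        p = prior_by_key.get(k)
        if p is None:
            warnings.warn(
                f"bridge comparison {label_of[k]!r} has no location prior; "
                "beta and mu_P2 are only jointly identified",
                stacklevel=2,
            )
            prior_mean[col], prior_var[col] = VAGUE_MEAN, VAGUE_VAR
        else:
            prior_mean[col], prior_var[col] = sign * p.mean, p.variance

    blocks = []
    for s in studies:
        fam = scale_assignment.get(s.study_id, FixedWeight(1.0))
        kwargs = (
            {"w_fixed": fam.value}
            if isinstance(fam, FixedWeight)
            else {"weight_prior": fam}
        )
        # The likelihood informs the source-network summaries mu_P2 only;
        # beta is identified by its prior and enters the extrapolation
        # mu* = mu_P2 - beta draw-wise.  Putting the shift into the
        # likelihood mean instead would let the data pin mu_P2 - beta
        # directly and the extrapolated means would collapse onto the
        # unshifted source estimates.
        blocks.append(
            study_block(s, mu_cols, d, likelihood_sd=spec.likelihood_sd, **kwargs)
        )

    res = run_gibbs(
        blocks, prior_mean, prior_var,
        tau_scale=spec.tau_prior_scale,
        chains=mcmc.chains, iterations=mcmc.iterations,
        burnin=mcmc.burnin, thin=mcmc.thin, seed=mcmc.seed,
    )
    names = [f"mu[{label_of[k]}]" for k in others]
    names += [f"beta[{label_of[k]}]" for k in bridge]
    draws = {nm: res.phi[:, :, i] for i, nm in enumerate(names)}
    if sign < 0:  # report beta in the caller's (flipped) convention
        for k in bridge:
            draws[f"beta[{label_of[k]}]"] = -draws[f"beta[{label_of[k]}]"]
    draws["tau"] = res.tau
    for i, sid in enumerate(res.w_labels):
        draws[f"w[{sid}]"] = res.w[:, :, i]
    posterior = PosteriorSamples(
        draws=draws,
        reference=label_of[rk],
        treatments=[label_of[rk]] + [label_of[k] for k in others],
    )

    tau_flat = res.tau.reshape(-1)
    mean_tau2 = float(np.mean(tau_flat**2))
    mu_star: dict[str, np.ndarray] = {}
    predictive: list[PredictivePrior] = []
    for k in bridge:
        mu_d = res.phi[:, :, mu_cols[k]].reshape(-1)
        beta_d = res.phi[:, :, beta_cols[k]].reshape(-1)  # internal convention
        star = mu_d - beta_d  # extrapolated target-subgroup mean
        mu_star[label_of[k]] = star
        predictive.append(
            PredictivePrior(
                treatment=label_of[k],
                reference=label_of[rk],
                mean=float(star.mean()),
                variance=float(star.var(ddof=1)) + mean_tau2,
            )
        )
    return Stage1Result(posterior=posterior, mu_star=mu_star, predictive=predictive)
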