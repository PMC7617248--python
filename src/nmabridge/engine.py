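"""Bayesian hierarchical network meta-analysis on the SMD scale.

The likelihood is stated at arm level — each observed arm mean is normal
around a latent arm mean with variance ``sd^2/n`` — and the latent
standardized contrasts follow a multivariate normal random-effects
distribution with common heterogeneity ``tau`` and covariance ``tau^2/2``
between contrasts sharing the baseline arm.  Consistency holds by
construction because only basic parameters (each treatment versus the
network reference) are sampled.  Because the model is linear-Gaussian
given ``tau``, the latent arm means are integrated out analytically and
the basic parameters are updated by exact conjugate draws (see
``_sampler``); posterior draws are identical in distribution to those of
the full arm-level parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import arviz as az
import networkx as nx
import numpy as np
import pandas as pd

from ._sampler import GaussianBlock, WeightPrior, run_gibbs
from .data_model import Study, SubgroupDataset, ValidationError, _key
from .effects import pooled_sd

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "PosteriorSamples",
    "ConvergenceReport",
    "IdentifiabilityError",
    "fit_nma",
    "fit_pairwise_ma",
    "fit_shared_het_pairwise",
    "gelman_rubin",
    "relative_effects",
]

VAGUE_MEAN = 0.0
VAGUE_VAR = 1.0e4  # variance, i.e. precision 1e-4 in BUGS convention


class IdentifiabilityError(ValueError):
    """The requested model has parameters the data and priors cannot pin."""


@dataclass(frozen=True)
class ModelSpec:
    """Model family selector and prior settings.

    ``basic_priors`` maps a treatment label ``j`` to the ``(mean, variance)``
    of a normal prior on the basic parameter (j versus the reference);
    unlisted comparisons get the vague N(0, 10000).
    """

    kind: str = "standard"  # standard | naive | pairwise
    reference: str = "Placebo"
    mu_prior: tuple[float, float] = (VAGUE_MEAN, VAGUE_VAR)
    tau_prior_scale: float = 1.0  # half-normal scale for heterogeneity SD
    basic_priors: Mapping[str, tuple[float, float]] | None = None
    likelihood_sd: str = "se"  # "se": var = sd^2/n ; "sd": var = sd^2

    def __post_init__(self) -> None:
        if self.kind not in {"standard", "naive", "pairwise"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.mu_prior[1] <= 0 or self.tau_prior_scale <= 0:
            raise ValueError("prior variance/scale parameters must be positive")
        if self.likelihood_sd not in {"se", "sd"}:
            raise ValueError("likelihood_sd must be 'se' or 'sd'")
        if self.basic_priors:
            for t, (_, v) in self.basic_priors.items():
                if v <= 0:
                    raise ValueError(f"prior variance for {t!r} must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 2
    iterations: int = 50_000
    burnin: int = 10_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be below iterations")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence checking")

    def reduced(self, iterations: int, burnin: int) -> "MCMCSettings":
        return replace(self, iterations=iterations, burnin=burnin)


@dataclass
class PosteriorSamples:
    """Named posterior draws, one array of shape (chains, draws) each."""

    draws: dict[str, np.ndarray]
    reference: str
    treatments: list[str] = field(default_factory=list)

    def array(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return np.asarray(self.draws[name]).reshape(-1)

    def basic_draws(self, treatment: str) -> np.ndarray:
        """Draws of the basic parameter mu[treatment]; zeros for the reference."""
        if _key(treatment) == _key(self.reference):
            n = next(iter(self.draws.values())).size
            return np.zeros(n)
        name = f"mu[{treatment}]"
        if name not in self.draws:
            for t in self.treatments:
                if _key(t) == _key(treatment):
                    name = f"mu[{t}]"
                    break
        return self.array(name)

    def names(self) -> list[str]:
        return list(self.draws)

    def summary(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else self.names()
        rows = []
        for nm in names:
            a = self.array(nm)
            q = np.percentile(a, [2.5, 50.0, 97.5])
            rows.append(
                {"parameter": nm, "mean": a.mean(), "sd": a.std(ddof=1),
                 "q2.5": q[0], "q50": q[1], "q97.5": q[2]}
            )
        return pd.DataFrame(rows).set_index("parameter")

    def mc_se(self, name: str) -> float:
        """Monte-Carlo standard error via effective sample size."""
        a = np.asarray(self.draws[name])
        ess = float(az.ess(az.convert_to_dataset(a[None] if a.ndim == 1 else a)).x)
        return float(a.std(ddof=1) / np.sqrt(max(ess, 1.0)))


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: dict[str, float]
    converged: bool
    threshold: float = 1.1


# ---------------------------------------------------------------------------
# block construction


def _arm_var(arm, likelihood_sd: str) -> float:
    return arm.sd**2 / arm.n if likelihood_sd == "se" else arm.sd**2


def study_block(
    study: Study,
    columns: Mapping[str, int],
    d: int,
    *,
    likelihood_sd: str = "se",
    shift_columns: Mapping[str, int] | None = None,
    direct_pair: tuple[str, str] | None = None,
    direct_col: int | None = None,
    weight_prior: WeightPrior | None = None,
    w_fixed: float = 1.0,
) -> GaussianBlock:
    """Standardized-contrast block for one study.

    ``columns`` maps treatment keys to basic-parameter columns (the network
    reference has no column).  ``shift_columns`` adds the location-shift
    parameters beta with sign -1 for the arm and +1 for the baseline, i.e.
    the contrast mean becomes the contrast of (mu - beta).  When
    ``direct_pair=(a, b)`` is given and the study baseline is ``a``, the
    contrast of arm ``b`` loads on the separate direct-effect column
    instead of the basic parameters (node splitting).
    """
    sp = pooled_sd(study).value
    base = study.arms[0]
    bkey = _key(base.treatment)
    v = [_arm_var(a, likelihood_sd) for a in study.arms]
    m = study.n_arms - 1
    x = np.empty(m)
    X = np.zeros((m, d))
    C = (np.full((m, m), v[0]) + np.diag([v[k + 1] for k in range(m)])) / sp**2
    for r, arm in enumerate(study.arms[1:]):
        akey = _key(arm.treatment)
        x[r] = (arm.mean - base.mean) / sp
        if direct_pair is not None and bkey == direct_pair[0] and akey == direct_pair[1]:
            X[r, direct_col] = 1.0
            continue
        if akey in columns:
            X[r, columns[akey]] += 1.0
        if bkey in columns:
            X[r, columns[bkey]] -= 1.0
        if shift_columns is not None:
            if akey in shift_columns:
                X[r, shift_columns[akey]] -= 1.0
            if bkey in shift_columns:
                X[r, shift_columns[bkey]] += 1.0
    return GaussianBlock(
        label=study.study_id, X=X, x=x, C=C,
        weight_prior=weight_prior, w_fixed=w_fixed,
    )


def _check_connectivity(
    studies: Sequence[Study], reference: str, informed: set[str]
) -> None:
    g = nx.Graph()
    for s in studies:
        keys = [_key(t) for t in s.treatments]
        g.add_nodes_from(keys)
        g.add_edges_from(
            (keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))
        )
    rk = _key(reference)
    g.add_node(rk)
    for comp in nx.connected_components(g):
        if rk in comp:
            continue
        orphan = comp - informed
        if orphan:
            raise IdentifiabilityError(
                "treatments disconnected from the reference and without "
                f"informative priors: {sorted(orphan)}"
            )


# ---------------------------------------------------------------------------
# fitting


def fit_nma(
    ds: SubgroupDataset | Sequence[SubgroupDataset],
    spec: ModelSpec,
    mcmc: MCMCSettings,
    *,
    tau_fixed: float | None = None,
    split_comparison: tuple[str, str] | None = None,
) -> PosteriorSamples:
    """Fit the hierarchical NMA to one subgroup (or, naively, to several).

    With ``kind='naive'`` a sequence of subgroup datasets is concatenated
    and analyzed as if all studies came from one population.  With
    ``split_comparison=(a, b)`` a separate direct-effect parameter is
    estimated from the studies comparing a and b head to head
    (node splitting); those studies are re-baselined to ``a``.
    """
    if isinstance(ds, SubgroupDataset):
        datasets = [ds]
    else:
        datasets = list(ds)
        if spec.kind == "naive" and len(datasets) < 2:
            raise ValidationError("naive synthesis expects >= 2 subgroup datasets")
    studies: list[Study] = [s for d_ in datasets for s in d_.studies]
    if not studies:
        raise ValidationError("no studies to fit")

    label_of: dict[str, str] = {}
    for s in studies:
        for t in s.treatments:
            label_of.setdefault(_key(t), t)
    rk = _key(spec.reference)
    if rk not in label_of:
        raise ValidationError(f"reference {spec.reference!r} not present in data")

    prior_map = { _key(t): mv for t, mv in (spec.basic_priors or {}).items() }
    _check_connectivity(studies, spec.reference, informed=set(prior_map))

    others = sorted(k for k in label_of if k != rk)
    columns = {k: i for i, k in enumerate(others)}
    d = len(others)
    names = [f"mu[{label_of[k]}]" for k in others]
    prior_mean = np.full(d, spec.mu_prior[0])
    prior_var = np.full(d, spec.mu_prior[1])
    for k, (m0, v0) in prior_map.items():
        if k in columns:
            prior_mean[columns[k]] = m0
            prior_var[columns[k]] = v0

    direct_col = None
    if split_comparison is not None:
        a, b = (_key(split_comparison[0]), _key(split_comparison[1]))
        direct_col = d
        names.append(f"direct[{label_of[a]}:{label_of[b]}]")
        prior_mean = np.append(prior_mean, VAGUE_MEAN)
        prior_var = np.append(prior_var, VAGUE_VAR)
        d += 1
        split_keys = (a, b)

    blocks = []
    for s in studies:
        pair = None
        if split_comparison is not None:
            keys = {_key(t) for t in s.treatments}
            if split_keys[0] in keys and split_keys[1] in keys:
                s = s.rebaseline(label_of[split_keys[0]])
                pair = split_keys
        blocks.append(
            study_block(
                s, columns, d, likelihood_sd=spec.likelihood_sd,
                direct_pair=pair, direct_col=direct_col,
            )
        )

    res = run_gibbs(
        blocks, prior_mean, prior_var,
        tau_scale=spec.tau_prior_scale, tau_fixed=tau_fixed,
        chains=mcmc.chains, iterations=mcmc.iterations,
        burnin=mcmc.burnin, thin=mcmc.thin, seed=mcmc.seed,
    )
    draws = {nm: res.phi[:, :, i] for i, nm in enumerate(names)}
    draws["tau"] = res.tau
    return PosteriorSamples(
        draws=draws,
        reference=label_of[rk],
        treatments=[label_of[k] for k in [rk] + others],
    )


def _restrict_to_pair(ds: SubgroupDataset, comparison: tuple[str, str]) -> list[Study]:
    a, b = (_key(comparison[0]), _key(comparison[1]))
    out = []
    for s in ds.studies:
        keys = {_key(t): t for t in s.treatments}
        if a in keys and b in keys:
            arms = tuple(
                arm for arm in s.arms if _key(arm.treatment) in (a, b)
            )
            arms = tuple(sorted(arms, key=lambda arm: _key(arm.treatment) != a))
            out.append(replace(s, arms=arms))
    return out


def fit_pairwise_ma(
    ds: SubgroupDataset,
    comparison: tuple[str, str],
    mcmc: MCMCSettings,
    *,
    tau_prior_scale: float = 1.0,
    likelihood_sd: str = "se",
    mu_prior: tuple[float, float] = (VAGUE_MEAN, VAGUE_VAR),
    tau_fixed: float | None = None,
) -> PosteriorSamples:
    """Random-effects pairwise meta-analysis of one comparison.

    Returns draws of ``u`` (the summary SMD of ``comparison[1]`` versus
    ``comparison[0]``) and ``tau`` (comparison heterogeneity).  Only the two
    arms of interest enter; other arms of multi-arm studies are dropped.
    """
    studies = _restrict_to_pair(ds, comparison)
    if not studies:
        raise ValidationError(
            f"no study in subgroup {ds.subgroup!r} compares {comparison[0]!r} "
            f"and {comparison[1]!r} directly"
        )
    bkey = _key(comparison[1])
    columns = {bkey: 0}
    blocks = [
        study_block(s, columns, 1, likelihood_sd=likelihood_sd) for s in studies
    ]
    res = run_gibbs(
        blocks, np.array([mu_prior[0]]), np.array([mu_prior[1]]),
        tau_scale=tau_prior_scale, tau_fixed=tau_fixed,
        chains=mcmc.chains, iterations=mcmc.iterations,
        burnin=mcmc.burnin, thin=mcmc.thin, seed=mcmc.seed,
    )
    return PosteriorSamples(
        draws={"u": res.phi[:, :, 0], "tau": res.tau},
        reference=comparison[0],
        treatments=[comparison[0], comparison[1]],
    )


def fit_shared_het_pairwise(
    ds1: SubgroupDataset,
    ds2: SubgroupDataset,
    comparison: tuple[str, str],
    mcmc: MCMCSettings,
    *,
    tau_prior_scale: float = 1.0,
    likelihood_sd: str = "se",
) -> PosteriorSamples:
    """Joint pairwise meta-analysis of both subgroups with one shared
    comparison-specific heterogeneity SD ``sigma``.

    Returns draws of ``u_P1`` and ``u_P2`` (the subgroup summary SMDs) and
    ``sigma``; the per-draw difference ``u_P2 - u_P1`` is the basis of the
    data-based location priors.
    """
    s1 = _restrict_to_pair(ds1, comparison)
    s2 = _restrict_to_pair(ds2, comparison)
    if not s1 or not s2:
        missing = ds1.subgroup if not s1 else ds2.subgroup
        raise ValidationError(
            f"comparison {comparison!r} has no direct study in subgroup {missing!r}"
        )
    bkey = _key(comparison[1])
    blocks = []
    for col, studies in ((0, s1), (1, s2)):
        for s in studies:
            blk = study_block(s, {bkey: col}, 2, likelihood_sd=likelihood_sd)
            blk.label = f"{'P1' if col == 0 else 'P2'}:{s.study_id}"
            blocks.append(blk)
    res = run_gibbs(
        blocks, np.zeros(2), np.full(2, VAGUE_VAR),
        tau_scale=tau_prior_scale,
        chains=mcmc.chains, iterations=mcmc.iterations,
        burnin=mcmc.burnin, thin=mcmc.thin, seed=mcmc.seed,
    )
    return PosteriorSamples(
        draws={
            "u_P1": res.phi[:, :, 0],
            "u_P2": res.phi[:, :, 1],
            "sigma": res.tau,
        },
        reference=comparison[0],
        treatments=[comparison[0], comparison[1]],
    )


# ---------------------------------------------------------------------------
# diagnostics and derived effects


def gelman_rubin(
    samples: PosteriorSamples,
    parameters: Sequence[str] | None = None,
    threshold: float = 1.1,
) -> ConvergenceReport:
    """Potential-scale-reduction diagnostic; convergence means rhat < 1.1.

    By default all basic parameters, shift parameters and heterogeneity
    SDs are monitored (study weights are not inference targets).
    """
    if parameters is None:
        parameters = [
            nm for nm in samples.names()
            if not nm.startswith("w[") and not nm.startswith("delta[")
        ]
    rhat: dict[str, float] = {}
    for nm in parameters:
        a = np.asarray(samples.draws[nm])
        if a.ndim != 2 or a.shape[0] < 2:
            raise ValidationError("Gelman-Rubin needs >= 2 chains per parameter")
        if np.allclose(a.var(axis=1), 0.0):
            # constant chains: identical -> converged trivially, else divergent
            rhat[nm] = 1.0 if np.allclose(a.mean(axis=1), a.mean()) else np.inf
            continue
        rhat[nm] = float(az.rhat(az.convert_to_dataset(a)).x)
    return ConvergenceReport(
        rhat=rhat,
        converged=all(np.isfinite(v) and v < threshold for v in rhat.values()),
        threshold=threshold,
    )


def relative_effects(
    samples: PosteriorSamples, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Posterior summaries of mu[l] - mu[j] for each requested pair (j, l).

    Formed draw-wise from the basic parameters, so consistency holds
    exactly for every draw.
    """
    known = {_key(t) for t in samples.treatments}
    rows = []
    for j, l in pairs:
        if _key(j) not in known or _key(l) not in known:
            raise KeyError(f"unknown treatment in pair ({j!r}, {l!r})")
        a = samples.basic_draws(l) - samples.basic_draws(j)
        q = np.percentile(a, [2.5, 50.0, 97.5])
        rows.append(
            {"comparison": f"{l} vs {j}", "mean": a.mean(), "sd": a.std(ddof=1),
             "q2.5": q[0], "q50": q[1], "q97.5": q[2]}
        )
    return pd.DataFrame(rows).set_index("comparison")


def relative_effect_draws(
    samples: PosteriorSamples, j: str, l: str
) -> np.ndarray:
    """Flat draws of mu[l] - mu[j]."""
    return samples.basic_draws(l) - samples.basic_draws(j)
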