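"""Priors for the location-shift parameters beta.

beta_1j is the difference between the two subgroups' summary SMDs for the
basic comparison of treatment j versus the reference.  Two routes build a
normal prior N(d_1j, var(d_1j)) for it:

* data-based: a joint pairwise meta-analysis of the comparison in both
  subgroups with a shared comparison-specific heterogeneity; the prior
  moments are those of the per-draw difference u_P2 - u_P1;
* expert-based: clinicians state an expected change score (with an SD and
  a 0-10 confidence) per bridge treatment for the target population; the
  responses are pooled by a confidence-weighted random-effects model on
  the standardized scale, and u_P1 is replaced by the pooled elicited
  contrast xi_j - xi_ref.

Comparisons that cannot be informed on either route fall back to the
vague N(0, 10000).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sampler import GaussianBlock, run_gibbs
from .data_model import SubgroupDataset, ValidationError, _key
from .effects import pooled_sd
from .engine import (
    MCMCSettings,
    VAGUE_MEAN,
    VAGUE_VAR,
    fit_pairwise_ma,
    fit_shared_het_pairwise,
)

__all__ = [
    "LocationPrior",
    "ExpertResponse",
    "ExpertPoolResult",
    "median_pooled_sd",
    "data_based_beta_priors",
    "pool_expert_responses",
    "expert_based_beta_priors",
    "read_expert_table",
    "write_location_priors",
    "read_location_priors",
]


@dataclass(frozen=True)
class LocationPrior:
    """Normal prior for beta (treatment vs reference shift between subgroups)."""

    treatment: str
    reference: str
    mean: float
    variance: float
    source: str  # data | expert | vague

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValidationError(
                f"prior variance for {self.treatment!r} must be positive"
            )

    @classmethod
    def vague(cls, treatment: str, reference: str) -> "LocationPrior":
        return cls(treatment, reference, VAGUE_MEAN, VAGUE_VAR, "vague")


@dataclass(frozen=True)
class ExpertResponse:
    expert_id: str
    treatment: str
    x: float  # elicited change score, instrument units
    sd: float  # elicited SD, instrument units
    confidence: int  # 1..10

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError(f"expert {self.expert_id!r}: sd must be > 0")
        if not (1 <= self.confidence <= 10):
            raise ValidationError(
                f"expert {self.expert_id!r}: confidence must be in 1..10"
            )


@dataclass
class ExpertPoolResult:
    """Pooled elicited SMD-scale means per treatment."""

    xi: dict[str, np.ndarray]  # treatment -> flat draws of xi_j
    sigma: np.ndarray  # flat draws of the between-expert SD
    med_pooled_sd: float  # the standardizing constant, instrument units


def median_pooled_sd(*datasets: SubgroupDataset) -> float:
    """Median pooled within-study SD across all studies of the datasets.

    Used to place elicited change scores on the SMD scale.
    """
    values = [pooled_sd(s).value for ds in datasets for s in ds.studies]
    if not values:
        raise ValidationError("no studies to compute a median pooled SD from")
    return float(median(values))


def _has_direct(ds: SubgroupDataset, reference: str, j: str) -> bool:
    rk, jk = _key(reference), _key(j)
    return any(
        {rk, jk} <= {_key(t) for t in s.treatments} for s in ds.studies
    )


def data_based_beta_priors(
    sparse: SubgroupDataset,
    dense: SubgroupDataset,
    t_c: Sequence[str],
    reference: str,
    mcmc: MCMCSettings,
) -> list[LocationPrior]:
    """Data-based location priors for every bridge comparison.

    For each j in T_c with direct evidence in *both* subgroups, a joint
    shared-heterogeneity pairwise meta-analysis gives draws of
    d_1j = u_P2 - u_P1, summarized into N(mean, variance).  Comparisons
    without direct data on either side get the vague prior.
    """
    t_c = [t for t in t_c if _key(t) != _key(reference)]
    if not t_c:
        raise ValidationError("empty bridge set: no comparisons to build priors for")
    out = []
    for j in sorted(t_c, key=_key):
        if _has_direct(sparse, reference, j) and _has_direct(dense, reference, j):
            fit = fit_shared_het_pairwise(sparse, dense, (reference, j), mcmc)
            diff = fit.array("u_P2") - fit.array("u_P1")
            out.append(
                LocationPrior(j, reference, float(diff.mean()),
                              float(diff.var(ddof=1)), "data")
            )
        else:
            out.append(LocationPrior.vague(j, reference))
    return out


def pool_expert_responses(
    responses: Sequence[ExpertResponse],
    med_pooled_sd: float,
    mcmc: MCMCSettings,
    *,
    gamma: Mapping[int, float] | None = None,
) -> ExpertPoolResult:
    """Pool elicited change scores into SMD-scale treatment means.

    Model: each response's change score is normal around the expert's
    latent opinion with variance sd^2/gamma_h (gamma_h = confidence/10 by
    default, so full confidence leaves the stated variance untouched);
    opinions, standardized by the median pooled SD of the data, are
    exchangeable around a treatment mean xi_j with between-expert SD
    sigma ~ HN(1); xi_j ~ N(0, 10000).
    """
    if med_pooled_sd <= 0:
        raise ValidationError("med_pooled_sd must be positive")
    if not responses:
        raise ValidationError("no expert responses to pool")

    def gamma_of(conf: int) -> float:
        if gamma is not None:
            return float(gamma[conf])
        return conf / 10.0

    treatments: dict[str, str] = {}
    for r in responses:
        treatments.setdefault(_key(r.treatment), r.treatment)
    cols = {k: i for i, k in enumerate(sorted(treatments))}
    d = len(cols)

    blocks = []
    for r in responses:
        X = np.zeros((1, d))
        X[0, cols[_key(r.treatment)]] = 1.0
        blocks.append(
            GaussianBlock(
                label=f"{r.expert_id}:{r.treatment}",
                X=X,
                x=np.array([r.x / med_pooled_sd]),
                C=np.array([[r.sd**2 / (gamma_of(r.confidence) * med_pooled_sd**2)]]),
            )
        )
    res = run_gibbs(
        blocks, np.zeros(d), np.full(d, VAGUE_VAR),
        tau_scale=1.0, chains=mcmc.chains, iterations=mcmc.iterations,
        burnin=mcmc.burnin, thin=mcmc.thin, seed=mcmc.seed,
    )
    xi = {
        treatments[k]: res.phi[:, :, i].reshape(-1) for k, i in cols.items()
    }
    return ExpertPoolResult(
        xi=xi, sigma=res.tau.reshape(-1), med_pooled_sd=med_pooled_sd
    )


def expert_based_beta_priors(
    pool: ExpertPoolResult,
    dense: SubgroupDataset,
    t_c: Sequence[str],
    reference: str,
    mcmc: MCMCSettings,
) -> list[LocationPrior]:
    """Location priors from expert opinion.

    The target-subgroup summary u_P1 for each bridge comparison is the
    elicited contrast xi_j - xi_ref; the source-subgroup summary u_P2
    comes from a pairwise meta-analysis of the dense data.  The prior is
    the normal summary of d = u_P2 - u_P1 over draws.
    """
    xi_by_key = {_key(t): v for t, v in pool.xi.items()}
    rk = _key(reference)
    if rk not in xi_by_key:
        raise ValidationError(
            f"reference {reference!r} was not elicited; elicited contrasts "
            "cannot be formed"
        )
    xi_ref = xi_by_key[rk]
    out = []
    for j in sorted((t for t in t_c if _key(t) != rk), key=_key):
        jk = _key(j)
        if jk not in xi_by_key or not _has_direct(dense, reference, j):
            out.append(LocationPrior.vague(j, reference))
            continue
        u_p1 = xi_by_key[jk] - xi_ref
        fit = fit_pairwise_ma(dense, (reference, j), mcmc)
        u_p2 = fit.array("u")
        n = min(u_p1.size, u_p2.size)
        diff = u_p2[:n] - u_p1[:n]  # independent fits; paired draw-wise
        out.append(
            LocationPrior(j, reference, float(diff.mean()),
                          float(diff.var(ddof=1)), "expert")
        )
    return out


# ---------------------------------------------------------------------------
# exchange formats


def read_expert_table(path, sep: str = ",") -> list[ExpertResponse]:
    """Read elicitation responses: expert, treatment, x, sd, confidence."""
    df = pd.read_csv(path, sep=sep)
    required = ["expert", "treatment", "x", "sd", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"expert table missing column(s): {missing}")
    return [
        ExpertResponse(
            expert_id=str(r["expert"]), treatment=str(r["treatment"]).strip(),
            x=float(r["x"]), sd=float(r["sd"]), confidence=int(r["confidence"]),
        )
        for _, r in df.iterrows()
    ]


def write_location_priors(priors: Sequence, path) -> None:
    """Write a prior set (LocationPrior or PredictivePrior) as CSV."""
    rows = []
    for p in priors:
        rows.append(
            {
                "treatment": p.treatment,
                "reference": p.reference,
                "mean": p.mean,
                "variance": p.variance,
                "source": getattr(p, "source", "predictive"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_location_priors(path) -> list[LocationPrior]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        LocationPrior(
            treatment=str(r["treatment"]), reference=str(r["reference"]),
            mean=float(r["mean"]), variance=float(r["variance"]),
            source=str(r.get("source", "data")),
        )
        for _, r in df.iterrows()
    ]
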