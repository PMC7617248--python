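"""Stage 2: NMA of the sparse target network with informative priors.

Identical to the standard hierarchical NMA except that the basic
parameters carry the normal predictive priors exported by stage 1;
comparisons without a prior keep the vague N(0, 10000), and the
heterogeneity prior remains HN(1).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .data_model import SubgroupDataset, ValidationError, _key
from .engine import MCMCSettings, ModelSpec, PosteriorSamples, fit_nma
from .stage1 import PredictivePrior

__all__ = ["fit_informed_nma"]


def fit_informed_nma(
    sparse: SubgroupDataset,
    priors: Sequence[PredictivePrior],
    spec: ModelSpec,
    mcmc: MCMCSettings,
) -> PosteriorSamples:
    """Fit the target-subgroup NMA under stage-1 informative priors.

    Every prior must be expressed relative to the same network reference
    as ``spec.reference``; the prior exchange format is reference-relative
    and a mismatch is a hard error.
    """
    basic: dict[str, tuple[float, float]] = dict(spec.basic_priors or {})
    for p in priors:
        if _key(p.reference) != _key(spec.reference):
            raise ValidationError(
                f"prior for {p.treatment!r} is relative to {p.reference!r}, "
                f"but the model reference is {spec.reference!r}"
            )
        if p.variance <= 0:
            raise ValidationError(f"prior variance for {p.treatment!r} must be > 0")
        basic[p.treatment] = (p.mean, p.variance)
    informed_spec = replace(spec, kind="standard", basic_priors=basic)
    return fit_nma(sparse, informed_spec, mcmc)
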