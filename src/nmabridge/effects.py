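"""Standardized mean difference (SMD) machinery shared by all models.

The SMD for arm ``k`` versus the study baseline is the mean difference
divided by the pooled within-study SD, making effects comparable across
studies that measured the outcome on different instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data_model import Study, ValidationError

__all__ = ["PooledSD", "SMDVector", "pooled_sd", "observed_smd"]


@dataclass(frozen=True)
class PooledSD:
    study_id: str
    value: float  # outcome-scale units, > 0


@dataclass(frozen=True)
class SMDVector:
    study_id: str
    baseline: str
    entries: dict[str, float]  # treatment of arm k (k > 1) -> SMD


def pooled_sd(study: Study, *, hedges: bool = False) -> PooledSD:
    """Pooled within-study SD across all arms.

    Uses the standard (n_k - 1)-weighted pooled sample SD,

        sd_pooled = sqrt( sum_k (n_k - 1) sd_k^2 / (sum_k n_k - K) ).

    ``hedges`` is accepted for signature stability but no small-sample
    correction is applied here (it would act on the SMD, not the SD).
    """
    n_total = study.total_n
    k = study.n_arms
    if n_total <= k:
        raise ValidationError(
            f"study {study.study_id!r}: pooled SD denominator "
            f"(sum n - K = {n_total - k}) must be positive"
        )
    num = sum((a.n - 1) * a.sd**2 for a in study.arms)
    return PooledSD(study.study_id, math.sqrt(num / (n_total - k)))


def observed_smd(study: Study, *, hedges: bool = False) -> SMDVector:
    """Observed SMD of every non-baseline arm versus arm 1.

    By default no Hedges' small-sample correction is applied; pass
    ``hedges=True`` to multiply each entry by ``J = 1 - 3/(4*df - 1)``
    with ``df = sum n - K``.
    """
    sp = pooled_sd(study).value
    base = study.arms[0]
    j = 1.0
    if hedges:
        df = study.total_n - study.n_arms
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    entries = {
        a.treatment: j * (a.mean - base.mean) / sp for a in study.arms[1:]
    }
    return SMDVector(study.study_id, base.treatment, entries)
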