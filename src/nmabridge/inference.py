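"""Post-fit inference: rankings, league tables, node splitting.

SUCRA (surface under the cumulative ranking curve) summarizes each
treatment's rank distribution into a single number in [0, 1]: 1 means
certainly best, 0 certainly worst.  Node splitting decouples a
comparison's direct evidence from the indirect estimate implied by the
rest of the network and reports a Bayesian two-sided p-value
2 * min{P, 1 - P}, with P the posterior probability that the
direct-minus-indirect difference is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import SubgroupDataset, ValidationError, _key
from .engine import (
    MCMCSettings,
    ModelSpec,
    PosteriorSamples,
    fit_nma,
)

__all__ = [
    "SucraTable",
    "NodeSplitResult",
    "sucra",
    "node_split",
    "splittable_comparisons",
    "league_table",
    "bayesian_p",
]


@dataclass
class SucraTable:
    treatments: list[str]
    sucra: dict[str, float]
    rank_probabilities: pd.DataFrame  # treatments x ranks (1 = best)

    def ranked(self) -> list[str]:
        return sorted(self.treatments, key=lambda t: -self.sucra[t])


@dataclass(frozen=True)
class NodeSplitResult:
    comparison: tuple[str, str]
    direct: dict[str, float]
    indirect: dict[str, float]
    difference: dict[str, float]
    p_value: float


def _summ(a: np.ndarray) -> dict[str, float]:
    q = np.percentile(a, [2.5, 97.5])
    return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)),
            "q2.5": float(q[0]), "q97.5": float(q[1])}


def sucra(samples: PosteriorSamples, direction: str = "smaller_better") -> SucraTable:
    """Rank treatments per posterior draw and average the cumulative curve.

    ``direction='smaller_better'`` ranks the most negative effect first
    (appropriate when the outcome is symptom reduction coded so that
    negative SMDs favor the treatment); ``'larger_better'`` flips it.
    """
    if direction not in {"smaller_better", "larger_better"}:
        raise ValidationError("direction must be smaller_better or larger_better")
    ts = samples.treatments
    if len(ts) < 2:
        raise ValidationError("ranking needs >= 2 treatments")
    mat = np.column_stack([samples.basic_draws(t) for t in ts])
    if direction == "larger_better":
        mat = -mat
    order = np.argsort(mat, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n, t = mat.shape
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(t)[None, :]  # 0 = best
    probs = np.stack([(ranks == r).mean(axis=0) for r in range(t)], axis=1)
    cum = np.cumsum(probs, axis=1)
    sucra_vals = cum[:, :-1].sum(axis=1) / (t - 1)
    rp = pd.DataFrame(probs, index=ts, columns=[f"rank{r+1}" for r in range(t)])
    return SucraTable(
        treatments=list(ts),
        sucra={tr: float(v) for tr, v in zip(ts, sucra_vals)},
        rank_probabilities=rp,
    )


def bayesian_p(diff_draws: np.ndarray) -> float:
    """Two-sided Bayesian p-value 2*min{P, 1-P}, P = Pr(diff > 0).

    Draws exactly equal to zero count half toward P, guarding degenerate
    fixtures without affecting continuous posteriors.
    """
    d = np.asarray(diff_draws, dtype=float)
    p = float(np.mean((d > 0) + 0.5 * (d == 0)))
    return 2.0 * min(p, 1.0 - p)


def splittable_comparisons(
    ds: SubgroupDataset, reference: str
) -> list[tuple[str, str]]:
    """Pairs with direct evidence and an independent indirect path."""
    from .data_model import build_network

    net = build_network(ds, reference)
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    weights: dict[frozenset, int] = {}
    for pair, sids in net.edges.items():
        a, b = sorted(pair)
        g.add_edge(a, b)
        weights[pair] = len(sids)
    out = []
    for pair in net.edges:
        a, b = sorted(pair)
        h = g.copy()
        h.remove_edge(a, b)
        if nx.has_path(h, a, b):
            out.append((a, b))
    return sorted(out)


def node_split(
    ds: SubgroupDataset,
    comparison: tuple[str, str],
    spec: ModelSpec,
    mcmc: MCMCSettings,
    *,
    tau_fixed: float | None = None,
) -> NodeSplitResult:
    """Split one comparison into direct and indirect components.

    The model gains a separate direct-effect parameter estimated from the
    head-to-head studies of the pair, while the basic parameters carry the
    remaining (indirect) evidence; both are sampled jointly.
    ``tau_fixed`` pins the heterogeneity SD (useful for common-effect
    splits and calibration checks); by default tau keeps its HN prior.
    """
    a, b = comparison
    pairs = {tuple(sorted((_key(x), _key(y)))) for x, y in splittable_comparisons(ds, spec.reference)}
    if tuple(sorted((_key(a), _key(b)))) not in pairs:
        raise ValidationError(
            f"comparison ({a!r}, {b!r}) not splittable: needs both direct "
            "evidence and an independent indirect path"
        )
    samples = fit_nma(ds, spec, mcmc, split_comparison=(a, b), tau_fixed=tau_fixed)
    direct_name = next(nm for nm in samples.names() if nm.startswith("direct["))
    direct = samples.array(direct_name)
    indirect = samples.basic_draws(b) - samples.basic_draws(a)
    diff = direct - indirect
    return NodeSplitResult(
        comparison=(a, b),
        direct=_summ(direct),
        indirect=_summ(indirect),
        difference=_summ(diff),
        p_value=bayesian_p(diff),
    )


def league_table(samples: PosteriorSamples, digits: int = 2) -> pd.DataFrame:
    """All-pairs matrix of 'mean (2.5, 97.5)' SMD summaries.

    Entry (row j, column l) is the effect of l versus j, so the mean part
    of the matrix is antisymmetric and the diagonal is zero.
    """
    ts = samples.treatments
    draws = {t: samples.basic_draws(t) for t in ts}
    out = pd.DataFrame(index=ts, columns=ts, dtype=object)
    for j in ts:
        for l in ts:
            if j == l:
                out.loc[j, l] = f"{0.0:.{digits}f}"
                continue
            d = draws[l] - draws[j]
            lo, hi = np.percentile(d, [2.5, 97.5])
            out.loc[j, l] = f"{d.mean():.{digits}f} ({lo:.{digits}f}, {hi:.{digits}f})"
    return out
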